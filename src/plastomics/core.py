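"""Core domain types and I/O for comparative plastome analysis.

The chloroplast genome of most land plants is a circular molecule with a
quadripartite architecture: a large single-copy region (LSC), a small
single-copy region (SSC), and two inverted repeats (IRa/IRb) that are exact
reverse complements of each other.  Every region-aware statistic in this
package is expressed in a single coordinate frame: the plastome linearized
at the conventional origin (the start of the LSC), with 1-based inclusive
coordinates throughout (the GFF3 convention).  Features and repeat runs are
never traced across the origin.

Reported values (percentages, densities, ratios) are rounded half-up at a
declared precision via :class:`ReportValue`; the full-precision raw value is
always retained alongside the rounded one.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
STRICT_DNA = set("ACGTN")

VALID_FEATURE_CLASSES = ("protein_coding", "tRNA", "rRNA", "pseudogene")


class PlastomeError(ValueError):
    """Raised on malformed inputs (sequences, annotations, partitions)."""


# ---------------------------------------------------------------------------
# Rounding / reporting conventions
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int) -> float:
    """Round *value* half-up at *decimals* decimal places.

    Python's built-in ``round`` is banker's rounding; printed tables in
    comparative-genomics reports conventionally use half-up (0.125 -> 0.13 at
    two decimals).  ``decimal`` with ``ROUND_HALF_UP`` on the shortest repr
    gives the decimal-string behaviour.
    """
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ReportValue:
    """A raw number together with its half-up rounded, printable form."""

    raw: float
    decimals: int
    units: str = ""

    @property
    def rounded(self) -> float:
        return round_half_up(self.raw, self.decimals)

    def __float__(self) -> float:
        return self.rounded

    def __str__(self) -> str:
        s = f"{self.rounded:.{self.decimals}f}"
        return f"{s} {self.units}".strip()


def report_percentage(numerator: float, denominator: float, decimals: int = 2) -> ReportValue:
    """``100 * numerator / denominator`` as a half-up rounded percentage."""
    if denominator <= 0:
        raise PlastomeError(f"percentage denominator must be > 0, got {denominator}")
    return ReportValue(100.0 * numerator / denominator, decimals, units="%")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on the linearized plastome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise PlastomeError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RegionPartition:
    """The quadripartite LSC -> IRb -> SSC -> IRa coordinate frame.

    Invariants: the four intervals are contiguous in that order, cover
    ``[1, total]``, the two IRs have equal length, and the LSC is the longer
    of the two single-copy regions.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    total: int

    REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")

    def __post_init__(self) -> None:
        regions = [self.lsc, self.irb, self.ssc, self.ira]
        if self.lsc.start != 1:
            raise PlastomeError("LSC must start at position 1")
        for a, b in zip(regions, regions[1:]):
            if b.start != a.end + 1:
                raise PlastomeError("regions must be contiguous in LSC,IRb,SSC,IRa order")
        if self.ira.end != self.total:
            raise PlastomeError("IRa must end at the genome length")
        if len(self.irb) != len(self.ira):
            raise PlastomeError(
                f"inverted repeats must have equal length (IRb {len(self.irb)}, IRa {len(self.ira)})"
            )
        if len(self.lsc) < len(self.ssc):
            raise PlastomeError("LSC must be the longer single-copy region")

    @property
    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, position: int) -> str:
        if not 1 <= position <= self.total:
            raise PlastomeError(f"position {position} outside [1, {self.total}]")
        for name, iv in self.regions.items():
            if position in iv:
                return name
        raise AssertionError("unreachable: partition covers [1, total]")

    @property
    def junctions(self) -> dict[str, int]:
        """Last position of the upstream region at each boundary.

        ``IRa/LSC`` is the circular junction at the linearization origin.
        """
        return {
            "LSC/IRb": self.lsc.end,
            "IRb/SSC": self.irb.end,
            "SSC/IRa": self.ssc.end,
            "IRa/LSC": self.ira.end,
        }


def build_partition(lsc_len: int, irb_len: int, ssc_len: int, ira_len: int) -> RegionPartition:
    """Lay out the four regions from position 1 in LSC,IRb,SSC,IRa order."""
    for name, n in (("lsc", lsc_len), ("irb", irb_len), ("ssc", ssc_len), ("ira", ira_len)):
        if n <= 0:
            raise PlastomeError(f"{name} length must be > 0, got {n}")
    if irb_len != ira_len:
        raise PlastomeError(f"unequal IR lengths: IRb {irb_len} != IRa {ira_len}")
    b0 = lsc_len
    b1 = b0 + irb_len
    b2 = b1 + ssc_len
    total = b2 + ira_len
    return RegionPartition(
        lsc=Interval(1, b0),
        irb=Interval(b0 + 1, b1),
        ssc=Interval(b1 + 1, b2),
        ira=Interval(b2 + 1, total),
        total=total,
    )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise PlastomeError(
                f"gene {self.gene_id}: invalid coordinates {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise PlastomeError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.feature_class not in VALID_FEATURE_CLASSES:
            raise PlastomeError(
                f"gene {self.gene_id}: unknown feature class {self.feature_class!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class PlastomeRecord:
    species_id: str
    sequence: str
    circular: bool = True
    partition: RegionPartition | None = None
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise PlastomeError(
                f"record {self.species_id}: non-IUPAC characters {sorted(bad)}"
            )
        if self.partition is not None and self.partition.total != len(self.sequence):
            raise PlastomeError(
                f"record {self.species_id}: partition total {self.partition.total} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_sequence(self, region: str) -> str:
        if self.partition is None:
            raise PlastomeError(f"record {self.species_id} has no partition")
        iv = self.partition.regions[region]
        return self.sequence[iv.start - 1 : iv.end]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    """Read plastome sequences from FASTA.

    Sequences are upper-cased and U mapped to T; record order is preserved.
    Empty files, duplicate identifiers and non-IUPAC characters are hard
    errors naming the offending record.
    """
    records: list[PlastomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PlastomeError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(PlastomeRecord(species_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise PlastomeError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.species_id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


_GFF_TYPE_TO_CLASS = {
    "gene": "protein_coding",
    "CDS": "protein_coding",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "pseudogene": "pseudogene",
}


def read_gff3(path: str | Path, seq_id: str | None = None,
              genome_length: int | None = None) -> list[GeneAnnotation]:
    """Read gene/tRNA/rRNA/pseudogene features from a GFF3 file.

    Coordinates are GFF3-native 1-based inclusive.  Features are filtered to
    *seq_id* when given and validated against *genome_length* when given.
    The feature class comes from the ``gene_biotype``/``biotype`` attribute
    when present, else from the GFF3 type column.
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise PlastomeError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in _GFF_TYPE_TO_CLASS:
                continue
            if seq_id is not None and seqid != seq_id:
                continue
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attributes.get("ID") or attributes.get("Name") or f"feature_{lineno}"
            start, end = int(start_s), int(end_s)
            if end < start:
                raise PlastomeError(f"{path}:{lineno}: end {end} < start {start} for {gene_id}")
            if genome_length is not None and end > genome_length:
                raise PlastomeError(
                    f"{path}:{lineno}: feature {gene_id} ends at {end} beyond "
                    f"genome length {genome_length}"
                )
            feature_class = attributes.get("gene_biotype", attributes.get("biotype"))
            if feature_class is None:
                feature_class = _GFF_TYPE_TO_CLASS[ftype]
            annotations.append(
                GeneAnnotation(gene_id=gene_id, start=start, end=end,
                               strand=strand, feature_class=feature_class)
            )
    return annotations


def write_gff3(genes: Sequence[GeneAnnotation], seq_id: str, path: str | Path,
               genome_length: int | None = None) -> None:
    _CLASS_TO_TYPE = {
        "protein_coding": "gene", "tRNA": "tRNA", "rRNA": "rRNA",
        "pseudogene": "pseudogene",
    }
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        if genome_length is not None:
            handle.write(f"##sequence-region {seq_id} 1 {genome_length}\n")
        for g in genes:
            ftype = _CLASS_TO_TYPE[g.feature_class]
            attrs = f"ID={g.gene_id};gene_biotype={g.feature_class}"
            handle.write(
                f"{seq_id}\tplastomics\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

def gc_content(sequence: str, interval: Interval | None = None) -> ReportValue:
    """GC fraction over ACGT bases (N excluded from the denominator).

    Returned as a :class:`ReportValue` percentage at two decimals, the
    precision used throughout plastome characterization tables.
    """
    if interval is not None:
        if interval.end > len(sequence):
            raise PlastomeError(
                f"interval [{interval.start}, {interval.end}] outside sequence "
                f"of length {len(sequence)}"
            )
        sequence = sequence[interval.start - 1 : interval.end]
    if not sequence:
        raise PlastomeError("empty sequence")
    sequence = sequence.upper()
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise PlastomeError("GC content undefined: no unambiguous bases")
    return ReportValue(100.0 * gc / (gc + at), 2, units="%")


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]
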