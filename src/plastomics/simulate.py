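"""Seeded synthetic-data generators for every pipeline input.

Two generators produce the study-shaped inputs with machine-readable truth
sets:

* :func:`synth_plastome` — a quadripartite plastome (LSC -> IRb -> SSC ->
  IRa, IRa the exact reverse complement of IRb) with planted perfect SSRs at
  known coordinates and genes planted across region junctions.  The random
  background is guaranteed free of unplanned threshold-qualifying SSRs by a
  bounded resampling loop, so the emitted truth set is exhaustive.
* :func:`synth_alignment` — a multi-taxon gene alignment with planted
  biallelic SNPs (chosen carriers, chosen Ts/Tv class via the ref/alt
  bases), planted gap blocks, and optional i.i.d. background substitution
  noise at a per-site probability theta outside the planted columns.

Both are pure functions of (spec, seed): identical inputs give byte-identical
output.  :func:`table6_fixture` builds the fixed four-taxon marker-gene
alignment used throughout the diagnostics worked examples (three cactiform
taxa against one pachycaul reference, ten substitution columns, one 3-bp
deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    GeneAnnotation,
    PlastomeError,
    PlastomeRecord,
    RegionPartition,
    build_partition,
    reverse_complement,
)
from .diversity import AlignedSet
from .ssr import SSRLocus, SSRThresholds, assign_regions, detect_ssrs

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Plastome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSSR:
    """A perfect repeat to embed: motif x repeats at a 1-based offset within
    one of LSC, IRb or SSC.  (IRa is derived from IRb, so an SSR planted in
    IRb automatically appears reverse-complemented in IRa and both copies
    enter the truth set.)"""

    motif: str
    repeats: int
    region: str
    offset: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeats


@dataclass(frozen=True)
class PlantedGene:
    """A gene laid across one junction: extends *upstream_bp* into the region
    before the boundary and *downstream_bp* past it."""

    gene_id: str
    junction: str
    upstream_bp: int
    downstream_bp: int
    strand: str = "+"
    feature_class: str = "protein_coding"


@dataclass
class PlastomeSpec:
    lsc_len: int
    ir_len: int
    ssc_len: int
    gc: float = 0.35
    ssrs: list[PlantedSSR] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)
    seed: int = 0
    species_id: str = "synthetic_plastome"
    thresholds: SSRThresholds | None = None

    def __post_init__(self) -> None:
        if self.lsc_len < self.ssc_len:
            raise PlastomeError("LSC must be at least as long as SSC")
        if not 0.0 < self.gc < 1.0:
            raise PlastomeError("background GC must be in (0, 1)")


@dataclass
class PlastomeTruth:
    partition: RegionPartition
    ssrs: list[SSRLocus]
    genes: list[GeneAnnotation]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _guard_base(rng: np.random.Generator, forbidden: str, gc: float) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    weights = np.array([(gc / 2) if b in "GC" else ((1 - gc) / 2) for b in choices])
    return str(rng.choice(np.array(choices), p=weights / weights.sum()))


def synth_plastome(spec: PlastomeSpec) -> tuple[PlastomeRecord, PlastomeTruth]:
    """Generate a quadripartite plastome with exhaustive SSR truth.

    Regions are drawn i.i.d. at the spec GC; planted SSRs are written at
    their offsets with one guard base on each side (chosen to break one-unit
    extension, so planted coordinates are exactly maximal); IRa is the
    reverse complement of IRb.  The assembled genome is re-scanned and any
    unplanned qualifying run has its window resampled, bounded at 1,000
    passes, guaranteeing the detected set equals the truth set.
    """
    thresholds = spec.thresholds or SSRThresholds.default()
    rng = np.random.default_rng(spec.seed)
    partition = build_partition(spec.lsc_len, spec.ir_len, spec.ssc_len, spec.ir_len)
    region_ivs = {"LSC": partition.lsc, "IRb": partition.irb, "SSC": partition.ssc}

    buffers = {
        "LSC": _random_bases(rng, spec.lsc_len, spec.gc),
        "IRb": _random_bases(rng, spec.ir_len, spec.gc),
        "SSC": _random_bases(rng, spec.ssc_len, spec.gc),
    }

    # ---- plant SSRs (with guard bases), checking for overlap -------------
    protected: dict[str, set[int]] = {r: set() for r in buffers}  # 0-based, incl. guards
    planted_genomic: list[SSRLocus] = []
    for planted in spec.ssrs:
        if planted.region not in buffers:
            raise PlastomeError(
                f"SSRs can be planted in LSC, IRb or SSC only (IRa is derived), "
                f"got {planted.region!r}"
            )
        u = len(planted.motif)
        if not (1 <= u <= 6):
            raise PlastomeError(f"motif {planted.motif!r} must be 1-6 bp")
        if planted.repeats < thresholds[u]:
            raise PlastomeError(
                f"planted {planted.motif} x {planted.repeats} is below the "
                f"unit-{u} threshold {thresholds[u]}"
            )
        buf = buffers[planted.region]
        s = planted.offset - 1
        e = s + planted.length  # 0-based exclusive
        if s < 1 or e > len(buf) - 1:
            raise PlastomeError(
                f"planted SSR {planted.motif} x {planted.repeats} at offset "
                f"{planted.offset} does not fit inside {planted.region} "
                f"(guard bases need one position on each side)"
            )
        footprint = set(range(s - 1, e + 1))
        if footprint & protected[planted.region]:
            raise PlastomeError(f"planted features overlap in {planted.region}")
        protected[planted.region] |= footprint
        buf[s:e] = list(planted.motif * planted.repeats)
        buf[s - 1] = _guard_base(rng, planted.motif[-1], spec.gc)
        buf[e] = _guard_base(rng, planted.motif[0], spec.gc)
        g0 = region_ivs[planted.region].start - 1  # genomic 0-based offset
        planted_genomic.append(
            SSRLocus(motif=planted.motif, unit_size=u, repeat_count=planted.repeats,
                     start=g0 + s + 1, end=g0 + e)
        )

    # mirror IRb plants into IRa coordinates (reverse-complement motif)
    def _mirrored(loci: list[SSRLocus]) -> list[SSRLocus]:
        out = []
        for l in loci:
            if l.start < partition.irb.start or l.end > partition.irb.end:
                continue
            # revcomp(m * k) == revcomp(m) * k, so the mirrored run is a
            # maximal run of the reverse-complement motif at the same phase
            rc_motif = reverse_complement(l.motif)
            new_end = partition.ira.end - (l.start - partition.irb.start)
            new_start = new_end - l.length + 1
            out.append(SSRLocus(motif=rc_motif, unit_size=l.unit_size,
                                repeat_count=l.repeat_count,
                                start=new_start, end=new_end))
        return out

    expected = planted_genomic + _mirrored(planted_genomic)

    def assemble() -> str:
        irb = "".join(buffers["IRb"])
        return "".join(buffers["LSC"]) + irb + "".join(buffers["SSC"]) + reverse_complement(irb)

    # ---- resample any unplanned qualifying run ---------------------------
    expected_keys = {(l.motif, l.start, l.end) for l in expected}
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for _attempt in range(1000):
        # the first and last SSC bases must not be complementary, or the
        # exact reverse-complement match would extend the IRs inward by one
        ssc = buffers["SSC"]
        while ssc[0] == comp[str(ssc[-1])]:
            target = 0 if 0 not in protected["SSC"] else len(ssc) - 1
            ssc[target] = str(_random_bases(rng, 1, spec.gc)[0])
        genome = assemble()
        detected = detect_ssrs(genome, thresholds)
        extra = [l for l in detected
                 if (l.motif, l.start, l.end) not in expected_keys]
        if not extra and len(detected) == len(expected):
            break
        for l in extra:
            for pos in range(l.start - 1, l.end):  # genomic 0-based
                region = partition.region_of(pos + 1)
                if region == "IRa":  # mirror into the IRb buffer
                    pos = partition.irb.start - 1 + (partition.ira.end - 1 - pos)
                    region = "IRb"
                off = pos - (region_ivs[region].start - 1)
                if off in protected[region]:
                    continue
                buffers[region][off] = str(_random_bases(rng, 1, spec.gc)[0])
    else:
        raise PlastomeError("could not clear unplanned SSRs within 1,000 passes")

    # ---- genes across junctions -----------------------------------------
    genes: list[GeneAnnotation] = []
    for pg in spec.genes:
        if pg.junction not in partition.junctions or pg.junction == "IRa/LSC":
            raise PlastomeError(
                f"gene {pg.gene_id}: junction must be one of LSC/IRb, IRb/SSC, "
                f"SSC/IRa (no origin-spanning genes)"
            )
        if pg.upstream_bp < 1 or pg.downstream_bp < 1:
            raise PlastomeError(f"gene {pg.gene_id}: spans must be >= 1 bp")
        boundary = partition.junctions[pg.junction]
        genes.append(
            GeneAnnotation(gene_id=pg.gene_id,
                           start=boundary - pg.upstream_bp + 1,
                           end=boundary + pg.downstream_bp,
                           strand=pg.strand, feature_class=pg.feature_class)
        )

    record = PlastomeRecord(species_id=spec.species_id, sequence=genome,
                            partition=partition, genes=genes)
    truth = PlastomeTruth(partition=partition,
                          ssrs=assign_regions(sorted(expected, key=lambda l: l.start),
                                              partition),
                          genes=genes)
    return record, truth


# ---------------------------------------------------------------------------
# Alignment generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSNP:
    position: int  # 1-based alignment column
    ref: str
    alt: str
    carriers: frozenset[str]  # taxa carrying the alt base


@dataclass(frozen=True)
class PlantedIndel:
    start: int
    length: int
    carriers: frozenset[str]  # taxa carrying the gap


@dataclass
class AlignmentSpec:
    taxa: list[str]
    length: int
    theta: float = 0.0
    snps: list[PlantedSNP] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 0.5:
            raise PlastomeError("theta must be in [0, 0.5)")
        if len(set(self.taxa)) != len(self.taxa):
            raise PlastomeError("duplicate taxon labels")


@dataclass
class AlignmentTruth:
    snps: list[PlantedSNP]
    indels: list[PlantedIndel]


def expected_background_diversity(theta: float) -> float:
    """Expected pairwise difference proportion between two taxa whose bases
    were each independently substituted with probability theta (uniform over
    the three alternatives): ``1 - ((1-theta)^2 + theta^2 / 3)``."""
    return 1.0 - ((1.0 - theta) ** 2 + theta ** 2 / 3.0)


def synth_alignment(spec: AlignmentSpec) -> tuple[AlignedSet, AlignmentTruth]:
    """Generate a multi-taxon alignment realizing the planted variants
    exactly, with background noise at per-site probability theta restricted
    to columns that are neither planted SNPs nor inside/adjacent to planted
    gap blocks."""
    rng = np.random.default_rng(spec.seed)
    n, L = len(spec.taxa), spec.length
    if n < 2:
        raise PlastomeError("alignment needs at least two taxa")
    taxa_set = set(spec.taxa)

    protected = np.zeros(L, dtype=bool)
    for indel in spec.indels:
        if not indel.carriers or not set(indel.carriers) < taxa_set:
            raise PlastomeError("indel carriers must be a non-empty proper taxon subset")
        s, e = indel.start - 1, indel.start - 1 + indel.length
        if s < 0 or e > L:
            raise PlastomeError(f"indel at {indel.start} does not fit the alignment")
        protected[max(0, s - 1) : min(L, e + 1)] = True
    for snp in spec.snps:
        if not snp.carriers or not set(snp.carriers) < taxa_set:
            raise PlastomeError("SNP carriers must be a non-empty proper taxon subset")
        if snp.ref == snp.alt or snp.ref not in "ACGT" or snp.alt not in "ACGT":
            raise PlastomeError(f"invalid planted SNP {snp.ref}->{snp.alt}")
        col = snp.position - 1
        if not 0 <= col < L:
            raise PlastomeError(f"SNP position {snp.position} outside alignment")
        if protected[col]:
            raise PlastomeError(
                f"planted SNP at {snp.position} collides with another planted feature"
            )
        protected[col] = True

    ancestral = _random_bases(rng, L, 0.35)
    rows = np.tile(ancestral, (n, 1))

    if spec.theta > 0:
        noise = (rng.random((n, L)) < spec.theta) & ~protected[None, :]
        shifts = rng.integers(1, 4, size=(n, L))
        idx = np.searchsorted(_BASES, rows)
        rows = np.where(noise, _BASES[(idx + shifts) % 4], rows)

    taxon_index = {t: i for i, t in enumerate(spec.taxa)}
    for snp in spec.snps:
        col = snp.position - 1
        for t in spec.taxa:
            rows[taxon_index[t], col] = snp.alt if t in snp.carriers else snp.ref
    for indel in spec.indels:
        s, e = indel.start - 1, indel.start - 1 + indel.length
        for t in indel.carriers:
            rows[taxon_index[t], s:e] = "-"

    aligned = AlignedSet(list(spec.taxa), ["".join(r) for r in rows])
    return aligned, AlignmentTruth(snps=list(spec.snps), indels=list(spec.indels))


# ---------------------------------------------------------------------------
# Fixed marker-gene fixture
# ---------------------------------------------------------------------------

REFERENCE_TAXON = "E_drupifera"
CACTIFORM_TAXA = ("E_resinifera", "E_ampliphylla", "E_royleana")

#: column -> (drupifera, resinifera, ampliphylla, royleana) bases
_FIXTURE_SNPS: dict[int, tuple[str, str, str, str]] = {
    223: ("A", "G", "G", "G"),
    385: ("A", "G", "G", "G"),
    390: ("A", "G", "G", "G"),
    391: ("T", "C", "C", "C"),
    392: ("A", "T", "T", "T"),
    394: ("G", "T", "T", "T"),
    396: ("A", "T", "T", "T"),
    397: ("G", "A", "A", "A"),
    405: ("T", "T", "T", "G"),
    409: ("C", "A", "A", "A"),
}

_FIXTURE_INDEL_START = 150  # columns 150-152; retained string AGC
_FIXTURE_LENGTH = 426


def table6_fixture() -> AlignedSet:
    """The fixed four-taxon marker-gene alignment (synthetic stand-in).

    426 columns; the ten substitution columns carry the published per-taxon
    bases; a 3-column AGC block retained only by the pachycaul reference is
    gapped in the three cactiform taxa.  The gap block is placed in an
    otherwise invariant stretch (columns 150-152) so that gap columns never
    coincide with substitution columns; all remaining columns are invariant.
    Everything outside the variable columns is synthetic background — this
    is a structural stand-in, not the deposited gene sequence.
    """
    rng = np.random.default_rng(426_2026)
    background = _random_bases(rng, _FIXTURE_LENGTH, 0.35)
    taxa = (REFERENCE_TAXON,) + CACTIFORM_TAXA
    rows = np.tile(background, (4, 1))
    for col, bases in _FIXTURE_SNPS.items():
        for i, b in enumerate(bases):
            rows[i, col - 1] = b
    s = _FIXTURE_INDEL_START - 1
    rows[0, s : s + 3] = list("AGC")
    for i in range(1, 4):
        rows[i, s : s + 3] = "-"
    return AlignedSet(list(taxa), ["".join(r) for r in rows])
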