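"""Alignment-column variant analysis for marker genes.

Given a small multiple alignment of a candidate marker (e.g. a plastid
ribosomal-protein gene), this module extracts the full variant picture used
in lineage typing:

* SNP calling per alignment column, polarized against an explicit reference
  taxon (reference polarity decides "gains" vs "loses" below);
* transition/transversion classification (purine<->purine or
  pyrimidine<->pyrimidine = transition; cross-class = transversion);
* the A/T compositional effect of each substitution ("loses_A", "gains_T",
  ...), the base-level counterpart of the T/A homopolymer gradient;
* maximal shared gap blocks (indels) with the retained string;
* group-diagnostic columns (one base fixed in a taxon group, a single
  different base fixed outside it) and private alleles (exactly one taxon
  deviating);
* pairwise percent identity over gap-free pair columns.

Positions are 1-based alignment columns of the supplied alignment.
Multiallelic columns are retained in the SNP list but excluded from Ts/Tv
and A/T-effect summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Mapping, Sequence

from .core import PlastomeError, round_half_up
from .diversity import AlignedSet

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = {"A", "C", "G", "T"}


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """'transition' or 'transversion' for one base change."""
    r, a = ref_base.upper(), alt_base.upper()
    if r not in _BASES or a not in _BASES:
        raise PlastomeError(f"substitution needs two bases, got {ref_base!r}->{alt_base!r}")
    if r == a:
        raise PlastomeError(f"not a substitution: {r}->{a}")
    if {r, a} <= _PURINES or {r, a} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def ta_effect(ref_base: str, alt_base: str) -> frozenset[str]:
    """A/T gain/loss labels for one substitution (possibly empty).

    ``loses_X`` iff the reference base is X in {A, T}; ``gains_Y`` iff the
    alternate base is Y in {A, T}.  Antisymmetric: swapping ref and alt
    mirrors gains and loses.
    """
    r, a = ref_base.upper(), alt_base.upper()
    if r == a:
        raise PlastomeError(f"not a substitution: {r}->{a}")
    labels = set()
    if r in ("A", "T"):
        labels.add(f"loses_{r}")
    if a in ("A", "T"):
        labels.add(f"gains_{a}")
    return frozenset(labels)


@dataclass(frozen=True)
class SNPRecord:
    position: int
    alleles: Mapping[str, str]  # taxon -> base (or '-')
    reference_base: str
    derived_base: str | None
    change_type: str  # transition | transversion | multiallelic
    ta_effect: frozenset[str] = field(default_factory=frozenset)
    warning: str | None = None


def call_snps(aligned: AlignedSet, reference_taxon: str | None = None) -> list[SNPRecord]:
    """One record per column with >= 2 distinct non-gap bases.

    The reference base is taken from *reference_taxon* (default: first row).
    Biallelic columns get a derived base, Ts/Tv class and A/T-effect labels;
    columns with three or more bases — or a gapped reference — are flagged
    multiallelic and excluded from downstream Ts/Tv and effect summaries.
    """
    if aligned.n < 2:
        raise PlastomeError("SNP calling requires at least two sequences")
    if reference_taxon is None:
        reference_taxon = aligned.taxa[0]
    if reference_taxon not in aligned.taxa:
        raise PlastomeError(f"reference taxon {reference_taxon!r} not in alignment")
    ref_row = aligned.row(reference_taxon)
    records: list[SNPRecord] = []
    for col in range(aligned.length):
        column = {t: r[col] for t, r in zip(aligned.taxa, aligned.rows)}
        bases = {b for b in column.values() if b in _BASES}
        if len(bases) < 2:
            continue
        position = col + 1
        ref_base = ref_row[col]
        if ref_base not in _BASES:
            records.append(
                SNPRecord(position=position, alleles=column, reference_base=ref_base,
                          derived_base=None, change_type="multiallelic",
                          warning="reference has gap/N at variable site")
            )
            continue
        alts = bases - {ref_base}
        if len(alts) == 1:
            alt = next(iter(alts))
            records.append(
                SNPRecord(position=position, alleles=column, reference_base=ref_base,
                          derived_base=alt,
                          change_type=classify_substitution(ref_base, alt),
                          ta_effect=ta_effect(ref_base, alt))
            )
        else:
            records.append(
                SNPRecord(position=position, alleles=column, reference_base=ref_base,
                          derived_base=None, change_type="multiallelic")
            )
    return records


def transition_transversion_counts(records: Sequence[SNPRecord]) -> tuple[int, int]:
    ts = sum(1 for r in records if r.change_type == "transition")
    tv = sum(1 for r in records if r.change_type == "transversion")
    return ts, tv


def pairwise_identity(row_i: str, row_j: str) -> tuple[float, int]:
    """(percent identity half-up at 2 decimals, compared length).

    The denominator is the number of columns where neither row carries a
    gap or N (ambiguous sites are excluded from the comparison, like gaps).
    """
    if len(row_i) != len(row_j):
        raise PlastomeError("rows must have equal aligned length")
    ri, rj = row_i.upper(), row_j.upper()
    comparable = [(a, b) for a, b in zip(ri, rj) if a in _BASES and b in _BASES]
    if not comparable:
        raise PlastomeError("no gap-free columns shared by the pair")
    matches = sum(1 for a, b in comparable if a == b)
    return round_half_up(100.0 * matches / len(comparable), 2), len(comparable)


@dataclass
class IdentityMatrix:
    taxa: list[str]
    percent: list[list[float]]  # half-up, 2 decimals; diagonal 100.00
    compared_length: list[list[int]]


def identity_matrix(aligned: AlignedSet) -> IdentityMatrix:
    n = aligned.n
    percent = [[100.00] * n for _ in range(n)]
    compared = [[0] * n for _ in range(n)]
    for i in range(n):
        compared[i][i] = sum(1 for c in aligned.rows[i] if c in _BASES)
        for j in range(i + 1, n):
            p, m = pairwise_identity(aligned.rows[i], aligned.rows[j])
            percent[i][j] = percent[j][i] = p
            compared[i][j] = compared[j][i] = m
    return IdentityMatrix(taxa=list(aligned.taxa), percent=percent,
                          compared_length=compared)


def diagnostic_sites(aligned: AlignedSet, group: Sequence[str]
                     ) -> tuple[list[int], dict[str, list[int]]]:
    """Shared group-diagnostic columns and private-allele columns.

    A column is *shared diagnostic* for *group* when every group member
    carries one base, every non-member carries a single different base, and
    no row is gapped there.  A column is *private* to a taxon when exactly
    one taxon differs from the (uniform) rest.
    """
    group_set = set(group)
    if not group_set or not group_set < set(aligned.taxa):
        raise PlastomeError("group must be a non-empty proper subset of the taxa")
    others = [t for t in aligned.taxa if t not in group_set]
    shared: list[int] = []
    private: dict[str, list[int]] = {}
    for col in range(aligned.length):
        column = {t: r[col] for t, r in zip(aligned.taxa, aligned.rows)}
        if any(b not in _BASES for b in column.values()):
            continue
        in_bases = {column[t] for t in group_set}
        out_bases = {column[t] for t in others}
        if len(in_bases) == 1 and len(out_bases) == 1 and in_bases != out_bases:
            shared.append(col + 1)
        # private allele: exactly one taxon deviates from the uniform rest
        values = list(column.values())
        distinct = set(values)
        if len(distinct) == 2:
            minority = [t for t in aligned.taxa
                        if values.count(column[t]) == 1]
            if len(minority) == 1:
                private.setdefault(minority[0], []).append(col + 1)
    return shared, private


@dataclass(frozen=True)
class IndelRecord:
    start: int
    end: int
    inserted_or_deleted: str
    taxa_with_gap: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_indels(aligned: AlignedSet) -> list[IndelRecord]:
    """Maximal contiguous gap blocks grouped by identical gapped-taxon set.

    The retained string is read from any non-gapped taxon.  A column gapped
    in every row is a malformed alignment and rejected.
    """
    if aligned.n < 2:
        raise PlastomeError("indel detection requires at least two sequences")
    gap_sets = []
    for col in range(aligned.length):
        gapped = frozenset(t for t, r in zip(aligned.taxa, aligned.rows) if r[col] == "-")
        if len(gapped) == aligned.n:
            raise PlastomeError(f"column {col + 1} is all-gap; malformed alignment")
        gap_sets.append(gapped)
    records: list[IndelRecord] = []
    col = 0
    for gapped, run in groupby(gap_sets):
        width = len(list(run))
        if gapped:
            donor = next(t for t in aligned.taxa if t not in gapped)
            retained = aligned.row(donor)[col : col + width]
            records.append(
                IndelRecord(start=col + 1, end=col + width,
                            inserted_or_deleted=retained, taxa_with_gap=gapped)
            )
        col += width
    return records
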