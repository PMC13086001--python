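"""Perfect simple-sequence-repeat (SSR) detection and genome-level statistics.

Chloroplast SSRs (cpSSRs) are perfect tandem repeats of a 1-6 bp motif.  The
scanner reports every maximal perfect run whose *primitive* unit size is at
most six and whose repeat count meets a per-unit-size minimum — the
MISA-style convention with default minima of 10, 6, 4, 4, 3 and 3 repeats
for mono- through hexanucleotide motifs.

Conventions (all deliberate, all consequential for the counts):

* a run qualifies only at its smallest period: ``ATATATATATAT`` is one
  dinucleotide AT x 6, never a qualifying mononucleotide run;
* motifs are reported exactly as observed on the given strand — no
  reverse-complement or cyclic-rotation canonicalization, so A- and
  T-homopolymers are distinct classes, as are TAA/ATA/AAT;
* ``N`` breaks runs; runs never wrap the circular origin;
* compound SSRs are not merged — adjacent qualifying runs are reported
  independently;
* a locus is assigned to the quadripartite region containing its *start*
  coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .core import (
    PlastomeError,
    RegionPartition,
    ReportValue,
    round_half_up,
)

#: MISA-style minimum repeat counts, indexed by unit size 1..6.
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 4, 5: 3, 6: 3}

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat count per motif unit size (1..6)."""

    min_repeats: dict[int, int]

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise PlastomeError("thresholds must cover unit sizes 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise PlastomeError("all repeat thresholds must be >= 2")

    @classmethod
    def default(cls) -> "SSRThresholds":
        return cls(dict(DEFAULT_THRESHOLDS))

    @classmethod
    def from_sequence(cls, values: Sequence[int]) -> "SSRThresholds":
        if len(values) != 6:
            raise PlastomeError("expected six threshold values (unit sizes 1..6)")
        return cls({u: int(v) for u, v in zip(range(1, 7), values)})

    def __getitem__(self, unit_size: int) -> int:
        return self.min_repeats[unit_size]


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect repeat run (1-based inclusive coordinates)."""

    motif: str
    unit_size: int
    repeat_count: int
    start: int
    end: int
    region: str = "unassigned"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_size * self.repeat_count:
            raise PlastomeError(
                f"SSR span {self.start}-{self.end} inconsistent with "
                f"{self.repeat_count} x {self.unit_size} bp units"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def is_primitive(motif: str) -> bool:
    """True iff *motif* is not a repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def detect_ssrs(sequence: str, thresholds: SSRThresholds | None = None) -> list[SSRLocus]:
    """Find all threshold-qualifying maximal perfect SSRs in *sequence*.

    For each unit size u, a left-maximal periodic run is grown by comparing
    each base with the base one unit downstream; the run is truncated to
    whole units.  Runs whose motif is non-primitive are left to the smaller
    period at which they are reported.  Empty input yields an empty list.
    """
    if thresholds is None:
        thresholds = SSRThresholds.default()
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for u in range(1, 7):
        thr = thresholds[u]
        i = 0
        while i + u * thr <= n:
            j = i
            # grow while base j matches base j+u; N never matches anything
            while j + u < n and seq[j] in _ACGT and seq[j] == seq[j + u]:
                j += 1
            repeats = (j - i + u) // u
            if repeats >= thr:
                motif = seq[i : i + u]
                if _ACGT.issuperset(motif) and is_primitive(motif):
                    loci.append(
                        SSRLocus(
                            motif=motif,
                            unit_size=u,
                            repeat_count=repeats,
                            start=i + 1,
                            end=i + repeats * u,
                        )
                    )
            i = j + 1
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def assign_regions(loci: Sequence[SSRLocus], partition: RegionPartition) -> list[SSRLocus]:
    """Tag each locus with the quadripartite region containing its start."""
    assigned = []
    for locus in loci:
        if not (1 <= locus.start <= partition.total and locus.end <= partition.total):
            raise PlastomeError(
                f"SSR at {locus.start}-{locus.end} outside genome [1, {partition.total}]"
            )
        assigned.append(
            SSRLocus(
                motif=locus.motif,
                unit_size=locus.unit_size,
                repeat_count=locus.repeat_count,
                start=locus.start,
                end=locus.end,
                region=partition.region_of(locus.start),
            )
        )
    return assigned


@dataclass
class SSRSummary:
    """Genome-level SSR statistics in the layout of a plastome survey table."""

    total: int
    by_unit_size: dict[int, int]
    by_region: dict[str, int]
    region_density_per_100kb: dict[str, ReportValue]
    region_percent: dict[str, ReportValue]
    density_per_kb: ReportValue
    by_region_unit: dict[str, dict[int, int]]
    mono_counts: dict[str, int]
    mono_length_histogram: dict[int, int]


def ssr_summary(loci: Sequence[SSRLocus], partition: RegionPartition) -> SSRSummary:
    """Counts, per-region densities (per 100 kb) and the genome-wide density
    (per kb), with mononucleotide composition and length histogram.

    Densities are region count / region length, scaled, and rounded half-up
    at two decimals; raw values are retained inside each ReportValue.
    """
    if any(l.region == "unassigned" for l in loci):
        raise PlastomeError("loci must be region-assigned before summarising")
    total = len(loci)
    by_unit = {u: 0 for u in range(1, 7)}
    by_region = {r: 0 for r in RegionPartition.REGION_NAMES}
    by_region_unit = {r: {u: 0 for u in range(1, 7)} for r in RegionPartition.REGION_NAMES}
    mono_counts = {b: 0 for b in "ATCG"}
    mono_hist: Counter[int] = Counter()
    for l in loci:
        by_unit[l.unit_size] += 1
        by_region[l.region] += 1
        by_region_unit[l.region][l.unit_size] += 1
        if l.unit_size == 1:
            mono_counts[l.motif] += 1
            mono_hist[l.length] += 1
    densities = {}
    percents = {}
    for region, iv in partition.regions.items():
        length = len(iv)
        if length == 0:
            raise PlastomeError(f"zero-length region {region}")
        densities[region] = ReportValue(by_region[region] * 1e5 / length, 2, "per 100 kb")
        percents[region] = ReportValue(
            100.0 * by_region[region] / total if total else 0.0, 2, "%"
        )
    return SSRSummary(
        total=total,
        by_unit_size=by_unit,
        by_region=by_region,
        region_density_per_100kb=densities,
        region_percent=percents,
        density_per_kb=ReportValue(total * 1e3 / partition.total, 2, "per kb"),
        by_region_unit=by_region_unit,
        mono_counts=mono_counts,
        mono_length_histogram=dict(sorted(mono_hist.items())),
    )


def region_density_per_100kb(count: int, region_length: int) -> ReportValue:
    """SSR density for one region, per 100 kb, half-up at two decimals."""
    if region_length <= 0:
        raise PlastomeError("region length must be > 0")
    return ReportValue(count * 1e5 / region_length, 2, "per 100 kb")


def genome_density_per_kb(count: int, genome_length: int) -> ReportValue:
    if genome_length <= 0:
        raise PlastomeError("genome length must be > 0")
    return ReportValue(count * 1e3 / genome_length, 2, "per kb")


@dataclass(frozen=True)
class MonoComposition:
    counts: dict[str, int]
    percent_a: int
    percent_t: int
    ta_ratio: ReportValue


def mono_composition(loci: Sequence[SSRLocus]) -> MonoComposition:
    """A/T/C/G homopolymer counts, integer A/T percentages of the
    mononucleotide pool, and the T/A ratio at two decimals.

    The T/A ratio (T-homopolymer count over A-homopolymer count) is the
    compositional gradient statistic that separates growth forms in
    section *Euphorbia*; it is undefined when no A-homopolymer exists.
    """
    counts = {b: 0 for b in "ATCG"}
    for l in loci:
        if l.unit_size == 1:
            counts[l.motif] += 1
    n_mono = sum(counts.values())
    if n_mono == 0:
        raise PlastomeError("no mononucleotide SSRs")
    if counts["A"] == 0:
        raise PlastomeError("T/A ratio undefined: no A homopolymers")
    return MonoComposition(
        counts=counts,
        percent_a=int(round_half_up(100.0 * counts["A"] / n_mono, 0)),
        percent_t=int(round_half_up(100.0 * counts["T"] / n_mono, 0)),
        ta_ratio=ReportValue(counts["T"] / counts["A"], 2),
    )
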