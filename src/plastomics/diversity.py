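"""Nucleotide diversity (Pi) from multiple alignments.

Pi is the average proportion of differing sites over all unordered sequence
pairs.  The default site filter is *complete deletion*: any column holding a
gap or N in any row is excluded for every pair (the convention of
sliding-window diversity scans); pairwise deletion is available as an
option.  Windows are full-length only — the scan runs at the canonical
600 bp window / 200 bp step and drops a trailing partial window.

Per-gene Pi values are binned into four conservation classes with half-open
cuts at 0.012, 0.024 and 0.038, and summarised per quadripartite region
with the share of genes at Pi >= 0.024 ("variable or above") overall and
per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PlastomeError, ReportValue

CATEGORY_ORDER = ("highly_conserved", "conserved", "variable", "highly_variable")

#: Half-open class bounds: [0, .012) hc, [.012, .024) c, [.024, .038) v, [.038, inf) hv.
CLASS_BOUNDS = (0.012, 0.024, 0.038)

VARIABLE_CUTOFF = 0.024  # Pi at or above this counts as "variable or above"


@dataclass
class AlignedSet:
    """A multiple alignment: equal-length rows over {A,C,G,T,N,-}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise PlastomeError("taxa and rows must align")
        if len(set(self.taxa)) != len(self.taxa):
            raise PlastomeError("duplicate taxon labels")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PlastomeError(f"rows have unequal lengths {sorted(lengths)}")
        allowed = set("ACGTN-")
        for t, r in zip(self.taxa, self.rows):
            bad = set(r) - allowed
            if bad:
                raise PlastomeError(f"row {t}: illegal characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def columns(self, start: int, end: int) -> "AlignedSet":
        """Sub-alignment over 1-based inclusive column interval."""
        if not (1 <= start <= end <= self.length):
            raise PlastomeError(f"column interval [{start}, {end}] outside alignment")
        return AlignedSet(self.taxa, [r[start - 1 : end] for r in self.rows])

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(self.n, -1)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def read_aligned_fasta(path) -> AlignedSet:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise PlastomeError(f"no records in alignment {path}")
    return AlignedSet(taxa, rows)


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    """Columns free of gaps and N in every row (complete deletion)."""
    bad = (arr == b"-") | (arr == b"N")
    return ~bad.any(axis=0)


def nucleotide_diversity(aligned: AlignedSet, *, pairwise_deletion: bool = False) -> float:
    """Mean pairwise difference proportion (Pi).

    Complete deletion (default): columns with any gap/N are dropped for all
    pairs, and each pair contributes differences / shared valid length.
    Pairwise deletion: each pair is scored over the columns where neither of
    its two rows carries a gap/N.
    """
    if aligned.n < 2:
        raise PlastomeError("Pi requires at least two sequences")
    arr = aligned.to_array()
    pairs = list(combinations(range(aligned.n), 2))
    if pairwise_deletion:
        props = []
        for i, j in pairs:
            ok = ~((arr[i] == b"-") | (arr[i] == b"N") | (arr[j] == b"-") | (arr[j] == b"N"))
            if not ok.any():
                raise PlastomeError(f"no comparable columns for pair ({i}, {j})")
            props.append((arr[i][ok] != arr[j][ok]).mean())
        return float(np.mean(props))
    mask = _valid_mask(arr)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise PlastomeError("Pi undefined: no column free of gaps/N in all rows")
    sub = arr[:, mask]
    total_diffs = sum(int((sub[i] != sub[j]).sum()) for i, j in pairs)
    return total_diffs / (len(pairs) * n_valid)


@dataclass(frozen=True)
class DiversityWindow:
    start: int
    end: int
    pi: float
    valid_sites: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def sliding_pi(aligned: AlignedSet, window: int = 600, step: int = 200) -> list[DiversityWindow]:
    """Pi per full sliding window (start columns 1, 1+step, ...).

    Windows without any valid column get ``pi = nan`` rather than an error,
    so a scan over a gappy alignment stays contiguous.
    """
    if window <= 0 or step <= 0:
        raise PlastomeError("window and step must be positive")
    if aligned.length < window:
        raise PlastomeError(
            f"alignment of {aligned.length} columns shorter than window {window}"
        )
    arr = aligned.to_array()
    pairs = list(combinations(range(aligned.n), 2))
    mask = _valid_mask(arr)
    diff = np.zeros(aligned.length, dtype=np.int64)
    for i, j in pairs:
        diff += (arr[i] != arr[j]) & mask
    out = []
    start = 1
    while start + window - 1 <= aligned.length:
        sl = slice(start - 1, start + window - 1)
        n_valid = int(mask[sl].sum())
        if n_valid == 0:
            pi = float("nan")
        else:
            pi = float(diff[sl].sum()) / (len(pairs) * n_valid)
        out.append(DiversityWindow(start=start, end=start + window - 1,
                                   pi=pi, valid_sites=n_valid))
        start += step
    return out


def classify_diversity(pi: float) -> str:
    """Bin Pi into the four conservation classes (half-open intervals)."""
    if pi < 0:
        raise PlastomeError(f"negative Pi {pi}")
    for bound, category in zip(CLASS_BOUNDS, CATEGORY_ORDER):
        if pi < bound:
            return category
    return CATEGORY_ORDER[-1]


@dataclass(frozen=True)
class GeneDiversity:
    gene_id: str
    region: str  # LSC, SSC or IR
    pi: float

    @property
    def category(self) -> str:
        return classify_diversity(self.pi)


def gene_diversities(aligned: AlignedSet,
                     gene_columns: Mapping[str, tuple[int, int, str]]) -> list[GeneDiversity]:
    """Per-gene Pi over each gene's aligned column interval.

    *gene_columns* maps gene id -> (start_col, end_col, region).
    """
    out = []
    for gene_id, (start, end, region) in gene_columns.items():
        sub = aligned.columns(start, end)
        out.append(GeneDiversity(gene_id=gene_id, region=region,
                                 pi=nucleotide_diversity(sub)))
    return out


def regional_variability_summary(genes: Sequence[GeneDiversity]) -> dict:
    """Counts per (region x conservation class), class percentages of the
    total, and the share of genes at Pi >= 0.024 overall and per region
    (half-up, one decimal)."""
    if not genes:
        raise PlastomeError("no gene diversities supplied")
    regions = sorted({g.region for g in genes})
    counts = pd.DataFrame(0, index=list(CATEGORY_ORDER), columns=regions + ["Total"])
    for g in genes:
        counts.loc[g.category, g.region] += 1
        counts.loc[g.category, "Total"] += 1
    total = len(genes)
    percent_of_total = {
        cat: ReportValue(100.0 * counts.loc[cat, "Total"] / total, 1, "%")
        for cat in CATEGORY_ORDER
    }
    variable_or_above = {}
    n_var_total = sum(1 for g in genes if g.pi >= VARIABLE_CUTOFF)
    variable_or_above["Total"] = ReportValue(100.0 * n_var_total / total, 1, "%")
    for region in regions:
        in_region = [g for g in genes if g.region == region]
        n_var = sum(1 for g in in_region if g.pi >= VARIABLE_CUTOFF)
        variable_or_above[region] = ReportValue(100.0 * n_var / len(in_region), 1, "%")
    return {
        "counts": counts,
        "percent_of_total": percent_of_total,
        "variable_or_above_percent": variable_or_above,
        "n_genes": total,
    }
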