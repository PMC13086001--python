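"""Cross-species cpSSR compositional analysis.

Motif presence/absence across species is summarised four ways:

* a binary species x motif matrix (exact motif strings, no canonicalization);
* a per-motif *balance index* ``min(n_present, n_absent) / n_species`` — a
  motif splitting the species set in half (index 0.5) is maximally
  informative for clustering, a universal or unique motif (index near 0)
  carries little signal;
* Sørensen (Dice) dissimilarities between species motif repertoires,
  clustered with Ward's minimum-variance criterion in its squared-input
  (Ward.D2) form;
* a Mantel permutation test of the SSR-based distances against any
  user-supplied comparator matrix (e.g. patristic distances).

Heights in the dendrogram are reported on the unsquared dissimilarity scale
(square root of the Ward.D2 criterion), the convention of R's
``hclust(..., method = "ward.D2")``.  Tie-breaking is deterministic: among
equally close pairs the one whose smallest leaf labels sort first is merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PlastomeError
from .ssr import SSRLocus


@dataclass
class MotifMatrix:
    """Binary presence/absence of exact motif strings per species."""

    data: pd.DataFrame  # species rows x motif columns, values in {0, 1}

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise PlastomeError("duplicate species or motif labels")
        if not self.data.isin([0, 1]).all().all():
            raise PlastomeError("matrix cells must be 0/1")
        if (self.data.sum(axis=0) == 0).any():
            raise PlastomeError("every motif must be present in at least one species")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.data.columns)

    def presence_set(self, species: str) -> frozenset[str]:
        row = self.data.loc[species]
        return frozenset(row.index[row == 1])


def build_motif_matrix(per_species_loci: Mapping[str, Sequence[SSRLocus | str]]) -> MotifMatrix:
    """Encode motif presence per species as a binary matrix.

    Accepts per-species lists of :class:`SSRLocus` or raw motif strings; the
    motif universe is the union over species, ordered by first appearance.
    """
    if len(per_species_loci) < 2:
        raise PlastomeError("motif matrix requires at least two species")
    repertoire: dict[str, set[str]] = {}
    motif_order: list[str] = []
    for species, loci in per_species_loci.items():
        motifs = {l.motif if isinstance(l, SSRLocus) else str(l).upper() for l in loci}
        repertoire[species] = motifs
        for m in sorted(motifs):
            if m not in motif_order:
                motif_order.append(m)
    data = pd.DataFrame(
        [[int(m in repertoire[s]) for m in motif_order] for s in per_species_loci],
        index=list(per_species_loci),
        columns=motif_order,
        dtype=int,
    )
    return MotifMatrix(data)


def balance_index(matrix: MotifMatrix, motif: str) -> float:
    """``min(n_present, n_absent) / n_species`` for one motif column.

    Ranges over [0, 0.5]; 0.5 means the motif bisects the species set.
    Symmetric under complementing the column.
    """
    if motif not in matrix.data.columns:
        raise PlastomeError(f"unknown motif {motif!r}")
    n = len(matrix.species)
    present = int(matrix.data[motif].sum())
    return min(present, n - present) / n


def balance_table(matrix: MotifMatrix) -> pd.DataFrame:
    """All motifs with presence/absence counts and balance index, sorted
    descending by index (most informative first)."""
    rows = []
    n = len(matrix.species)
    for motif in matrix.motifs:
        present = int(matrix.data[motif].sum())
        rows.append(
            {"motif": motif, "present": present, "absent": n - present,
             "balance_index": min(present, n - present) / n}
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["balance_index", "motif"], ascending=[False, True])
        .reset_index(drop=True)
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise PlastomeError("distance matrix must be square and match labels")
        if not np.allclose(v, v.T):
            raise PlastomeError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise PlastomeError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise PlastomeError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_phylip(self) -> str:
        lines = [f"{self.n}"]
        for label, row in zip(self.labels, self.values):
            lines.append(label + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def sorensen_dissimilarity(matrix: MotifMatrix) -> DistanceMatrix:
    """Pairwise Sørensen dissimilarity ``1 - 2|Pi & Pj| / (|Pi| + |Pj|)``
    between species motif presence sets."""
    sets = {s: matrix.presence_set(s) for s in matrix.species}
    empty = [s for s, p in sets.items() if not p]
    if empty:
        raise PlastomeError(f"species with empty motif repertoire: {empty}")
    n = len(matrix.species)
    d = np.zeros((n, n))
    for i, si in enumerate(matrix.species):
        for j in range(i + 1, n):
            sj = matrix.species[j]
            inter = len(sets[si] & sets[sj])
            d[i, j] = d[j, i] = 1.0 - 2.0 * inter / (len(sets[si]) + len(sets[sj]))
    return DistanceMatrix(labels=matrix.species, values=d)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: (n-1) merges of cluster indices.

    Clusters 0..n-1 are leaves (in ``leaf_labels`` order); merge k creates
    cluster n+k.  Heights are on the unsquared dissimilarity scale.
    """

    merges: list[tuple[int, int, float]]
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaf_labels) - 1:
            raise PlastomeError("a dendrogram over n leaves needs n-1 merges")

    def to_newick(self) -> str:
        n = len(self.leaf_labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6f},{node[b]}:{lb:.6f})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        n = len(self.leaf_labels)
        sets = {i: frozenset([self.leaf_labels[i]]) for i in range(n)}
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets


def ward_cluster(dmatrix: DistanceMatrix) -> Dendrogram:
    """Ward.D2 agglomerative clustering.

    The Lance-Williams recurrence is applied to *squared* dissimilarities
    (the D2 variant); merge heights are the square roots of the criterion.
    Among equally close pairs the pair whose member clusters contain the
    lexicographically smallest leaf labels is merged first.
    """
    if dmatrix.n < 2:
        raise PlastomeError("clustering requires at least two items")
    if np.isnan(dmatrix.values).any():
        raise PlastomeError("NaN in distance matrix")
    n = dmatrix.n
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dmatrix.values[i, j] ** 2
    sizes = {i: 1 for i in range(n)}
    # representative label tuple for deterministic tie-breaking
    rep = {i: (dmatrix.labels[i],) for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), v in d2.items():
            key = (v, tuple(sorted((min(rep[i]), min(rep[j])))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h2 = d2[(i, j)]
        new = next_id
        next_id += 1
        merges.append((i, j, float(np.sqrt(h2))))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * h2) / (ni + nj + nk)
            d2[(k, new)] = dnew
        active.discard(i)
        active.discard(j)
        d2 = {pair: v for pair, v in d2.items() if i not in pair and j not in pair}
        active.add(new)
        sizes[new] = ni + nj
        rep[new] = tuple(sorted(rep[i] + rep[j]))
    return Dendrogram(merges=merges, leaf_labels=list(dmatrix.labels))


@dataclass(frozen=True)
class MantelResult:
    r_observed: float
    n_permutations: int
    p_value: float
    seed: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise PlastomeError("zero variance in distance triangle")
    return float((xc * yc).sum() / (sx * sy))


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_permutations: int = 999,
           seed: int | None = None) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    Pearson correlation over the upper triangles; the null distribution is
    generated by jointly permuting rows and columns of *d2*; the p-value
    carries the +1 correction ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if d1.labels != d2.labels:
        raise PlastomeError("distance matrices must share labels and order")
    if d1.n < 4:
        raise PlastomeError("Mantel test requires n >= 4")
    if seed is None:
        raise PlastomeError("Mantel permutation test requires an explicit seed")
    iu = np.triu_indices(d1.n, k=1)
    x = d1.values[iu]
    r_obs = _pearson(x, d2.values[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(d1.n)
        r = _pearson(x, d2.values[np.ix_(perm, perm)][iu])
        if r >= r_obs:
            count += 1
    return MantelResult(
        r_observed=r_obs,
        n_permutations=n_permutations,
        p_value=(1 + count) / (1 + n_permutations),
        seed=seed,
    )


def count_density_correlation(counts: Sequence[float], genome_lengths: Sequence[float]) -> float:
    """Pearson correlation between per-species total SSR count and SSR
    density (count per kb of genome)."""
    if len(counts) != len(genome_lengths):
        raise PlastomeError("counts and genome lengths must align")
    if len(counts) < 3:
        raise PlastomeError("correlation requires at least three species")
    c = np.asarray(counts, dtype=float)
    g = np.asarray(genome_lengths, dtype=float)
    density = c / (g / 1000.0)
    return _pearson(c, density)
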