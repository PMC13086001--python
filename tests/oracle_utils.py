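"""Independent brute-force oracles used to validate the fast implementations.

Each oracle recomputes a quantity from first principles (exhaustive
enumeration or closed form) without sharing code paths with the package.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np

_ACGT = set("ACGT")


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> list[tuple]:
    """Test every (start, unit_size) pair for a threshold-qualifying,
    left-maximal, primitive-motif perfect repeat run (truncated to whole
    units).  Returns (motif, unit, repeats, start_1based, end_1based)."""
    seq = seq.upper()
    n = len(seq)
    found = []
    for i in range(n):
        for u in range(1, 7):
            motif = seq[i : i + u]
            if len(motif) < u or not _ACGT.issuperset(motif) or not _primitive(motif):
                continue
            # left-maximality at character level: the base immediately left
            # must not continue the period (one run = one SSR, leftmost start)
            if i > 0 and seq[i - 1] in _ACGT and seq[i - 1] == seq[i - 1 + u]:
                continue
            r = 1
            while seq[i + r * u : i + (r + 1) * u] == motif:
                r += 1
            if r >= thresholds[u]:
                found.append((motif, u, r, i + 1, i + r * u))
    return sorted(found, key=lambda t: (t[3], t[1]))


def ward_d2_closed_form(d: np.ndarray, labels: list[str]):
    """Greedy Ward.D2 merges via the closed-form criterion.

    Treating the dissimilarities as Euclidean distances, the Ward.D2
    inter-cluster criterion is ``2 |A||B| / (|A|+|B|) * ||mA - mB||^2``
    where the squared centroid gap comes directly from the original
    pairwise squared distances:

        ||mA - mB||^2 = mean_{a in A, b in B} d(a,b)^2
                        - mean_within(A)/2 - mean_within(B)/2

    with ``mean_within(X) = (1/|X|^2) sum_{x,x'} d(x,x')^2``.  No
    Lance-Williams recursion is involved, so this is an independent check
    of the recursive implementation.  Ties broken by smallest leaf labels.
    """
    n = len(labels)
    d2 = np.asarray(d, dtype=float) ** 2

    def centroid_gap2(A: tuple[int, ...], B: tuple[int, ...]) -> float:
        cross = np.mean([d2[a, b] for a in A for b in B])
        wA = np.sum([d2[a, a2] for a in A for a2 in A]) / (len(A) ** 2)
        wB = np.sum([d2[b, b2] for b in B for b2 in B]) / (len(B) ** 2)
        return cross - wA / 2 - wB / 2

    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for A, B in combinations(clusters, 2):
            crit = 2 * len(A) * len(B) / (len(A) + len(B)) * centroid_gap2(A, B)
            key = (crit, tuple(sorted((min(labels[i] for i in A),
                                       min(labels[i] for i in B)))))
            if best is None or key < best[0]:
                best = (key, A, B)
        _, A, B = best
        merges.append((frozenset(labels[i] for i in A) | frozenset(labels[i] for i in B),
                       float(np.sqrt(max(best[0][0], 0.0)))))
        clusters.remove(A)
        clusters.remove(B)
        clusters.append(tuple(sorted(A + B)))
    return merges


def exact_mantel_p(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Exhaustive Mantel: r_obs and the exact one-sided p over all n!
    joint row/column permutations of d2 (identity included)."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]

    def r(y: np.ndarray) -> float:
        xc, yc = x - x.mean(), y - y.mean()
        return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))

    r_obs = r(d2[iu])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        total += 1
        if r(d2[np.ix_(p, p)][iu]) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


def pairwise_pi(rows: list[str]) -> float:
    """Complete-deletion Pi by explicit pair loops."""
    cols = [c for c in zip(*rows) if all(b in _ACGT for b in c)]
    pairs = list(combinations(range(len(rows)), 2))
    if not cols:
        raise ValueError("no valid columns")
    total = 0
    for i, j in pairs:
        total += sum(1 for c in cols if c[i] != c[j])
    return total / (len(pairs) * len(cols))
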