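import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

import plastomics as p
from plastomics.compare import balance_table

from oracle_utils import exact_mantel_p, ward_d2_closed_form


def _matrix(rows: dict[str, list[str]]) -> p.MotifMatrix:
    return p.build_motif_matrix(rows)


class TestMotifMatrix:
    def test_identical_repertoires_identical_rows(self):
        m = _matrix({"s1": ["A", "AT"], "s2": ["A", "AT"]})
        assert (m.data.loc["s1"] == m.data.loc["s2"]).all()

    def test_union_universe_and_pattern(self):
        m = _matrix({"s1": ["A", "AT"], "s2": ["A", "TTA"]})
        assert sorted(m.motifs) == ["A", "AT", "TTA"]
        assert m.data.loc["s1", "AT"] == 1 and m.data.loc["s2", "AT"] == 0
        assert m.data.loc["s2", "TTA"] == 1 and m.data.loc["s1", "TTA"] == 0

    def test_single_species_rejected(self):
        with pytest.raises(p.PlastomeError):
            _matrix({"s1": ["A"]})

    def test_planted_repertoires_recovered(self):
        rng = np.random.default_rng(3)
        motifs = ["A", "T", "AT", "TA", "TTA", "AAT", "ATTT"]
        design = {f"sp{i}": sorted(rng.choice(motifs,
                                              size=rng.integers(1, len(motifs)),
                                              replace=False))
                  for i in range(10)}
        m = _matrix(design)
        for sp, reps in design.items():
            assert m.presence_set(sp) == frozenset(reps)


class TestBalanceIndex:
    def _ten_species(self, present: int) -> p.MotifMatrix:
        rows = {f"sp{i}": ["A"] + (["TTA"] if i < present else [])
                for i in range(10)}
        return _matrix(rows)

    @pytest.mark.parametrize("present,expected", [(5, 0.5), (7, 0.3), (10, 0.0)])
    def test_presence_counts(self, present, expected):
        assert p.balance_index(self._ten_species(present), "TTA" if present < 10 else "A") \
            == pytest.approx(expected)

    def test_unknown_motif_rejected(self):
        with pytest.raises(p.PlastomeError):
            p.balance_index(self._ten_species(5), "GGG")

    @given(present=st.integers(1, 9))
    @settings(derandomize=True, deadline=None)
    def test_complement_symmetry(self, present):
        m = self._ten_species(present)
        assert p.balance_index(m, "TTA") == pytest.approx(
            min(present, 10 - present) / 10)

    def test_table_sorted_descending(self):
        m = self._ten_species(5)
        t = balance_table(m)
        assert list(t["balance_index"]) == sorted(t["balance_index"], reverse=True)


class TestSorensen:
    def test_identical_and_disjoint(self):
        m = _matrix({"a": ["A", "AT"], "b": ["A", "AT"], "c": ["TTA", "CTA"]})
        d = p.sorensen_dissimilarity(m)
        i, j, k = (d.labels.index(x) for x in "abc")
        assert d.values[i, j] == 0.0
        assert d.values[i, k] == 1.0

    def test_hand_computed_overlap(self):
        # |Pi| = 3, |Pj| = 5, overlap 2 -> 1 - 4/8 = 0.5
        m = _matrix({"a": ["A", "T", "AT"],
                     "b": ["A", "T", "TA", "TTA", "CTA"]})
        d = p.sorensen_dissimilarity(m)
        assert d.values[0, 1] == pytest.approx(0.5)

    @given(st.integers(0, 2 ** 18 - 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_metric_axioms_on_random_matrices(self, bits):
        cells = [(bits >> k) & 1 for k in range(18)]
        data = pd.DataFrame(np.array(cells).reshape(3, 6),
                            index=["a", "b", "c"],
                            columns=["m1", "m2", "m3", "m4", "m5", "m6"])
        data = data.loc[:, data.sum(axis=0) > 0]
        if data.shape[1] == 0 or (data.sum(axis=1) == 0).any():
            return
        d = p.sorensen_dissimilarity(p.MotifMatrix(data))
        v = d.values
        assert np.allclose(np.diag(v), 0)
        assert np.allclose(v, v.T)
        assert ((v >= 0) & (v <= 1)).all()

    def test_matches_scipy_dice(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.integers(0, 2, size=(6, 12)),
                            index=[f"s{i}" for i in range(6)])
        data.iloc[:, 0] = 1  # no empty repertoires / motifs
        data = data.loc[:, data.sum(axis=0) > 0]
        d = p.sorensen_dissimilarity(p.MotifMatrix(data))
        expected = squareform(pdist(data.to_numpy(dtype=bool), metric="dice"))
        assert np.allclose(d.values, expected)


class TestWardClustering:
    def test_two_items_merge_at_their_distance(self):
        d = p.DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        tree = p.ward_cluster(d)
        assert tree.merges == [(0, 1, pytest.approx(0.4))]

    def test_matches_closed_form_oracle_n4(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.random((4, 3))
            dm = squareform(pdist(pts))
            labels = ["a", "b", "c", "d"]
            tree = p.ward_cluster(p.DistanceMatrix(labels, dm))
            oracle = ward_d2_closed_form(dm, labels)
            sets = tree.leaf_sets()
            got = [(sets[4 + k], h) for k, (_, _, h) in enumerate(tree.merges)]
            for (gs, gh), (os_, oh) in zip(got, oracle):
                assert gs == os_
                assert gh == pytest.approx(oh, abs=1e-9)

    def test_matches_scipy_heights(self):
        rng = np.random.default_rng(8)
        pts = rng.random((7, 4))
        y = pdist(pts)
        tree = p.ward_cluster(p.DistanceMatrix([f"s{i}" for i in range(7)],
                                               squareform(y)))
        Z = linkage(y, "ward")
        assert np.allclose([h for *_, h in tree.merges], Z[:, 2])

    def test_two_block_structure_recovered(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.full((6, 6), 0.9)
        for i in range(3):
            for j in range(3):
                d[i, j] = d[i + 3, j + 3] = 0.1
        np.fill_diagonal(d, 0)
        tree = p.ward_cluster(p.DistanceMatrix(labels, d))
        sets = tree.leaf_sets()
        blocks = {frozenset(["a1", "a2", "a3"]), frozenset(["b1", "b2", "b3"])}
        assert blocks <= set(sets.values())

    def test_ultrametric_input_reproduced(self):
        # heights non-decreasing and topology of a perfect ultrametric kept
        labels = ["a", "b", "c", "d"]
        d = np.array([[0, .2, .8, .8],
                      [.2, 0, .8, .8],
                      [.8, .8, 0, .4],
                      [.8, .8, .4, 0]])
        tree = p.ward_cluster(p.DistanceMatrix(labels, d))
        sets = tree.leaf_sets()
        assert frozenset(["a", "b"]) in sets.values()
        assert frozenset(["c", "d"]) in sets.values()
        heights = [h for *_, h in tree.merges]
        assert heights == sorted(heights)

    def test_newick_contains_all_leaves(self):
        d = p.DistanceMatrix(["x", "y", "z"],
                             np.array([[0, .1, .5], [.1, 0, .5], [.5, .5, 0]]))
        nwk = p.ward_cluster(d).to_newick()
        assert nwk.endswith(";") and all(l in nwk for l in "xyz")


class TestMantel:
    def _random_dm(self, rng, n=4):
        pts = rng.random((n, 3))
        return p.DistanceMatrix([f"s{i}" for i in range(n)],
                                squareform(pdist(pts)))

    def test_self_comparison_r_one(self):
        d = self._random_dm(np.random.default_rng(0))
        res = p.mantel(d, d, seed=1)
        assert res.r_observed == pytest.approx(1.0)

    def test_affine_invariance(self):
        d = self._random_dm(np.random.default_rng(2))
        d2 = p.DistanceMatrix(d.labels, 3.0 * d.values + (1 - np.eye(d.n)) * 0.2)
        res = p.mantel(d, d2, seed=3)
        assert res.r_observed == pytest.approx(1.0)

    def test_p_value_on_permutation_grid(self):
        # with the +1 correction p lies on {1/(B+1), ..., 1} and never at 0
        d = self._random_dm(np.random.default_rng(4))
        res = p.mantel(d, d, n_permutations=99, seed=5)
        assert 1 / 100 <= res.p_value <= 1
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_sampled_p_within_binomial_bounds_of_exact(self, seed):
        rng = np.random.default_rng(seed)
        d1 = self._random_dm(rng)
        d2 = self._random_dm(rng)
        _r, exact = exact_mantel_p(d1.values, d2.values)
        res = p.mantel(d1, d2, n_permutations=999, seed=seed)
        se = np.sqrt(exact * (1 - exact) / 999)
        assert abs(res.p_value - exact) <= 2.58 * se + 2 / 1000

    def test_label_mismatch_rejected(self):
        d1 = self._random_dm(np.random.default_rng(6))
        d2 = p.DistanceMatrix(list("wxyz"), d1.values)
        with pytest.raises(p.PlastomeError):
            p.mantel(d1, d2, seed=1)

    def test_missing_seed_rejected(self):
        d = self._random_dm(np.random.default_rng(7))
        with pytest.raises(p.PlastomeError, match="seed"):
            p.mantel(d, d)

    def test_matches_skbio_r_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(13)
        d1 = self._random_dm(rng, n=6)
        d2 = self._random_dm(rng, n=6)
        r_skbio, _p, _n = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, d1.labels),
            skbio_distance.DistanceMatrix(d2.values, d2.labels),
            method="pearson", permutations=0, alternative="greater")
        res = p.mantel(d1, d2, n_permutations=9, seed=0)
        assert res.r_observed == pytest.approx(r_skbio)


class TestCountDensityCorrelation:
    def test_equal_lengths_give_r_one(self):
        assert p.count_density_correlation([10, 20, 30], [1e5, 1e5, 1e5]) \
            == pytest.approx(1.0)

    def test_two_species_degenerate(self):
        with pytest.raises(p.PlastomeError):
            p.count_density_correlation([10, 20], [1e5, 2e5])

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(60, 140, size=10).astype(float)
        lengths = rng.uniform(1.4e5, 1.8e5, size=10)
        got = p.count_density_correlation(counts, lengths)
        dens = counts / (lengths / 1000)
        expected = np.corrcoef(counts, dens)[0, 1]
        assert got == pytest.approx(expected, abs=1e-6)
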