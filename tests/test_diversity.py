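import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plastomics as p
from plastomics.diversity import AlignedSet

from oracle_utils import pairwise_pi


def _aln(*rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return AlignedSet(list(taxa), list(rows))


class TestNucleotideDiversity:
    def test_identical_rows(self):
        assert p.nucleotide_diversity(_aln("ACGT" * 25, "ACGT" * 25)) == 0.0

    def test_single_difference_over_100(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert p.nucleotide_diversity(_aln(a, b)) == pytest.approx(0.01)

    def test_three_rows_pairwise_differences_1_2_3(self):
        # d(r1,r2)=1, d(r2,r3)=2, d(r1,r3)=3 over 100 columns
        # -> pi = (0.01 + 0.02 + 0.03) / 3 = 0.02
        r1 = "A" * 100
        r2 = "C" + "A" * 99
        r3 = "CCG" + "A" * 97
        rows = [r1, r2, r3]
        assert p.nucleotide_diversity(_aln(*rows)) == pytest.approx(0.02)
        assert p.nucleotide_diversity(_aln(*rows)) == pytest.approx(pairwise_pi(rows))

    def test_complete_deletion_drops_gap_columns_for_all_pairs(self):
        a = "AAAA-A"
        b = "AAAACA"
        c = "AATACA"
        # column 5 (gap in a) removed for everyone; valid columns: 1,2,3,4,6
        pi = p.nucleotide_diversity(_aln(a, b, c))
        assert pi == pytest.approx(pairwise_pi([a, b, c]))

    def test_pairwise_deletion_option(self):
        a = "AAAA-A"
        b = "AAAACA"
        got = p.nucleotide_diversity(_aln(a, b), pairwise_deletion=True)
        assert got == pytest.approx(0.0)

    def test_no_valid_columns_is_error(self):
        with pytest.raises(p.PlastomeError):
            p.nucleotide_diversity(_aln("A-", "-A"))

    @given(st.permutations(range(4)))
    @settings(derandomize=True, deadline=None)
    def test_invariant_under_row_reordering(self, order):
        rows = ["ACGTACGTAA", "ACGTACGTAC", "ACCTACGTAA", "TCGTACGAAA"]
        base = p.nucleotide_diversity(_aln(*rows))
        shuffled = [rows[i] for i in order]
        assert p.nucleotide_diversity(_aln(*shuffled)) == pytest.approx(base)

    def test_invariant_under_all_gap_column_removal(self):
        rows = ["ACGTACGTAA", "ACGTACGTAC", "ACCTACGTAA"]
        padded = [r[:4] + "-" + r[4:] for r in rows]
        # one all-gap column is malformed for indel calling but legal here:
        # complete deletion removes it, so Pi is unchanged
        assert p.nucleotide_diversity(_aln(*padded)) == \
            pytest.approx(p.nucleotide_diversity(_aln(*rows)))

    def test_duplicating_every_row_keeps_mean_pairwise_pi_scale(self):
        rows = ["ACGTACGTAA", "ACGTACGTAC", "ACCTACGTAA"]
        doubled = rows + rows
        taxa = [f"t{i}" for i in range(6)]
        got = p.nucleotide_diversity(_aln(*doubled, taxa=taxa))
        assert got == pytest.approx(pairwise_pi(doubled))


class TestSlidingWindows:
    def test_window_arithmetic(self):
        aln = _aln("A" * 1000, "A" * 1000)
        windows = p.sliding_pi(aln, window=600, step=200)
        assert [(w.start, w.end) for w in windows] == \
            [(1, 600), (201, 800), (401, 1000)]

    def test_constant_alignment_all_zero(self):
        aln = _aln("ACGT" * 300, "ACGT" * 300)
        assert all(w.pi == 0.0 for w in p.sliding_pi(aln))

    def test_variable_block_found_at_argmax_and_values_match_oracle(self):
        rng = np.random.default_rng(5)
        spec = p.AlignmentSpec(
            taxa=["t1", "t2", "t3", "t4"], length=2000, theta=0.0, seed=9,
            snps=[p.PlantedSNP(900 + 7 * k, "A", "T", frozenset(["t1", "t2"]))
                  for k in range(12)],
        )
        aligned, _ = p.synth_alignment(spec)
        windows = p.sliding_pi(aligned, window=600, step=200)
        best = max(windows, key=lambda w: w.pi)
        assert best.start <= 983 and best.end >= 900  # overlaps planted block
        for w in windows:
            sub = [r[w.start - 1 : w.end] for r in aligned.rows]
            assert w.pi == pytest.approx(pairwise_pi(sub))

    def test_short_alignment_rejected(self):
        with pytest.raises(p.PlastomeError):
            p.sliding_pi(_aln("ACGT", "ACGT"), window=600, step=200)

    def test_disjoint_windows_tile_difference_counts(self):
        rng = np.random.default_rng(31)
        spec = p.AlignmentSpec(taxa=["a", "b", "c"], length=1200,
                               theta=0.05, seed=31)
        aligned, _ = p.synth_alignment(spec)
        tiles = p.sliding_pi(aligned, window=300, step=300)
        whole = p.nucleotide_diversity(aligned)
        stitched = sum(w.pi * w.valid_sites for w in tiles) / \
            sum(w.valid_sites for w in tiles)
        assert stitched == pytest.approx(whole)


class TestClassification:
    @pytest.mark.parametrize("pi,category", [
        (0.000, "highly_conserved"),
        (0.009, "highly_conserved"),
        (0.0119, "highly_conserved"),
        (0.012, "conserved"),
        (0.0239, "conserved"),
        (0.024, "variable"),
        (0.034, "variable"),
        (0.0379, "variable"),
        (0.038, "highly_variable"),
        (0.057, "highly_variable"),
        (0.081, "highly_variable"),
    ])
    def test_half_open_class_bounds(self, pi, category):
        assert p.classify_diversity(pi) == category

    def test_negative_pi_rejected(self):
        with pytest.raises(p.PlastomeError):
            p.classify_diversity(-0.001)


class TestRegionalSummary:
    @staticmethod
    def _genes(counts: dict[str, dict[str, int]]):
        # counts: region -> category -> n; representative Pi per category
        rep = {"highly_conserved": 0.005, "conserved": 0.018,
               "variable": 0.03, "highly_variable": 0.05}
        genes = []
        i = 0
        for region, cats in counts.items():
            for cat, n in cats.items():
                for _ in range(n):
                    genes.append(p.GeneDiversity(f"g{i}", region, rep[cat]))
                    i += 1
        return genes

    def test_published_gene_category_distribution(self):
        # 129 genes: LSC 81 (29 hv, 30 v, 16 c, 6 hc), SSC 12 hc,
        # IR 36 (4 hv, 2 v, 16 c, 14 hc)
        genes = self._genes({
            "LSC": {"highly_variable": 29, "variable": 30,
                    "conserved": 16, "highly_conserved": 6},
            "SSC": {"highly_conserved": 12},
            "IR": {"highly_variable": 4, "variable": 2,
                   "conserved": 16, "highly_conserved": 14},
        })
        summary = p.regional_variability_summary(genes)
        assert summary["n_genes"] == 129
        assert summary["variable_or_above_percent"]["Total"].rounded == 50.4
        assert summary["variable_or_above_percent"]["LSC"].rounded == 72.8
        assert summary["variable_or_above_percent"]["SSC"].rounded == 0.0
        assert summary["percent_of_total"]["highly_variable"].rounded == 25.6
        counts = summary["counts"]
        assert counts.loc["highly_variable", "Total"] == 33
        assert counts.loc["variable", "Total"] == 32

    def test_single_category_rows(self):
        genes = self._genes({"LSC": {"conserved": 5}})
        summary = p.regional_variability_summary(genes)
        assert summary["percent_of_total"]["conserved"].rounded == 100.0
        assert summary["variable_or_above_percent"]["Total"].rounded == 0.0

    def test_empty_rejected(self):
        with pytest.raises(p.PlastomeError):
            p.regional_variability_summary([])


class TestParameterRecovery:
    def test_mean_pi_matches_planted_theta_moment(self):
        theta = 0.02
        expected = p.expected_background_diversity(theta)
        pis = []
        for seed in range(200):
            spec = p.AlignmentSpec(taxa=["a", "b"], length=2000,
                                   theta=theta, seed=seed)
            aligned, _ = p.synth_alignment(spec)
            pis.append(p.nucleotide_diversity(aligned))
        mean = np.mean(pis)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean - expected) < 3 * se
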