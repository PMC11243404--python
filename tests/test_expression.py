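"""Normalization, gland combining, variance tests and the correlation network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regnet.expression import (
    NormalizedMatrix,
    benjamini_hochberg,
    combine_glands,
    expression_variance,
    gene_trait_significance,
    normalize,
    size_factors_median_of_ratios,
    tf_venom_correlation,
    variance_group_test,
)
from regnet.types import GlandSide, SampleMeta


def _meta(sample_id, side, individual):
    return SampleMeta(sample_id, "viridis", "south", GlandSide(side), individual)


class TestCombineGlands:
    def test_left_plus_right_sums_raw_counts(self):
        counts = pd.DataFrame({"i1_L": [10, 0], "i1_R": [5, 7]},
                              index=["g1", "g2"]).astype(np.int64)
        meta = [_meta("i1_L", "left", "i1"), _meta("i1_R", "right", "i1")]
        out, new_meta = combine_glands(counts, meta)
        assert out["i1"].tolist() == [15, 7]
        assert new_meta[0].gland_side == GlandSide.COMBINED

    def test_single_gland_passes_through(self):
        counts = pd.DataFrame({"i1_R": [3, 4]}, index=["g1", "g2"]).astype(np.int64)
        out, new_meta = combine_glands(counts, [_meta("i1_R", "right", "i1")])
        assert out["i1"].tolist() == [3, 4]
        assert new_meta[0].gland_side == GlandSide.RIGHT

    def test_duplicate_side_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g"]).astype(np.int64)
        meta = [_meta("a", "left", "i1"), _meta("b", "left", "i1")]
        with pytest.raises(ValueError, match="duplicate gland side"):
            combine_glands(counts, meta)


class TestSizeFactors:
    def test_hand_computed_two_sample_example(self):
        # geometric-mean reference per gene, median ratio per sample
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]}).astype(np.int64)
        sf = size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(sf.to_numpy(), [0.7071, 1.4142], atol=1e-4)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9], "B": [5, 9], "C": [5, 9]}).astype(np.int64)
        assert np.allclose(size_factors_median_of_ratios(counts), 1.0)

    def test_single_sample_gives_unit_factor(self):
        counts = pd.DataFrame({"A": [5, 9]}).astype(np.int64)
        assert size_factors_median_of_ratios(counts).tolist() == [1.0]

    def test_scaled_copies_recover_scaling(self, rng):
        base = rng.integers(1, 1000, size=50)
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame({f"s{i}": np.round(base * c).astype(np.int64)
                               for i, c in enumerate(scales)})
        sf = size_factors_median_of_ratios(counts).to_numpy()
        ratio = sf / scales
        np.testing.assert_allclose(ratio, ratio[0], rtol=0.02)

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"A": [0, 3], "B": [2, 0]}).astype(np.int64)
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors_median_of_ratios(counts)
        norm = normalize(counts, allow_pseudo_reference=True)
        assert (norm.size_factors > 0).all()

    def test_agrees_with_deseq2_reference_implementation(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = pd.DataFrame(rng.negative_binomial(10, 0.05, (200, 6)) + 1)
        ours = size_factors_median_of_ratios(counts).to_numpy()
        _, theirs = pydeseq2.deseq2_norm(counts.T)
        np.testing.assert_allclose(ours, np.asarray(theirs).ravel(), rtol=1e-8)


class TestVariance:
    def _norm(self, arr):
        df = pd.DataFrame(arr, dtype=float)
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        return NormalizedMatrix(df, pd.Series(1.0, index=df.columns), "log2p1")

    def test_constant_gene_zero_and_closed_form(self):
        v = expression_variance(self._norm([[3, 3, 3], [0, 2, 1]]))
        assert v.iloc[0] == 0.0
        v2 = expression_variance(self._norm([[0.0, 2.0]]))
        assert v2.iloc[0] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        arr = rng.normal(size=(4, 6))
        norm = self._norm(arr)
        perm = self._norm(arr[:, ::-1])
        np.testing.assert_allclose(expression_variance(norm), expression_variance(perm))

    def test_subset_too_small(self):
        with pytest.raises(ValueError):
            expression_variance(self._norm([[1.0, 2.0]]), samples=["s0"])


class TestVarianceGroupTest:
    def test_identical_groups(self):
        t, p = variance_group_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(10, 1, 20)
        b = rng.normal(0, 1, 20)
        t, p = variance_group_test(a, b)
        # cross-check against an independent t-CDF evaluation (Welch df)
        va, vb = a.var(ddof=1) / 20, b.var(ddof=1) / 20
        df = (va + vb) ** 2 / (va**2 / 19 + vb**2 / 19)
        p_ref = 2 * stats.t.sf(abs((a.mean() - b.mean()) / np.sqrt(va + vb)), df)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert p < 0.01

    def test_swap_negates_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        t1, p1 = variance_group_test(a, b)
        t2, p2 = variance_group_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestGeneTraitSignificance:
    def _norm(self, arr, cols):
        df = pd.DataFrame(arr, columns=cols, dtype=float)
        return NormalizedMatrix(df, pd.Series(1.0, index=cols), "log2p1")

    def test_perfect_and_anticorrelated_genes(self):
        cols = list("abcd")
        trait = pd.Series([0, 0, 1, 1], index=cols, dtype=float)
        norm = self._norm([[0, 0, 1, 1], [1, 1, 0, 0], [5, 5, 5, 5]], cols)
        r = gene_trait_significance(norm, trait)
        assert r.iloc[0] == pytest.approx(1.0)
        assert r.iloc[1] == pytest.approx(1.0)  # absolute value
        assert r.iloc[2] == 0.0  # constant gene

    def test_independent_gene_near_zero(self, rng):
        n = 2000
        cols = [f"s{i}" for i in range(n)]
        trait = pd.Series(rng.integers(0, 2, n).astype(float), index=cols)
        norm = self._norm(rng.normal(size=(1, n)), cols)
        r = gene_trait_significance(norm, trait).iloc[0]
        # |r| of independent data: mean ~ sqrt(2/(pi n)), keep within 3 SE
        assert r < np.sqrt(2 / (np.pi * n)) + 3 / np.sqrt(n)


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert benjamini_hochberg([0.3]).tolist() == [0.3]
        assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestTfVenomCorrelation:
    def _norm(self, df):
        return NormalizedMatrix(df, pd.Series(1.0, index=df.columns), "log2p1")

    def test_identical_pair_significant(self, rng):
        cols = [f"s{i}" for i in range(8)]
        x = rng.normal(size=8)
        df = pd.DataFrame([x, x, rng.normal(size=8)],
                          index=["TF1", "VEN1", "VEN2"], columns=cols)
        res = tf_venom_correlation(self._norm(df), ["TF1"], ["VEN1", "VEN2"])
        assert res.rho.loc["TF1", "VEN1"] == pytest.approx(1.0)
        assert bool(res.significant.loc["TF1", "VEN1"])

    def test_requires_three_samples(self):
        df = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["TF1", "VEN1"],
                          columns=["a", "b"])
        with pytest.raises(ValueError):
            tf_venom_correlation(self._norm(df), ["TF1"], ["VEN1"])

    def test_null_pairs_controlled_and_uniform(self, rng):
        n, n_tf, n_v = 30, 20, 10
        cols = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(rng.normal(size=(n_tf + n_v, n)),
                          index=[f"TF{i}" for i in range(n_tf)] +
                                [f"V{i}" for i in range(n_v)], columns=cols)
        res = tf_venom_correlation(self._norm(df), [f"TF{i}" for i in range(n_tf)],
                                   [f"V{i}" for i in range(n_v)])
        m = n_tf * n_v
        # BH keeps expected false discoveries below alpha * m
        assert res.significant.to_numpy().sum() <= 0.1 * m
        # p-values of independent pairs are uniform
        ks = stats.kstest(res.p.to_numpy().ravel(), "uniform")
        assert ks.pvalue > 1e-3

    def test_mask_is_joint_threshold(self, rng):
        cols = [f"s{i}" for i in range(10)]
        df = pd.DataFrame(rng.normal(size=(2, 10)), index=["TF1", "V1"], columns=cols)
        res = tf_venom_correlation(self._norm(df), ["TF1"], ["V1"])
        expected = (res.p < 0.05) & (res.q < 0.1)
        pd.testing.assert_frame_equal(res.significant, expected)
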