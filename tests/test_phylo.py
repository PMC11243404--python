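"""Independent contrasts, per-class PCA and the per-gene regression."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from regnet.footprints import binarize_footprints
from regnet.phylo import (
    CLASS_ORDER,
    ContrastTransformer,
    assemble_feature_table,
    bm_sample,
    build_gene_window,
    class_pca_pc1,
    fit_feature_table,
    fit_gene_model,
    pic,
    select_denovo_peaks,
)
from regnet.simulate import random_binary_tree, simulate_tree
from regnet.types import ElementClass, GenomicInterval, ScoreMatrix

import dendropy


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestPic:
    def test_two_tip_closed_form(self):
        tree = _tree("(A:1,B:1);")
        out = pic(tree, {"A": 3.0, "B": 1.0})
        assert out[0] == pytest.approx((3 - 1) / np.sqrt(2), abs=1e-5)

    def test_constant_trait_gives_zero_contrasts(self):
        tree = _tree("((A:1,B:1):1,(C:2,D:1):2);")
        np.testing.assert_allclose(pic(tree, dict.fromkeys("ABCD", 4.2)), 0.0, atol=1e-12)

    def test_missing_tip_value_rejected(self):
        tree = _tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            pic(tree, {"A": 1.0})

    def test_polytomy_resolved(self):
        tree = _tree("(A:1,B:1,C:1);")
        out = pic(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert out.shape == (2,)

    def test_whitening_identity_on_random_trees(self, rng):
        """T C T' = I: contrasts are independent with unit variance under BM."""
        for _ in range(25):
            tree = random_binary_tree(int(rng.integers(3, 13)), rng)
            tr = ContrastTransformer(tree)
            C = tr.bm_covariance()
            gram = tr.matrix @ C @ tr.matrix.T
            assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8

    def test_quadratic_form_matches_gls(self, rng):
        """Sum of squared contrasts equals the GLS quadratic form around the
        phylogenetic mean."""
        for _ in range(10):
            tree = random_binary_tree(8, rng)
            tr = ContrastTransformer(tree)
            C = tr.bm_covariance()
            x = rng.normal(size=8)
            Cinv = np.linalg.inv(C)
            one = np.ones(8)
            mu = one @ Cinv @ x / (one @ Cinv @ one)
            qf = (x - mu) @ Cinv @ (x - mu)
            np.testing.assert_allclose((tr.transform(x) ** 2).sum(), qf, atol=1e-8)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_ape_reference_implementation(self, rng, tmp_path):
        """Contrast values agree with ape::pic on random trees (one batched call)."""
        cases = []
        lines = ["library(ape)"]
        for k in range(10):
            tree = random_binary_tree(int(rng.integers(3, 11)), rng)
            tr = ContrastTransformer(tree)
            x = rng.normal(size=len(tr.tips))
            cases.append(np.sort(np.abs(tr.transform(x))))
            nwk = tree.as_string(schema="newick").replace("[&R] ", "").strip()
            vals = ",".join(f"{float(v)!r}" for v in x)
            names = ",".join(f'"{t}"' for t in tr.tips)
            lines.append(f't<-read.tree(text="{nwk}"); x<-c({vals}); names(x)<-c({names});'
                         f'cat(sprintf("%.15g", sort(abs(pic(x,t)))),sep=" "); cat("\\n")')
        script = tmp_path / "pic.R"
        script.write_text("\n".join(lines) + "\n")
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=120)
        assert res.returncode == 0, res.stderr
        for ours, line in zip(cases, res.stdout.strip().splitlines()):
            theirs = np.array([float(v) for v in line.split()])
            np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_bm_contrast_variance_matches_rate(self, rng):
        tree = simulate_tree(4, 3, seed=3)
        tr = ContrastTransformer(tree)
        rate = 0.7
        contrasts = tr.matrix @ bm_sample(tr, rate, rng, size=300)
        assert contrasts.var() == pytest.approx(rate, rel=0.1)

    def test_tip_label_permutation_invariance(self, rng):
        tree = random_binary_tree(8, rng)
        tr = ContrastTransformer(tree)
        x = pd.Series(rng.normal(size=8), index=tr.tips)
        shuffled = x.sample(frac=1.0, random_state=3)
        np.testing.assert_allclose(tr.transform(x), tr.transform(shuffled))


class TestClassPca:
    def test_perfectly_correlated_block(self, rng):
        a = rng.normal(size=20)
        scores, ve, _ = class_pca_pc1(np.column_stack([a, 2 * a]))
        assert ve == pytest.approx(1.0)

    def test_orthonormal_block_splits_variance(self):
        block = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, ve, _ = class_pca_pc1(block)
        assert ve == pytest.approx(0.5)

    def test_single_column_passthrough(self, rng):
        col = rng.normal(size=10)
        scores, ve, _ = class_pca_pc1(col[:, None])
        np.testing.assert_allclose(scores, col)
        assert ve == 1.0

    def test_matches_power_iteration_oracle(self, rng):
        B = rng.normal(size=(15, 10))
        scores, ve, v1 = class_pca_pc1(B)
        # independent eigensolver: power iteration on B'B
        M = B.T @ B
        v = np.ones(10) / np.sqrt(10)
        for _ in range(5000):
            v = M @ v
            v /= np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        np.testing.assert_allclose(np.abs(v1), np.abs(v), atol=1e-6)
        np.testing.assert_allclose(scores, B @ v, atol=1e-5)

    def test_sign_fixed_by_largest_loading(self, rng):
        B = rng.normal(size=(12, 4))
        _, _, v1 = class_pca_pc1(B)
        assert v1[np.argmax(np.abs(v1))] > 0


class TestGeneWindow:
    def test_pad_and_clip(self):
        ivs = [GenomicInterval("c", 10_000, 20_000, "a")]
        w = build_gene_window(ivs)
        assert (w.start, w.end) == (9_000, 21_000)
        w2 = build_gene_window([GenomicInterval("c", 500, 600, "b")])
        assert (w2.start, w2.end) == (0, 1_600)

    def test_spans_multiple_features(self):
        ivs = [GenomicInterval("c", 5_000, 6_000, "a"),
               GenomicInterval("c", 8_000, 9_000, "b")]
        w = build_gene_window(ivs)
        assert (w.start, w.end) == (4_000, 10_000)

    def test_multiple_chromosomes_rejected(self):
        ivs = [GenomicInterval("c1", 0, 10, "a"), GenomicInterval("c2", 0, 10, "b")]
        with pytest.raises(ValueError, match="multiple chromosomes"):
            build_gene_window(ivs)


class TestSelectDenovo:
    def _peaks(self, variances, rng):
        ivs = [GenomicInterval("c", 100 * i, 100 * i + 50, f"p{i}")
               for i in range(len(variances))]
        base = rng.normal(size=6)
        rows = {f"p{i}": np.sqrt(v) * base if False else
                np.concatenate([[0.0] * 5, [np.sqrt(v * 5 * 2)]])
                for i, v in enumerate(variances)}
        df = pd.DataFrame(rows).T
        df.columns = [f"s{j}" for j in range(6)]
        return ScoreMatrix(ivs, df)

    def test_top_k_by_variance(self, rng):
        peaks = self._peaks([1, 5, 3, 2, 4], rng)
        w = GenomicInterval("c", 0, 1_000, "w")
        assert select_denovo_peaks(peaks, w, exclude=set()) == ["p1", "p4", "p2"]

    def test_tie_breaks_toward_lower_coordinate(self, rng):
        peaks = self._peaks([2, 2, 2, 2], rng)
        w = GenomicInterval("c", 0, 1_000, "w")
        assert select_denovo_peaks(peaks, w, exclude=set(), k=2) == ["p0", "p1"]

    def test_exclusions_and_empty(self, rng):
        peaks = self._peaks([1, 2], rng)
        w = GenomicInterval("c", 0, 1_000, "w")
        assert select_denovo_peaks(peaks, w, exclude={"p0", "p1"}) == []


class TestFitGeneModel:
    def test_known_single_class_solution(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.01, n)
        blocks = {"cre_accessibility": x[:, None],
                  "tf_expression": rng.normal(size=(n, 3))}
        res = fit_gene_model(y, blocks, gene="g")
        assert res.table.loc["cre_accessibility", "p"] < 1e-6
        assert res.table.loc["cre_accessibility", "coefficient"] == pytest.approx(1.0, abs=0.02)

    def test_too_few_contrasts_rejected(self, rng):
        blocks = {c: rng.normal(size=(5, 1)) for c in CLASS_ORDER}
        with pytest.raises(ValueError, match="cannot support"):
            fit_gene_model(rng.normal(size=5), blocks)

    def test_collinear_class_dropped_deterministically(self, rng):
        n = 20
        x = rng.normal(size=n)
        blocks = {"cre_accessibility": x[:, None],
                  "cre_genotype": (2 * x)[:, None]}  # collinear, later in order
        res = fit_gene_model(rng.normal(size=n), blocks)
        assert "cre_genotype" in res.dropped
        assert "cre_accessibility" in res.table.index

    def test_zero_variance_class_reported_dropped(self, rng):
        n = 15
        blocks = {"cre_accessibility": rng.normal(size=(n, 1)),
                  "tf_footprints": np.zeros((n, 2))}
        res = fit_gene_model(rng.normal(size=n), blocks)
        assert res.dropped["tf_footprints"] == "zero variance after contrasts"


class TestAssembleFeatureTable:
    def test_block_bookkeeping(self, small_bundle):
        from regnet.pipeline import normalized_expression
        b = small_bundle
        norm = normalized_expression(b)
        occ = binarize_footprints(b.footprint_scores)
        gene = b.venom_genes[0]
        ft = assemble_feature_table(gene, norm.values, b.accessibility, occ,
                                    b.variants, b.tf_genes, b.annotation.intervals)
        cres = b.annotation.cres_of(gene)
        assert ft.classes["cre_accessibility"].shape[1] == len(cres)
        assert ft.classes["tf_expression"].shape[1] == len(b.tf_genes)
        assert set(ft.classes["tf_footprints"].to_numpy().ravel()) <= {0.0, 1.0}
        if "cre_genotype" in ft.classes:
            assert set(np.unique(ft.classes["cre_genotype"])) <= {0.0, 1.0, 2.0}

    def test_unknown_gene_rejected(self, small_bundle):
        from regnet.pipeline import normalized_expression
        b = small_bundle
        norm = normalized_expression(b)
        occ = binarize_footprints(b.footprint_scores)
        with pytest.raises(KeyError):
            assemble_feature_table("NOPE", norm.values, b.accessibility, occ,
                                   b.variants, b.tf_genes, b.annotation.intervals)

    def test_sample_order_permutation_leaves_result_unchanged(self, small_bundle):
        from regnet.pipeline import normalized_expression
        b = small_bundle
        norm = normalized_expression(b)
        occ = binarize_footprints(b.footprint_scores)
        tr = ContrastTransformer(b.tree)
        gene = b.venom_genes[1]
        ft = assemble_feature_table(gene, norm.values, b.accessibility, occ,
                                    b.variants, b.tf_genes, b.annotation.intervals)
        res1 = fit_feature_table(ft, tr)
        perm = b.samples[::-1]
        ft2 = assemble_feature_table(gene, norm.values[perm], b.accessibility, occ,
                                     b.variants, b.tf_genes, b.annotation.intervals)
        ft2.response = ft2.response.reindex(perm)
        ft2.classes = {k: v.reindex(perm) for k, v in ft2.classes.items()}
        res2 = fit_feature_table(ft2, tr)
        pd.testing.assert_frame_equal(res1.table, res2.table)


def test_planted_driver_recovered_in_fig4_matrix(small_bundle):
    """The planted enhancer-accessibility driver makes its class significant
    for the planted gene in the full matrix run."""
    from regnet.pipeline import run_fig4_matrix
    fig4, excl = run_fig4_matrix(small_bundle)
    eff = small_bundle.config.planted_effects[0]
    rows = fig4[(fig4.gene == eff.gene) & (fig4["class"] == "cre_accessibility")]
    assert len(rows) == 1
    assert rows.iloc[0]["p"] == fig4[fig4.gene == eff.gene]["p"].min()
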