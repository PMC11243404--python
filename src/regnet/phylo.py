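"""Phylogenetically independent contrasts and the per-gene regulatory model.

Traits measured on the tips of a phylogeny are not independent draws: under a
Brownian-motion (BM) model their covariance equals shared root-to-ancestor
branch length. Felsenstein's independent contrasts remove that covariance; the
per-gene model then regresses contrasts of normalized expression on contrasts
of six regulatory feature classes (CRE accessibility, CTCF accessibility,
de novo peak accessibility, TF footprints, TF expression, CRE genotype), each
reduced to its first principal axis when multivariate.

The contrast transform is linear in the trait, so the recursion is run once on
unit vectors to produce an explicit (n_tips - 1) x n_tips operator ``T``; all
later transforms are matrix products. Under BM with tip covariance ``C`` the
operator satisfies ``T C Tᵀ = I`` (contrasts are independent with unit
variance), which is the exactness check used by the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ElementClass, GenomicInterval, ScoreMatrix, Variant

logger = logging.getLogger(__name__)

#: Fixed feature-class order; collinear classes are dropped later-first.
CLASS_ORDER = (
    "cre_accessibility",
    "ctcf_accessibility",
    "denovo_accessibility",
    "tf_footprints",
    "tf_expression",
    "cre_genotype",
)


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return max(leaf.root_distance for leaf in tree.leaf_node_iter())


class ContrastTransformer:
    """Precomputed independent-contrast operator for one tree.

    The input tree may contain polytomies and zero-length edges; it is cloned,
    polytomies are resolved to binary nodes, and zero/absent edge lengths are
    raised to ``eps_frac`` x tree height so every contrast denominator is
    positive.

    Attributes
    ----------
    tips : list of tip labels fixing the row order expected by ``transform``.
    matrix : the (n_tips - 1) x n_tips standardized-contrast operator, rows in
        post-order over internal nodes.
    """

    def __init__(self, tree: dendropy.Tree, eps_frac: float = 1e-6):
        work = tree.clone(depth=1)
        work.resolve_polytomies(limit=2, update_bipartitions=False)
        height = tree_height(work)
        if height <= 0:
            raise ValueError("tree has zero height; contrasts undefined")
        eps = eps_frac * height
        for edge in work.preorder_edge_iter():
            if edge.head_node is work.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                edge.length = eps
        self.tree = work
        self.tips = [leaf.taxon.label for leaf in work.leaf_node_iter()]
        self._tip_index = {t: i for i, t in enumerate(self.tips)}
        n = len(self.tips)
        if n < 2:
            raise ValueError("need at least 2 tips")

        rows = []
        for node in work.postorder_node_iter():
            if node.is_leaf():
                node._pic_x = np.eye(n)[self._tip_index[node.taxon.label]]
                node._pic_v = node.edge.length
                continue
            c1, c2 = node.child_nodes()
            v1, v2 = c1._pic_v, c2._pic_v
            if v1 + v2 <= 0:
                raise ValueError(
                    "zero-length cherry: raise eps_frac so contrast variances are positive"
                )
            rows.append((c1._pic_x - c2._pic_x) / np.sqrt(v1 + v2))
            node._pic_x = (c1._pic_x / v1 + c2._pic_x / v2) / (1.0 / v1 + 1.0 / v2)
            base = node.edge.length if node is not work.seed_node else 0.0
            node._pic_v = (base or 0.0) + v1 * v2 / (v1 + v2)
        self.matrix = np.vstack(rows)

    @property
    def n_contrasts(self) -> int:
        return self.matrix.shape[0]

    def transform(self, X) -> np.ndarray:
        """Contrasts of one or many traits.

        ``X`` may be a Series (index = tip labels) or a DataFrame/array with
        rows ordered/labeled by tips; returns an array of shape
        (n_contrasts,) or (n_contrasts, n_traits).
        """
        if isinstance(X, pd.Series):
            return self.matrix @ X.reindex(self.tips).to_numpy(dtype=float)
        if isinstance(X, pd.DataFrame):
            return self.matrix @ X.reindex(self.tips).to_numpy(dtype=float)
        return self.matrix @ np.asarray(X, dtype=float)

    def bm_covariance(self) -> np.ndarray:
        """BM tip covariance of the (adjusted) tree, in ``tips`` order."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        n = len(self.tips)
        depth = {leaf.taxon.label: leaf.root_distance for leaf in self.tree.leaf_node_iter()}
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        C = np.zeros((n, n))
        for i, a in enumerate(self.tips):
            for j, b in enumerate(self.tips):
                if i == j:
                    C[i, j] = depth[a]
                else:
                    d = pdm.patristic_distance(taxa[a], taxa[b])
                    C[i, j] = 0.5 * (depth[a] + depth[b] - d)
        return C


def pic(tree: dendropy.Tree, trait, eps_frac: float = 1e-6) -> np.ndarray:
    """Standardized independent contrasts of a single trait.

    ``trait`` maps tip label -> value (dict or Series); every tip must be
    present. Contrasts come back in post-order over internal nodes.
    """
    tr = ContrastTransformer(tree, eps_frac=eps_frac)
    series = pd.Series(trait)
    missing = set(tr.tips) - set(series.index)
    if missing:
        raise ValueError(f"trait values missing for tips: {sorted(missing)}")
    return tr.transform(series)


def bm_sample(transformer: ContrastTransformer, rate: float, rng: np.random.Generator,
              size: int = 1) -> np.ndarray:
    """Draw BM tip values (root state 0) with the given rate; shape (n_tips, size)."""
    C = transformer.bm_covariance()
    L = np.linalg.cholesky(rate * C + 1e-12 * np.eye(C.shape[0]))
    return L @ rng.standard_normal((C.shape[0], size))


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """Per-gene regressor bundle: response plus six predictor classes."""

    gene: str
    response: pd.Series  # normalized expression, index = samples
    classes: dict[str, pd.DataFrame] = field(default_factory=dict)  # samples x variables
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.response.index)


def build_gene_window(intervals: list[GenomicInterval], pad: int = 1000) -> GenomicInterval:
    """Window spanning a gene array's features, extended by ``pad`` bp each side."""
    if not intervals:
        raise ValueError("no features to build a window from")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"features span multiple chromosomes: {sorted(chroms)}")
    start = max(0, min(iv.start for iv in intervals) - pad)
    end = max(iv.end for iv in intervals) + pad
    return GenomicInterval(chroms.pop(), start, end, name="window")


def select_denovo_peaks(peaks: ScoreMatrix, window: GenomicInterval,
                        exclude: set[str], k: int = 3) -> list[str]:
    """Top-k most variable peaks in the window, excluding CRE/CTCF peaks.

    Ties in variance break toward the lower genomic coordinate.
    """
    eligible = [iv for iv in peaks.intervals
                if iv.name not in exclude
                and iv.element_class not in (ElementClass.PROMOTER, ElementClass.ENHANCER,
                                             ElementClass.CTCF)
                and iv.overlaps(window)]
    if not eligible:
        return []
    var = peaks.values.loc[[iv.name for iv in eligible]].var(axis=1, ddof=1)
    order = sorted(eligible, key=lambda iv: (-var[iv.name], iv.start))
    chosen = [iv.name for iv in order[:k]]
    if len(chosen) < k:
        logger.warning("window %s: only %d eligible de novo peaks (< %d)",
                       window.name, len(chosen), k)
    return chosen


def _impute_genotypes(variants: list[Variant], samples: list[str],
                      max_missing: float = 0.5) -> pd.DataFrame:
    cols = {}
    for v in variants:
        dos = pd.Series({s: v.genotypes.get(s, None) for s in samples}).map(
            lambda g: g.dosage if g is not None else np.nan)
        frac_missing = dos.isna().mean()
        if frac_missing > max_missing:
            logger.info("variant %s:%d dropped (%.0f%% missing)", v.chrom, v.pos,
                        100 * frac_missing)
            continue
        if dos.isna().any():
            mode = dos.mode()
            dos = dos.fillna(mode.iloc[0] if len(mode) else 0.0)
        cols[f"{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}"] = dos
    return pd.DataFrame(cols, index=samples)


def assemble_feature_table(
    gene: str,
    expression: pd.DataFrame,
    accessibility: ScoreMatrix,
    occupancy,  # footprints.OccupancyMatrix
    variants: list[Variant],
    tf_genes: list[str],
    cre_intervals: list[GenomicInterval],
    min_samples: int = 4,
) -> FeatureTable:
    """Assemble the per-gene response and six predictor classes.

    Samples missing any layer are dropped (with a logged list); the genotype
    class imputes missing calls to the per-variant mode.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    gene_cres = [iv for iv in cre_intervals
                 if iv.gene == gene
                 and iv.element_class in (ElementClass.PROMOTER, ElementClass.ENHANCER)]
    layer_samples = [set(expression.columns), set(accessibility.samples),
                     set(occupancy.samples)]
    shared = set.intersection(*layer_samples)
    dropped_samples = sorted(set(expression.columns) - shared)
    if dropped_samples:
        logger.info("gene %s: samples missing a layer dropped: %s", gene, dropped_samples)
    samples = [s for s in expression.columns if s in shared]
    if len(samples) < min_samples:
        raise ValueError(f"gene {gene}: only {len(samples)} samples shared across layers")

    ft = FeatureTable(gene=gene, response=expression.loc[gene, samples].astype(float))

    def add(name: str, block: pd.DataFrame):
        if block.shape[1] == 0:
            ft.dropped[name] = "no variables"
            return
        keep = block.columns[block.std(axis=0, ddof=0) > 0]
        if len(keep) == 0:
            ft.dropped[name] = "zero variance"
            return
        ft.classes[name] = block[keep]

    cre_names = [iv.name for iv in gene_cres]
    acc = accessibility.values
    add("cre_accessibility",
        acc.loc[[n for n in acc.index if n in set(cre_names)], samples].T)

    if gene_cres:
        window = build_gene_window(gene_cres)
        ctcf_names = [iv.name for iv in accessibility.intervals
                      if iv.element_class == ElementClass.CTCF and iv.overlaps(window)]
        add("ctcf_accessibility", acc.loc[ctcf_names, samples].T)
        denovo = select_denovo_peaks(accessibility, window,
                                     exclude=set(cre_names) | set(ctcf_names))
        add("denovo_accessibility", acc.loc[denovo, samples].T)
    else:
        ft.dropped["ctcf_accessibility"] = "gene has no annotated CREs"
        ft.dropped["denovo_accessibility"] = "gene has no annotated CREs"

    fp_names = [iv.name for iv in occupancy.intervals
                if any(cre.chrom == iv.chrom and cre.start <= iv.start and iv.end <= cre.end
                       for cre in gene_cres)]
    add("tf_footprints", occupancy.bound.loc[fp_names, samples].T.astype(float))

    add("tf_expression",
        expression.loc[[t for t in tf_genes if t in expression.index and t != gene],
                       samples].T)

    cre_vars = [v for v in variants if any(v.interval.overlaps(cre) for cre in gene_cres)]
    add("cre_genotype", _impute_genotypes(cre_vars, samples))
    return ft


# ---------------------------------------------------------------------------
# per-class PCA and the gene model


def class_pca_pc1(block: np.ndarray, center: bool = False):
    """First principal axis of a (contrasts x variables) block.

    Uncentered by default: contrasts have expectation zero under BM. The PC1
    sign is fixed so the largest-magnitude loading is positive. Returns
    (scores, variance_explained, loadings).
    """
    B = np.asarray(block, dtype=float)
    if B.ndim != 2 or B.shape[1] < 1:
        raise ValueError("block must be 2-D with >= 1 variable")
    if not np.any(B != 0):
        raise ValueError("all-zero block")
    if B.shape[1] == 1:
        return B[:, 0].copy(), 1.0, np.array([1.0])
    if center:
        B = B - B.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(B, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    scores = B @ v1
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return scores, var_explained, v1


@dataclass
class GeneModelResult:
    """Per-gene regression summary: one row per retained feature class."""

    gene: str
    table: pd.DataFrame  # index class; columns coefficient, abs_coefficient, p, pc1_var_explained
    r2: float
    n_contrasts: int
    dropped: dict[str, str] = field(default_factory=dict)

    def significant_classes(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p"] < alpha])


def fit_gene_model(response_contrasts: np.ndarray,
                   class_contrasts: dict[str, np.ndarray],
                   gene: str = "",
                   intercept: bool = True,
                   center_pca: bool = False) -> GeneModelResult:
    """OLS of response contrasts on one predictor per feature class.

    Multivariate classes are reduced to PC1 of their contrast block. Collinear
    classes are dropped deterministically, later classes in ``CLASS_ORDER``
    first. Requires more contrasts than predictors (plus intercept).
    """
    y = np.asarray(response_contrasts, dtype=float)
    n = y.shape[0]
    dropped: dict[str, str] = {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    pc1_var: dict[str, float] = {}

    for cls in CLASS_ORDER:
        if cls not in class_contrasts:
            continue
        block = np.atleast_2d(np.asarray(class_contrasts[cls], dtype=float))
        if block.shape[0] == 1 and n != 1:
            block = block.T
        keep = np.ptp(block, axis=0) > 0
        if not keep.any():
            dropped[cls] = "zero variance after contrasts"
            continue
        block = block[:, keep]
        scores, ve, _ = class_pca_pc1(block, center=center_pca)
        cols.append(scores)
        names.append(cls)
        pc1_var[cls] = ve

    if len(cols) == 0:
        raise ValueError(f"gene {gene}: no usable predictor classes")
    if n <= len(cols) + (1 if intercept else 0):
        raise ValueError(
            f"gene {gene}: {n} contrasts cannot support {len(cols)} classes"
            + (" + intercept" if intercept else "")
        )

    # deterministic collinearity handling: later classes dropped first
    X = np.empty((n, 0))
    kept_names: list[str] = []
    base_rank = 0
    if intercept:
        X = np.ones((n, 1))
        base_rank = 1
    for name, col in zip(names, cols):
        cand = np.column_stack([X, col])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X = cand
            kept_names.append(name)
        else:
            dropped[name] = "collinear with earlier classes"
    model = sm.OLS(y, X).fit()
    offset = base_rank
    rows = []
    for i, name in enumerate(kept_names):
        coef = model.params[offset + i]
        rows.append({
            "class": name,
            "coefficient": coef,
            "abs_coefficient": abs(coef),
            "p": model.pvalues[offset + i],
            "pc1_var_explained": pc1_var[name],
        })
    table = pd.DataFrame(rows).set_index("class")
    return GeneModelResult(gene=gene, table=table, r2=float(model.rsquared),
                           n_contrasts=n, dropped=dropped)


def fit_feature_table(ft: FeatureTable, transformer: ContrastTransformer,
                      **kwargs) -> GeneModelResult:
    """Transform a feature table into contrasts and fit the per-gene model."""
    y = transformer.transform(ft.response)
    blocks = {cls: transformer.transform(df) for cls, df in ft.classes.items()}
    result = fit_gene_model(y, blocks, gene=ft.gene, **kwargs)
    result.dropped.update(ft.dropped)
    return result
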