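"""Expression normalization, gland combining, variance analysis and the
significance-filtered TF-venom correlation network.

Normalization re-implements the median-of-ratios size-factor formula
(s_j = median_i k_ij / (prod_j k_ij)^(1/m), over genes with all-positive
counts) and proxies variance stabilization with log2(normalized + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import GlandSide, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x samples
    size_factors: pd.Series
    transform: str = "log2p1"  # or "none"

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")


@dataclass
class CorrelationResult:
    rho: pd.DataFrame  # TFs x venom genes
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame  # boolean mask: p < p_thresh AND q < q_thresh
    p_threshold: float
    q_threshold: float


def combine_glands(counts: pd.DataFrame, meta: list[SampleMeta]
                   ) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Sum left+right venom-gland raw counts per individual before normalization.

    Individuals with a single gland sample pass through; the combined column is
    named by the individual. Two same-side samples for one individual is an
    error.
    """
    by_id = {m.sample_id: m for m in meta}
    missing = set(counts.columns) - set(by_id)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    groups: dict[str, list[SampleMeta]] = {}
    for s in counts.columns:
        groups.setdefault(by_id[s].individual, []).append(by_id[s])
    new_cols = {}
    new_meta = []
    for indiv, members in groups.items():
        sides = [m.gland_side for m in members]
        if len(members) > 1 and len(set(sides)) != len(sides):
            raise ValueError(f"individual {indiv}: duplicate gland side among samples")
        summed = counts[[m.sample_id for m in members]].sum(axis=1)
        new_cols[indiv] = summed
        side = GlandSide.COMBINED if len(members) > 1 else sides[0]
        first = members[0]
        new_meta.append(SampleMeta(indiv, first.lineage, first.population, side, indiv))
    out = pd.DataFrame(new_cols).astype(np.int64)
    out.index = counts.index
    return out, new_meta


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors from the median ratio to a geometric-mean reference.

    Only genes with all-positive counts contribute; with no such gene the
    caller should fall back to a pseudo-reference (``allow_pseudo_reference``
    in :func:`normalize`).
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with allow_pseudo_reference=True"
        )
    sub = arr[positive]
    log_ref = np.log(sub).mean(axis=1)  # log geometric mean per gene
    sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def normalize(counts: pd.DataFrame, transform: str = "log2p1",
              allow_pseudo_reference: bool = False) -> NormalizedMatrix:
    """Median-of-ratios normalization, optionally log2(x+1)-transformed."""
    try:
        sf = size_factors_median_of_ratios(counts)
    except ValueError:
        if not allow_pseudo_reference:
            raise
        arr = counts.to_numpy(dtype=float)
        expressed = (arr > 0).any(axis=1)
        with np.errstate(divide="ignore"):
            logs = np.where(arr[expressed] > 0, np.log(arr[expressed]), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        ratios = np.log(np.maximum(arr[expressed], 0.5)) - log_ref[:, None]
        sf = pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)
    vals = counts.div(sf, axis=1)
    if transform == "log2p1":
        vals = np.log2(vals + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return NormalizedMatrix(vals, sf, transform)


def expression_variance(norm: NormalizedMatrix,
                        samples: Optional[list[str]] = None) -> pd.Series:
    """Unbiased per-gene variance over all samples or a subset."""
    sub = norm.values if samples is None else norm.values[samples]
    if sub.shape[1] < 2:
        raise ValueError("variance needs >= 2 samples")
    return sub.var(axis=1, ddof=1)


def top_variable_genes(variances: pd.Series, k: int) -> list[str]:
    return list(variances.sort_values(ascending=False).index[:k])


def variance_group_test(variances_a, variances_b, equal_var: bool = False):
    """Two-sample t-test on per-gene variances (Welch by default).

    Returns (t, p); degenerate all-constant groups yield NaN with a warning.
    """
    a = np.asarray(variances_a, dtype=float)
    b = np.asarray(variances_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        logger.warning("zero within-group variance in both groups; p undefined")
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def gene_trait_significance(norm: NormalizedMatrix, trait: pd.Series) -> pd.Series:
    """|Pearson r| between each gene's expression and a 0/1 trait indicator."""
    t = trait.reindex(norm.values.columns).to_numpy(dtype=float)
    if set(np.unique(t)) - {0.0, 1.0}:
        raise ValueError("trait must be binary 0/1")
    if len(np.unique(t)) < 2:
        raise ValueError("trait must have both classes present")
    X = norm.values.to_numpy(dtype=float)
    tc = t - t.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (tc**2).sum())
    const = denom == 0
    if const.any():
        logger.warning("%d constant genes given |r| = 0", int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(const, 0.0, np.abs(Xc @ tc) / np.where(denom == 0, 1.0, denom))
    return pd.Series(r, index=norm.values.index)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between rows of A and rows of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def tf_venom_correlation(norm: NormalizedMatrix, tf_genes: list[str],
                         venom_genes: list[str], p_threshold: float = 0.05,
                         q_threshold: float = 0.1) -> CorrelationResult:
    """Pearson correlation of each TF against each venom gene, BH-adjusted jointly.

    p-values come from t = r sqrt((n-2)/(1-r^2)) on n-2 df; the significance
    mask requires p < 0.05 and FDR < 0.1 (both configurable).
    """
    n = norm.values.shape[1]
    if n < 3:
        raise ValueError("correlation needs >= 3 samples")
    A = norm.values.loc[tf_genes].to_numpy(dtype=float)
    B = norm.values.loc[venom_genes].to_numpy(dtype=float)
    r = _pearson_matrix(A, B)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    q = benjamini_hochberg(p.ravel()).reshape(p.shape)
    rho = pd.DataFrame(r, index=tf_genes, columns=venom_genes)
    pdf = pd.DataFrame(p, index=tf_genes, columns=venom_genes)
    qdf = pd.DataFrame(q, index=tf_genes, columns=venom_genes)
    mask = (pdf < p_threshold) & (qdf < q_threshold)
    return CorrelationResult(rho, pdf, qdf, mask, p_threshold, q_threshold)
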