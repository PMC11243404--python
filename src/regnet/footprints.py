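"""Footprint-score binarization and TF occupancy summaries.

ATAC-seq footprint scores are continuous evidence of protein occupancy at
TFBSs. Bound/unbound calls use a per-sample threshold: supplied externally
(e.g. from upstream footprinting software) or estimated as the midpoint of a
deterministic two-means split of that sample's scores. Ties at the threshold
count as bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Genotype, GenomicInterval, ScoreMatrix, Variant

logger = logging.getLogger(__name__)


@dataclass
class OccupancyMatrix:
    intervals: list[GenomicInterval]  # TFBS intervals; name encodes motif/TF
    scores: pd.DataFrame  # TFBS x samples
    thresholds: pd.Series  # per sample
    bound: pd.DataFrame  # binary, bound[i, j] = 1 iff scores[i, j] >= thresholds[j]
    tf_names: pd.Series | None = None  # TFBS name -> TF

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


def two_means_threshold(scores: np.ndarray, max_iter: int = 100) -> float:
    """Midpoint between the two cluster centers of a 1-D 2-means split.

    Deterministic initialization at the 10th and 90th percentiles; returns NaN
    for a constant score vector (threshold undefined).
    """
    x = np.asarray(scores, dtype=float)
    if np.ptp(x) == 0:
        return float("nan")
    c = np.percentile(x, [10.0, 90.0]).astype(float)
    if c[0] == c[1]:
        c = np.array([x.min(), x.max()], dtype=float)
    for _ in range(max_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[assign == k].mean() if (assign == k).any() else c[k]
                        for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


def binarize_footprints(scores: ScoreMatrix,
                        thresholds: pd.Series | None = None,
                        min_rows: int = 20) -> OccupancyMatrix:
    """Binarize footprint scores into bound/unbound per sample.

    Supplied thresholds are used as-is; otherwise each sample's threshold is
    estimated by the deterministic two-means rule (requires >= ``min_rows``
    TFBS rows). A constant score column yields an undefined threshold and an
    all-unbound sample, with a warning.
    """
    vals = scores.values
    if thresholds is None:
        if vals.shape[0] < min_rows:
            raise ValueError(
                f"threshold estimation needs >= {min_rows} TFBS rows, got {vals.shape[0]}"
            )
        thresholds = pd.Series({s: two_means_threshold(vals[s].to_numpy())
                                for s in vals.columns})
    else:
        thresholds = thresholds.reindex(vals.columns)
        if thresholds.isna().any():
            raise ValueError("thresholds missing for some samples")
    bound = pd.DataFrame(0, index=vals.index, columns=vals.columns, dtype=np.int8)
    for s in vals.columns:
        thr = thresholds[s]
        if np.isnan(thr):
            logger.warning("sample %s: constant footprint scores; all sites called unbound", s)
            continue
        bound[s] = (vals[s] >= thr).astype(np.int8)
    tf_names = None
    return OccupancyMatrix(scores.intervals, vals, thresholds, bound, tf_names)


def count_binding_events(occ: OccupancyMatrix, element: GenomicInterval,
                         tf_of: dict[str, str]) -> pd.DataFrame:
    """Bound-TFBS counts per TF per sample within one element (zero rows kept).

    ``tf_of`` maps TFBS interval name -> TF name. Counts TFBS rows, not
    distinct binding events, when a TF has overlapping motifs.
    """
    inside = [iv.name for iv in occ.intervals
              if iv.chrom == element.chrom and element.start <= iv.start and iv.end <= element.end]
    if not inside:
        logger.warning("element %s contains no TFBS", element.name)
        return pd.DataFrame(columns=occ.samples)
    tfs = sorted({tf_of[n] for n in inside})
    out = pd.DataFrame(0, index=tfs, columns=occ.samples, dtype=int)
    for name in inside:
        out.loc[tf_of[name]] += occ.bound.loc[name]
    return out


def intersect_bound_variants(occ: OccupancyMatrix, variants: list[Variant]) -> pd.DataFrame:
    """Join bound/unbound state with genotype for variants inside TFBSs.

    One row per (TFBS, overlapping variant); a TFBS is flagged
    ``differentially_bound`` when the bound states of ref-carrying and
    alt-carrying samples are disjoint (e.g. bound only among hom_ref samples).
    """
    rows = []
    for iv in occ.intervals:
        for v in variants:
            if not v.interval.overlaps(iv):
                continue
            ref_samples = [s for s in occ.samples
                           if v.genotypes.get(s) == Genotype.HOM_REF]
            alt_samples = [s for s in occ.samples
                           if v.genotypes.get(s) in (Genotype.HET, Genotype.HOM_ALT)]
            ref_states = {int(occ.bound.loc[iv.name, s]) for s in ref_samples}
            alt_states = {int(occ.bound.loc[iv.name, s]) for s in alt_samples}
            flagged = (bool(ref_states) and bool(alt_states)
                       and ref_states.isdisjoint(alt_states))
            rows.append({
                "tfbs": iv.name,
                "variant": f"{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}",
                "bound_alt_carriers": sorted(s for s in alt_samples
                                             if occ.bound.loc[iv.name, s]),
                "bound_ref_carriers": sorted(s for s in ref_samples
                                             if occ.bound.loc[iv.name, s]),
                "n_alt_carriers": len(alt_samples),
                "differentially_bound": flagged,
            })
    return pd.DataFrame(rows)
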