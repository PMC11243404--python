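"""Compositional coupling of venom-gland mRNA abundance and venom protein abundance.

Both layers are compositions (relative abundances within an individual), so
each sample's vector is centered-log-ratio (CLR) transformed before a pooled
ordinary least squares fit of protein on mRNA across all gene x individual
points. The fit R^2 is the squared Pearson correlation of the pooled points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def clr_transform(x) -> np.ndarray:
    """Centered log-ratio: clr_i = ln x_i - mean(ln x). Requires x > 0.

    Zero-sum by construction and invariant to rescaling the whole vector.
    """
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("CLR requires strictly positive entries (apply an offset first)")
    logs = np.log(arr)
    return logs - logs.mean(axis=-1, keepdims=True)


def half_min_offset(mat: pd.DataFrame) -> float:
    """Half the smallest positive entry: the pseudo-count used before CLR."""
    arr = mat.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive entries")
    return float(positive.min() / 2.0)


@dataclass
class PairedAbundance:
    """Matched venom-gene mRNA and protein abundances over the same samples."""

    mrna: pd.DataFrame  # genes x samples, positive after offset
    protein: pd.DataFrame
    clr_mrna: pd.DataFrame
    clr_protein: pd.DataFrame


def pair_abundances(mrna: pd.DataFrame, protein: pd.DataFrame) -> PairedAbundance:
    """Align the two layers on shared genes/samples and CLR-transform per sample.

    Zeros are handled by adding each matrix's half-minimum positive value
    before taking logs.
    """
    genes = [g for g in mrna.index if g in set(protein.index)]
    samples = [s for s in mrna.columns if s in set(protein.columns)]
    if len(genes) < 2 or len(samples) < 1:
        raise ValueError("need >= 2 shared genes and >= 1 shared sample")
    m = mrna.loc[genes, samples].astype(float)
    p = protein.loc[genes, samples].astype(float)
    m_off = m + (half_min_offset(m) if (m.to_numpy() <= 0).any() else 0.0)
    p_off = p + (half_min_offset(p) if (p.to_numpy() <= 0).any() else 0.0)
    clr_m = pd.DataFrame(clr_transform(m_off.to_numpy().T).T, index=genes, columns=samples)
    clr_p = pd.DataFrame(clr_transform(p_off.to_numpy().T).T, index=genes, columns=samples)
    return PairedAbundance(m_off, p_off, clr_m, clr_p)


def mrna_protein_fit(paired: PairedAbundance, per_individual: bool = False):
    """OLS of CLR protein on CLR mRNA.

    Pooled over all gene x sample points by default (matching a single
    scatter of every gene in every individual); ``per_individual`` instead
    returns one fit per sample. Returns (slope, intercept, r2) or a DataFrame
    of per-sample fits.
    """
    if per_individual:
        rows = []
        for s in paired.clr_mrna.columns:
            res = _fit(paired.clr_mrna[s].to_numpy(), paired.clr_protein[s].to_numpy())
            rows.append({"sample": s, "slope": res[0], "intercept": res[1], "r2": res[2]})
        return pd.DataFrame(rows).set_index("sample")
    x = paired.clr_mrna.to_numpy().ravel()
    y = paired.clr_protein.to_numpy().ravel()
    return _fit(x, y)


def _fit(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
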