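"""Deletion evidence from windowed resequencing depth.

Per-sample depth in fixed-width windows is normalized by that sample's
background median; runs of consecutive low-ratio windows over a query
interval are called as homozygous or heterozygous deletions. The thresholds
(0.25 hom, 0.75 het, 3 consecutive windows) operationalize a read-density
inspection and are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenomicInterval


@dataclass
class DepthProfile:
    windows: list[GenomicInterval]  # fixed width, ordered along the chromosome
    depth: pd.DataFrame  # windows (by name) x samples, >= 0
    medians: pd.Series | None = None  # per-sample background median depth

    def __post_init__(self):
        widths = {len(w) for w in self.windows}
        if len(widths) > 1:
            raise ValueError(f"window widths differ: {sorted(widths)}")
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("depth must be non-negative")


def depth_ratio(profile: DepthProfile,
                exclude: GenomicInterval | None = None) -> pd.DataFrame:
    """Depth divided by the per-sample median over background windows.

    ``exclude`` removes the query region from the median so a real deletion
    does not drag its own baseline down.
    """
    if profile.medians is not None:
        med = profile.medians
    else:
        bg = [w.name for w in profile.windows
              if exclude is None or not w.overlaps(exclude)]
        if not bg:
            raise ValueError("no background windows left to compute medians")
        med = profile.depth.loc[bg].median(axis=0)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"zero median depth for samples {bad}")
    return profile.depth.div(med, axis=1)


@dataclass
class DeletionCall:
    sample: str
    call: str  # 'none' | 'het_del' | 'hom_del'
    run_start: int | None  # window index of the supporting run (within query)
    run_length: int
    mean_ratio: float


def _longest_run(mask: np.ndarray) -> tuple[int | None, int]:
    best_start, best_len = None, 0
    cur_start, cur_len = None, 0
    for i, m in enumerate(mask):
        if m:
            if cur_start is None:
                cur_start, cur_len = i, 0
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_start, cur_len = None, 0
    return best_start, best_len


def call_deletion(ratios: pd.DataFrame, windows: list[GenomicInterval],
                  query: GenomicInterval, hom_threshold: float = 0.25,
                  het_threshold: float = 0.75,
                  min_consecutive_windows: int = 3) -> list[DeletionCall]:
    """Per-sample deletion call over a query interval.

    hom_del when >= min consecutive query windows fall below ``hom_threshold``;
    het_del when a run falls below ``het_threshold`` (but not hom); else none.
    The longest qualifying run is reported.
    """
    idx = [i for i, w in enumerate(windows) if w.overlaps(query)]
    if len(idx) < min_consecutive_windows:
        raise ValueError(
            f"query covered by {len(idx)} windows; need >= {min_consecutive_windows}"
        )
    names = [windows[i].name for i in idx]
    out = []
    for s in ratios.columns:
        r = ratios.loc[names, s].to_numpy(dtype=float)
        hom_start, hom_len = _longest_run(r < hom_threshold)
        het_start, het_len = _longest_run(r < het_threshold)
        if hom_len >= min_consecutive_windows:
            call, start, length = "hom_del", hom_start, hom_len
        elif het_len >= min_consecutive_windows:
            call, start, length = "het_del", het_start, het_len
        else:
            call, start, length = "none", None, 0
        mean_ratio = float(r[start:start + length].mean()) if length else float(r.mean())
        out.append(DeletionCall(s, call, start, length, mean_ratio))
    return out
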