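"""ROI summaries and the RRTD contrast metric over relaxation maps.

RRTD (relative relaxation time difference) is the contrast statistic
(T_infarct - T_remote) / T_remote * 100 %, computed from ROI means of
relaxation *times* (not rates).  Group inferential statistics are out of
scope by design; the report carries per-region summaries only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import RelaxationMap
from .phantom import ROIMask


@dataclass
class ROISummary:
    region: str
    mean: float
    sd: float
    n_pixels: int


@dataclass
class RRTDResult:
    method_label: str
    rrtd_percent: float
    t_mi: float
    t_remote: float


def roi_stats(rmap: RelaxationMap, mask: ROIMask, region: str) -> ROISummary:
    """Mean and SD of the map over valid in-region pixels."""
    if region not in mask:
        raise ValueError(f"region {region!r} not present in mask")
    if mask.shape != rmap.shape:
        raise ValueError("mask and map grids do not match")
    sel = mask[region] & rmap.fit_mask & np.isfinite(rmap.grid)
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError(f"region {region!r} has no valid pixels")
    vals = rmap.grid[sel]
    return ROISummary(region=region, mean=float(vals.mean()), sd=float(vals.std()), n_pixels=n)


def rrtd(t_mi: float, t_remote: float, method_label: str = "") -> RRTDResult:
    """(T_mi - T_remote) / T_remote * 100, in percent."""
    if t_remote <= 0:
        raise ValueError(f"t_remote must be positive, got {t_remote}")
    return RRTDResult(
        method_label=method_label,
        rrtd_percent=(t_mi - t_remote) / t_remote * 100.0,
        t_mi=t_mi,
        t_remote=t_remote,
    )


def contrast_report(
    maps: Sequence[RelaxationMap],
    mask: ROIMask,
    mi_region: str = "MI",
    remote_region: str = "remote",
) -> pd.DataFrame:
    """One row per method: T_mi +/- sd, T_remote +/- sd, RRTD %.

    Rows are ordered deterministically by method label.
    """
    rows = []
    for rmap in maps:
        if rmap.shape != mask.shape:
            raise ValueError(f"map {rmap.method_label!r} grid does not match the mask")
        s_mi = roi_stats(rmap, mask, mi_region)
        s_rem = roi_stats(rmap, mask, remote_region)
        res = rrtd(s_mi.mean, s_rem.mean, method_label=rmap.method_label)
        rows.append(
            {
                "method": rmap.method_label,
                "T_mi": s_mi.mean,
                "T_mi_sd": s_mi.sd,
                "n_mi": s_mi.n_pixels,
                "T_remote": s_rem.mean,
                "T_remote_sd": s_rem.sd,
                "n_remote": s_rem.n_pixels,
                "rrtd_percent": res.rrtd_percent,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "method", "T_mi", "T_mi_sd", "n_mi",
            "T_remote", "T_remote_sd", "n_remote", "rrtd_percent",
        ],
    )
    return df.sort_values("method", kind="stable").reset_index(drop=True)
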