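"""Synthetic short-axis cardiac phantom for relaxation mapping.

The phantom is a 192 x 192 slice holding a myocardial annulus with three
labelled regions: an infarct (MI) sector, a remote (septal) sector, and the
rest of the annulus as healthy myocardium.  Each region carries ground-truth
steady-state-model parameters (R, SS fraction, SI0); image series are the
noiseless forward model at the requested train lengths plus Gaussian or
Rician noise.  Everything is deterministic given the spec, including noise
(the seed is part of the spec).

Coordinates are row-major and 0-based; angles are measured counterclockwise
from the positive x axis (columns increase along +x, rows along -y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import ss_forward_model

#: Default MI/remote relaxation-time ratios emulating the published contrast
#: (RRTD of 18.2 / 17.0 / 12.3 % for TL0.6 / TL0.8 / TL1.0).
DEFAULT_TIME_RATIOS = {"RAFF2 TL0.6": 1.182, "RAFF2 TL0.8": 1.170, "RAFF2 TL1.0": 1.123}


@dataclass(frozen=True)
class RegionParams:
    R: float  # 1/s
    SS_fraction: float
    SI0: float = 1.0


def default_region_params(time_ratio: float = 1.123) -> dict[str, RegionParams]:
    """Ground-truth parameters with a remote relaxation time of 50 ms.

    The MI relaxation time is ``time_ratio`` times the remote time; healthy
    myocardium matches the remote region, as in an unoperated heart.
    """
    t_remote = 0.050  # s, ex vivo myocardial rotating-frame scale
    return {
        "MI": RegionParams(R=1.0 / (time_ratio * t_remote), SS_fraction=0.25),
        "remote": RegionParams(R=1.0 / t_remote, SS_fraction=0.30),
        "healthy": RegionParams(R=1.0 / t_remote, SS_fraction=0.30),
    }


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (192, 192)
    center: tuple[float, float] | None = None  # (row, col); default grid centre
    inner_radius: float = 38.0
    outer_radius: float = 68.0
    mi_sector: tuple[float, float] = (-50.0, 55.0)  # deg, anterolateral wall
    remote_sector: tuple[float, float] = (150.0, 215.0)  # deg, septum
    region_params: dict[str, RegionParams] = field(default_factory=default_region_params)
    noise_sigma: float = 0.0  # fraction of SI0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius <= 0 or self.outer_radius <= self.inner_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if _sectors_overlap(self.mi_sector, self.remote_sector):
            raise ValueError("MI and remote sectors must be disjoint")
        for key in ("MI", "remote", "healthy"):
            if key not in self.region_params:
                raise ValueError(f"region_params must define {key!r}")


def _norm_deg(a: float) -> float:
    return a % 360.0


def _in_sector(theta: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    lo, hi = _norm_deg(sector[0]), _norm_deg(sector[1])
    if lo <= hi:
        return (theta >= lo) & (theta < hi)
    return (theta >= lo) | (theta < hi)


def _sectors_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    grid = np.arange(0.0, 360.0, 0.25)
    return bool(np.any(_in_sector(grid, a) & _in_sector(grid, b)))


@dataclass
class ROIMask:
    """Disjoint boolean region masks over the phantom grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one shape")
        total = None
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[name] = m
            overlap = m if total is None else (total & m)
            if total is not None and np.any(overlap):
                raise ValueError("region masks must be disjoint")
            total = m if total is None else (total | m)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def regions(self) -> list[str]:
        return list(self.masks)


def make_phantom(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], ROIMask]:
    """Ground-truth parameter grids (R, SS, SI0) and region masks."""
    rows, cols = spec.shape
    cr, cc = spec.center if spec.center is not None else ((rows - 1) / 2, (cols - 1) / 2)
    rr, cc_idx = np.mgrid[0:rows, 0:cols]
    x = cc_idx - cc
    y = cr - rr  # +y up
    radius = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0

    annulus = (radius >= spec.inner_radius) & (radius < spec.outer_radius)
    mi = annulus & _in_sector(theta, spec.mi_sector)
    remote = annulus & _in_sector(theta, spec.remote_sector)
    healthy = annulus & ~mi & ~remote
    background = ~annulus

    masks = ROIMask(
        {"MI": mi, "remote": remote, "healthy_whole": healthy, "background": background}
    )

    grids = {
        "R": np.zeros(spec.shape),
        "SS": np.zeros(spec.shape),
        "SI0": np.zeros(spec.shape),
    }
    region_to_param = {"MI": mi, "remote": remote, "healthy": healthy}
    for name, region_mask in region_to_param.items():
        p = spec.region_params[name]
        grids["R"][region_mask] = p.R
        grids["SS"][region_mask] = p.SS_fraction
        grids["SI0"][region_mask] = p.SI0
    return grids, masks


def synthesize_series(
    spec: PhantomSpec, times, polarity: str = "both"
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Relaxation-weighted image series from the steady-state forward model.

    Returns a (time, rows, cols) stack for polarity '+Z' or '-Z', or the
    (+Z, -Z) pair for 'both'.  Noise is added per the spec's noise model:
    Gaussian directly on the signal, or Rician via Gaussian noise on the
    real and imaginary channels before the magnitude.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if polarity not in ("+Z", "-Z", "both"):
        raise ValueError(f"invalid polarity {polarity!r}")
    grids, _ = make_phantom(spec)
    e = np.exp(-np.multiply.outer(times, grids["R"]))  # (t, r, c)
    plateau = grids["SS"] * grids["SI0"]
    stacks = {
        "+Z": grids["SI0"] * e + plateau * (1 - e),
        "-Z": -grids["SI0"] * e + plateau * (1 - e),
    }
    rng = np.random.default_rng(spec.seed)
    out = {}
    for pol in ("+Z", "-Z"):
        stack = stacks[pol]
        if spec.noise_sigma > 0:
            sigma = spec.noise_sigma  # fraction of unit SI0
            if spec.noise_model == "gaussian":
                stack = stack + rng.normal(0.0, sigma, stack.shape)
            else:
                re = stack + rng.normal(0.0, sigma, stack.shape)
                im = rng.normal(0.0, sigma, stack.shape)
                stack = np.sign(re) * np.hypot(re, im)
        out[pol] = stack
    if polarity == "both":
        return out["+Z"], out["-Z"]
    return out[polarity]
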