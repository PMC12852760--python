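"""Relaxation model fitting: dual-polarity steady-state fit, monoexponential
decay, B1 nutation, and pixel-wise relaxation mapping.

The steady-state model for periodic irradiation is

    SI_{+/-Z}(t) = SI_{0,+/-Z} exp(-R t) - S_SS (1 - exp(-R t))

fitted jointly to the two acquisitions that start from +z and -z.  Both
curves share the relaxation rate R and the asymptote: the driven steady
state of the spin system does not depend on the initial polarity, so the
-S_SS term is one common plateau.  The reported steady-state fraction is
SS = plateau / SI_{0,+Z}, a number in (0, 1] for a decay that levels off
above zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dynamics import DecayCurve
from .waveforms import TWO_PI

_R_BOUNDS = (0.0, 1e4)  # 1/s


@dataclass
class SSFitResult:
    R: float  # 1/s
    SI0_plus: float
    SI0_minus: float
    S_SS: float  # printed-form parameter; the common plateau is -S_SS
    residual_norm: float
    converged: bool

    @property
    def plateau(self) -> float:
        return -self.S_SS

    @property
    def SS_fraction(self) -> float:
        return self.plateau / self.SI0_plus


@dataclass
class MonoexpFitResult:
    T: float  # s
    S0: float
    residual_norm: float
    converged: bool

    @property
    def R(self) -> float:
        return 1.0 / self.T


@dataclass
class RelaxationMap:
    """Per-pixel fitted parameter over an image grid."""

    grid: np.ndarray
    method_label: str
    units: str
    fit_mask: np.ndarray
    companion: np.ndarray | None = None  # e.g. the SS-fraction map

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if self.grid.shape != self.fit_mask.shape:
            raise ValueError("grid and fit_mask shapes must match")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


def _init_rate(t: np.ndarray, s: np.ndarray) -> float:
    """Log-linear rate estimate from the first and last positive samples."""
    s0, s1 = s[0], s[-1]
    if s0 > 0 and s1 > 0 and s1 < s0 and t[-1] > 0:
        return float(np.log(s0 / s1) / t[-1])
    return 1.0 / max(t[-1], 1e-9)


def fit_ss_model(
    curve_plus: DecayCurve,
    curve_minus: DecayCurve,
    init: tuple[float, float, float, float] | None = None,
) -> SSFitResult:
    """Joint least-squares fit of the dual-polarity steady-state model.

    Initialization is deterministic: R from a log-linear estimate of the +Z
    curve (plus a fixed small multi-start ladder), the plateau from the tail
    of the +Z curve.  Non-convergence is flagged on the result, not raised.
    """
    tp, tm = curve_plus.times, curve_minus.times
    if tp.size < 3:
        raise ValueError("need at least 3 time points")
    if tp.shape != tm.shape or not np.allclose(tp, tm):
        raise ValueError("curves must share the same time grid")
    sp, sm = curve_plus.signal, curve_minus.signal

    def resid(x: np.ndarray) -> np.ndarray:
        R, a, b, plateau = x
        e = np.exp(-R * tp)
        return np.concatenate(
            [a * e + plateau * (1 - e) - sp, b * e + plateau * (1 - e) - sm]
        )

    scale = max(abs(sp[0]), abs(sm[0]), 1e-12)
    lo = [_R_BOUNDS[0], -4 * scale, -4 * scale, -4 * scale]
    hi = [_R_BOUNDS[1], 4 * scale, 4 * scale, 4 * scale]
    starts: list[np.ndarray]
    if init is not None:
        starts = [np.clip(np.asarray(init, dtype=float), lo, hi)]
    else:
        r0 = _init_rate(tp, np.abs(sp))
        plateau0 = float(np.mean(sp[-max(3, tp.size // 4):]))
        starts = [
            np.clip([r, sp[0], sm[0], plateau0], lo, hi)
            for r in (r0, 0.5, 2.0, 8.0, 32.0)
        ]
    best = None
    for x0 in starts:
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < (1e-10 * scale) ** 2 * tp.size:  # already at machine-level fit
            break
    R, a, b, plateau = best.x
    return SSFitResult(
        R=float(R),
        SI0_plus=float(a),
        SI0_minus=float(b),
        S_SS=float(-plateau),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


def ss_forward_model(
    times: np.ndarray, R: float, SS_fraction: float, SI0: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless +Z and -Z signals of the steady-state model.

    The shared plateau is SS_fraction * SI0; the -Z curve starts at -SI0
    and recovers toward the same plateau.
    """
    times = np.asarray(times, dtype=float)
    e = np.exp(-R * times)
    plateau = SS_fraction * SI0
    return SI0 * e + plateau * (1 - e), -SI0 * e + plateau * (1 - e)


def fit_monoexp(curve: DecayCurve) -> MonoexpFitResult:
    """Least-squares fit of S0 * exp(-t / T) to a single decay curve."""
    t, s = curve.times, curve.signal
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.all(s == 0):
        raise ValueError("signal is identically zero")
    if np.any(s <= 0):
        raise ValueError("monoexponential fit requires positive signals")

    r0 = _init_rate(t, s)

    def resid(x: np.ndarray) -> np.ndarray:
        R, s0 = x
        return s0 * np.exp(-R * t) - s

    best = None
    for r in (r0, r0 * 4, r0 / 4):
        sol = least_squares(
            resid,
            [max(r, 1e-9), s[0]],
            bounds=([1e-9, 0.0], [1e9, 10 * abs(s[0]) + 1e-9]),
            xtol=1e-14,
            ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    R, s0 = best.x
    at_bound = R <= 2e-9 or R >= 1e9 / 2
    return MonoexpFitResult(
        T=float(1.0 / R),
        S0=float(s0),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success and not at_bound),
    )


def fit_b1_nutation(durations, signals) -> float:
    """Fit a cosinusoidal nutation S(t) = A cos(2 pi f t) + c; return f in Hz.

    Needs at least 4 samples spanning roughly half a nutation period.
    """
    t = np.asarray(durations, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples for a nutation fit")

    # coarse frequency from the densely zero-padded spectrum
    dt = np.median(np.diff(np.sort(t)))
    n = 1 << 12
    spec = np.abs(np.fft.rfft(s - s.mean(), n))
    freqs = np.fft.rfftfreq(n, dt)
    f0 = float(freqs[np.argmax(spec[1:]) + 1])
    if f0 <= 0:
        f0 = 0.25 / (t.max() - t.min())

    def resid(x: np.ndarray) -> np.ndarray:
        A, f, c = x
        return A * np.cos(TWO_PI * f * t) + c - s

    best = None
    for f_try in (f0, f0 * 0.5, f0 * 2.0):
        sol = least_squares(resid, [np.ptp(s) / 2, f_try, s.mean()], xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return float(abs(best.x[1]))


def fit_map(
    image_stack: np.ndarray,
    times,
    model: str = "monoexp",
    mask: np.ndarray | None = None,
    paired_stack: np.ndarray | None = None,
    method_label: str = "",
) -> RelaxationMap:
    """Pixel-by-pixel relaxation fit over an image time series.

    ``image_stack`` is (time, rows, cols).  For ``model='ss_model'`` a
    ``paired_stack`` holding the -Z acquisition is required and the map
    value is the relaxation time 1/R with the SS-fraction as companion map;
    for ``model='monoexp'`` the map value is the time constant T.  Pixels
    outside the mask (or where fitting fails) are NaN with fit_mask False.
    """
    stack = np.asarray(image_stack, dtype=float)
    times = np.asarray(times, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != times.size:
        raise ValueError("image_stack must be (time, rows, cols) matching times")
    shape = stack.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match image shape")
    if model not in ("monoexp", "ss_model"):
        raise ValueError(f"unknown model {model!r}")
    if model == "ss_model":
        if paired_stack is None:
            raise ValueError("ss_model requires the paired -Z stack")
        paired = np.asarray(paired_stack, dtype=float)
        if paired.shape != stack.shape:
            raise ValueError("paired_stack shape must match image_stack")

    grid = np.full(shape, np.nan)
    companion = np.full(shape, np.nan) if model == "ss_model" else None
    ok = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(mask)):
        try:
            if model == "monoexp":
                fit = fit_monoexp(
                    DecayCurve(times, stack[:, r, c], polarity="+Z")
                )
                if not fit.converged:
                    continue
                grid[r, c] = fit.T
            else:
                fit = fit_ss_model(
                    DecayCurve(times, stack[:, r, c], polarity="+Z"),
                    DecayCurve(times, paired[:, r, c], polarity="-Z"),
                )
                if not fit.converged or fit.R <= 0:
                    continue
                grid[r, c] = 1.0 / fit.R
                companion[r, c] = fit.SS_fraction
            ok[r, c] = True
        except (ValueError, FloatingPointError):
            continue
    return RelaxationMap(
        grid=grid,
        method_label=method_label or model,
        units="s",
        fit_mask=ok,
        companion=companion,
    )
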