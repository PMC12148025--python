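"""Photobleaching kinetics: ROI traces and single-exponential decay fits.

Under continuous illumination the fluorescence of a cell (or of a single
nanocage — the kinetics are the same) decays approximately as a single
exponential. The half-life t_1/2 = ln 2 / k is the standard photostability
figure. The fitted model is

    I(t) = (1 - c) * exp(-k t) + c

on the first-frame-normalized trace, where the plateau c absorbs
non-bleaching background (bounded to [0, 0.5]; c is fixed to 0 when the
plateau is disabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["BleachCurve", "BleachFit", "roi_mean_trace", "fit_decay", "compare_half_lives"]


@dataclass
class BleachCurve:
    """First-frame-normalized mean-ROI intensity over time."""

    times: np.ndarray  # s, strictly increasing, times[0] = 0
    intensities: np.ndarray  # normalized, intensities[0] = 1
    roi_id: str = "cell0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class BleachFit:
    rate: float  # k, s^-1
    half_life: float  # ln2 / k, s
    plateau: float
    r_squared: float
    status: str  # ok | failed


def roi_mean_trace(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    camera_offset: float,
    frame_interval: float,
    roi_id: str = "cell0",
) -> BleachCurve:
    """Offset-subtracted, first-frame-normalized mean intensity in an ROI.

    The camera offset is removed before normalization — leaving it in biases
    the fitted rate low. Frame f is assigned time ``f * frame_interval``
    (first exposure = t 0).
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("roi_mask is empty")
    if stack.ndim != 3 or stack.shape[0] < 5:
        raise ValueError("stack must be 3D with >= 5 frames")
    trace = stack[:, mask].mean(axis=1) - camera_offset
    if trace[0] <= 0:
        raise ValueError("first-frame ROI mean is <= 0 after offset subtraction")
    times = np.arange(stack.shape[0]) * frame_interval
    return BleachCurve(times=times, intensities=trace / trace[0], roi_id=roi_id)


def fit_decay(curve: BleachCurve, with_plateau: bool = True) -> BleachFit:
    """Least-squares single-exponential fit of a normalized bleaching curve.

    Returns rate k, half-life ln2/k, plateau (0 when disabled) and R^2.
    Non-convergence, a non-positive rate, or a decay too shallow to be
    identified (< 1% over the observation window) give ``status='failed'``
    with the best-effort parameters attached.
    """
    t, y = curve.times, curve.intensities
    if t.size < 5:
        raise ValueError("need at least 5 points to fit a decay")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    span = t[-1] - t[0]
    # log-linear initial rate estimate over the early decay
    head = max(3, t.size // 4)
    slope = np.polyfit(t[:head], np.log(y[:head]), 1)[0]
    k0 = max(-slope, 1e-6 / span)

    if with_plateau:
        model = lambda t, k, c: (1.0 - c) * np.exp(-k * t) + c
        p0, bounds = [k0, 0.0], ([1e-12, 0.0], [np.inf, 0.5])
    else:
        model = lambda t, k: np.exp(-k * t)
        p0, bounds = [k0], ([1e-12], [np.inf])
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except Exception:
        return BleachFit(math.nan, math.nan, math.nan, math.nan, "failed")
    k = float(popt[0])
    c = float(popt[1]) if with_plateau else 0.0
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    half = math.log(2.0) / k if k > 0 else math.inf
    status = "ok"
    if k <= 0 or k * span < 0.01:  # < 1% decay over the window: no decay seen
        status = "failed"
    return BleachFit(rate=k, half_life=half, plateau=c, r_squared=r2, status=status)


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Box-plot summary: median, quartiles (linear interpolation), whiskers
    at the most extreme observations within 1.5 IQR of the quartiles."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr]
    hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(lo[0]), "whisker_high": float(hi[-1]),
    }


def compare_half_lives(half_lives_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group summary of photobleaching half-lives.

    Input maps group label (FP name) to an array of per-cell half-lives
    (>= 3 each, >= 2 groups). Output has one row per group with n, mean, SD
    and box-plot statistics.
    """
    if len(half_lives_by_group) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for name in sorted(half_lives_by_group):
        v = np.asarray(half_lives_by_group[name], dtype=float)
        if v.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 fits")
        rows.append({
            "group": name, "n": int(v.size),
            "mean_s": float(v.mean()), "sd_s": float(v.std(ddof=1)),
            **{f"{k}_s": val for k, val in boxplot_stats(v).items()},
        })
    return pd.DataFrame(rows)
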