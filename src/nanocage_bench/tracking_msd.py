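"""Particle tracking and MSD-based diffusion estimation.

Fast (85 frames/s) TIRF series of diffusing nanocages are analyzed in four
steps: local-maximum detection with sub-pixel Gaussian refinement;
frame-to-frame linking by optimal assignment under a hard displacement gate
(no gap closing, merging or splitting); a track-length filter keeping tracks
longer than 20 and shorter than 250 frames; and a per-cell time-averaged
mean-square-displacement curve whose initial 25% is fitted by a line with
free intercept — for 2D Brownian motion MSD(dt) = 4 D dt, so D = slope / 4.
The free intercept absorbs static localization error and motion-blur
offsets, which shift the MSD curve but not its slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .spot_quant import fit_spot
from .synthetic_data import OpticsModel

__all__ = [
    "Track",
    "MSDCurve",
    "DiffusionEstimate",
    "detect_spots",
    "link_tracks",
    "filter_tracks",
    "tracks_from_positions",
    "msd_per_cell",
    "fit_diffusion",
    "default_max_disp",
]


@dataclass
class Track:
    """One gap-free particle trajectory (pixel coordinates, frame indices
    strictly consecutive)."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.frames.size == self.x.size == self.y.size):
            raise ValueError("frames, x, y must have equal length")
        if self.frames.size >= 2 and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def length(self) -> int:
        return int(self.frames.size)


@dataclass
class MSDCurve:
    """Per-cell averaged time-lag MSD: lags in s (starting at one frame
    interval), MSD in um^2, displacement-pair counts per lag."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    n_tracks: int


@dataclass
class DiffusionEstimate:
    D: float  # um^2 s^-1, slope / 4
    slope: float  # um^2 s^-1
    intercept: float  # um^2
    fit_fraction: float
    n_lags_fit: int
    cell_id: str = "cell0"
    status: str = "ok"  # 'negative_slope' flags an unphysical fit


def detect_spots(
    frame: np.ndarray,
    min_snr: float,
    optics: OpticsModel,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect sub-diffraction particles in one frame.

    Local maxima above (background median + min_snr * robust noise SD,
    noise SD from the median absolute deviation) are refined to sub-pixel
    positions by a single-Gaussian fit in a small window; detections closer
    than one PSF sigma are merged keeping the brighter one. Returns a
    DataFrame with columns frame, x, y, intensity (may be empty).
    """
    from skimage.feature import peak_local_max

    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    sigma = optics.psf_sigma_px
    bg = float(np.median(frame))
    noise_sd = 1.4826 * float(np.median(np.abs(frame - bg)))
    thresh = bg + min_snr * max(noise_sd, 1e-12)
    peaks = peak_local_max(
        frame, min_distance=max(1, int(round(sigma))), threshold_abs=thresh
    )
    window = max(3, int(round(3.0 * sigma)))
    rows = []
    for py, px in peaks:
        fit = fit_spot(frame, (float(px), float(py)), window, expected_sigma=sigma)
        if fit.status == "ok":
            rows.append((frame_index, fit.x0, fit.y0, fit.amplitude))
    det = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"])
    if len(det) > 1:  # merge duplicates within 1 PSF sigma
        det = det.sort_values("intensity", ascending=False).reset_index(drop=True)
        tree = cKDTree(det[["x", "y"]].to_numpy())
        keep = np.ones(len(det), dtype=bool)
        for i in range(len(det)):
            if not keep[i]:
                continue
            for j in tree.query_ball_point(det.loc[i, ["x", "y"]].to_numpy(), sigma):
                if j != i and keep[j] and j > i:
                    keep[j] = False
        det = det[keep].sort_values(["y", "x"]).reset_index(drop=True)
    det["frame"] = det["frame"].astype(int)
    return det


def default_max_disp(optics: OpticsModel, d_prior: float = 1.0) -> float:
    """Displacement gate in px: 5 sigma of the expected 2D frame-to-frame
    step for a Brownian prior D (um^2/s), 5*sqrt(4 D dt)/pixel_size."""
    step_um = math.sqrt(4.0 * d_prior * optics.frame_interval)
    return 5.0 * step_um * 1000.0 / optics.pixel_size


def link_tracks(detections: pd.DataFrame, max_disp: float) -> list[Track]:
    """Greedy-over-frames optimal linking of detections into tracks.

    For each consecutive frame pair, an optimal bipartite assignment
    minimizes the total squared displacement; links longer than ``max_disp``
    px are forbidden. Unmatched detections start new tracks; a missed
    detection terminates its track (no gap closing).
    """
    req = {"frame", "x", "y"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    if len(detections) == 0:
        return []
    frames = np.arange(int(detections["frame"].min()), int(detections["frame"].max()) + 1)
    by_frame = {
        int(f): g[["x", "y"]].to_numpy(dtype=float)
        for f, g in detections.groupby("frame")
    }
    # active[i] = (track points list) for detection i of the previous frame
    tracks_done: list[list[tuple[int, float, float]]] = []
    prev_pts = by_frame.get(int(frames[0]), np.empty((0, 2)))
    active = [[(int(frames[0]), float(x), float(y))] for x, y in prev_pts]
    for f in frames[1:]:
        cur_pts = by_frame.get(int(f), np.empty((0, 2)))
        n_prev, n_cur = len(prev_pts), len(cur_pts)
        link_prev = np.full(n_cur, -1, dtype=int)
        if n_prev and n_cur:
            diff = prev_pts[:, None, :] - cur_pts[None, :, :]
            cost = np.einsum("ijk,ijk->ij", diff, diff)
            gate = max_disp * max_disp
            big = 1e12
            cost = np.where(cost <= gate, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < big:
                    link_prev[j] = i
        next_active: list[list[tuple[int, float, float]]] = []
        matched_prev = set(link_prev[link_prev >= 0].tolist())
        for i, tr in enumerate(active):
            if i not in matched_prev:
                tracks_done.append(tr)
        for j, (x, y) in enumerate(cur_pts):
            if link_prev[j] >= 0:
                tr = active[link_prev[j]]
                tr.append((int(f), float(x), float(y)))
                next_active.append(tr)
            else:
                next_active.append([(int(f), float(x), float(y))])
        active = next_active
        prev_pts = cur_pts
    tracks_done.extend(active)
    out = []
    for tid, pts in enumerate(tracks_done):
        if len(pts) < 2:
            continue
        arr = np.asarray(pts, dtype=float)
        out.append(Track(track_id=tid, frames=arr[:, 0].astype(int), x=arr[:, 1], y=arr[:, 2]))
    return out


def filter_tracks(
    tracks: list[Track], min_frames: int = 20, max_frames: int = 250
) -> list[Track]:
    """Keep tracks strictly longer than ``min_frames`` and strictly shorter
    than ``max_frames`` (boundaries excluded: 20 and 250 are dropped, 21 and
    249 kept with the defaults)."""
    return [t for t in tracks if min_frames < t.length < max_frames]


def tracks_from_positions(positions: np.ndarray, start_frame: int = 0) -> list[Track]:
    """Build Track objects from an array of per-frame positions, shape
    (n_particles, n_frames, 2) with last axis (y, x) — e.g. simulated
    ground-truth trajectories sampled at frame times."""
    positions = np.asarray(positions, dtype=float)
    n_particles, n_frames, _ = positions.shape
    frames = np.arange(start_frame, start_frame + n_frames)
    return [
        Track(track_id=p, frames=frames, x=positions[p, :, 1], y=positions[p, :, 0])
        for p in range(n_particles)
    ]


def msd_per_cell(tracks: list[Track], optics: OpticsModel) -> MSDCurve:
    """Pair-count-weighted average of per-track time-averaged MSD curves.

    Each track contributes, at lag j frames, the mean squared displacement
    over all of its ``length - j`` ordered (overlapping) position pairs;
    tracks are averaged with weights equal to those pair counts. Positions
    are converted from pixels to um before squaring; lags are reported in
    seconds starting at one frame interval.
    """
    if not tracks:
        raise ValueError("no tracks to analyze")
    px_um = optics.pixel_size / 1000.0
    max_lag = max(t.length for t in tracks) - 1
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for t in tracks:
        pos = np.column_stack([t.x, t.y]) * px_um
        n = t.length
        for j in range(1, n):
            d = pos[j:] - pos[:-j]
            sums[j] += float(np.einsum("ij,ij->", d, d))
            counts[j] += n - j
    valid = counts[1:] > 0
    lags_f = np.arange(1, max_lag + 1)[valid]
    msd = sums[1:][valid] / counts[1:][valid]
    return MSDCurve(
        lags=lags_f * optics.frame_interval,
        msd=msd,
        n_pairs=counts[1:][valid],
        n_tracks=len(tracks),
    )


def fit_diffusion(
    msd: MSDCurve,
    fit_fraction: float = 0.25,
    zero_intercept: bool = False,
    cell_id: str = "cell0",
) -> DiffusionEstimate:
    """Diffusion coefficient from the initial part of an MSD curve.

    Ordinary least squares of MSD against lag over the first
    ``ceil(fit_fraction * n_lags)`` lags (minimum 2), free intercept by
    default; D = slope / 4 for 2D Brownian motion. A negative slope is
    reported with status ``negative_slope``.
    """
    n_lags = msd.lags.size
    n_fit = max(2, math.ceil(fit_fraction * n_lags))
    if n_lags < 2 or n_fit > n_lags:
        raise ValueError("need at least 2 lags in the fitted prefix")
    x, y = msd.lags[:n_fit], msd.msd[:n_fit]
    if zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        res = linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    return DiffusionEstimate(
        D=slope / 4.0,
        slope=slope,
        intercept=intercept,
        fit_fraction=fit_fraction,
        n_lags_fit=n_fit,
        cell_id=cell_id,
        status="ok" if slope >= 0 else "negative_slope",
    )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tabulate tracks as (track_id, frame, x_px, y_px) rows for CSV export."""
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), float(x), float(y)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])
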