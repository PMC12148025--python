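"""Synthetic live-cell microscopy of FP-tagged protein nanocages.

This module generates ground-truth-annotated image stacks that emulate cells
expressing fluorescent-protein (FP) nanocages: sub-diffraction particles
carrying a fixed number of FPs (60 for a single tag, 120 for a tandem tag)
that diffuse in the cytoplasm, photobleach exponentially, and are imaged
either on a spinning-disc confocal (small pixels, long exposure — motion
blur) or a TIRF system (large pixels, fast frames — trackable particles).

The forward model per frame is:

    expected photons per particle = n_fp * photons_per_fp * exposure
                                    * mean over exposure of 2^(-t / t_half)

distributed over ``n_blur_substeps`` positions sampled along the Brownian
path during the exposure, each stamped as a pixel-integrated Gaussian PSF.
Poisson shot noise acts on photons; camera gain, Gaussian read noise, offset
and saturation clipping follow. Rendering returns float64 counts clipped to
the camera range; quantization to 16-bit happens only on TIFF export.

Coordinate convention: 0-based pixel-center coordinates; arrays are indexed
``[row, col]`` = (y, x); all public tables use explicit ``x_px`` / ``y_px``
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "OpticsModel",
    "CameraModel",
    "CageSpec",
    "MotionSpec",
    "SimulationScene",
    "CONFOCAL_OPTICS",
    "TIRF_OPTICS",
    "DEFAULT_CAMERA",
    "FP_LIBRARY",
    "simulate_tracks",
    "render_stack",
    "simulate_bleach_movie",
    "elliptical_cell_mask",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class OpticsModel:
    """Imaging-side parameters of one acquisition configuration.

    Parameters
    ----------
    pixel_size : float
        Effective pixel size in nm (27 nm for the confocal/SoRa configuration,
        110 nm for the TIRF configuration).
    psf_fwhm : float
        Full width at half maximum of the Gaussian PSF approximation, nm.
        A value near 200 nm puts spots close to the resolution limit.
    exposure : float
        Exposure time per frame, s.
    frame_interval : float
        Time between frame starts, s; must be >= exposure.
    n_blur_substeps : int
        Number of particle positions sampled within one exposure to render
        motion blur.
    """

    pixel_size: float
    psf_fwhm: float
    exposure: float
    frame_interval: float
    n_blur_substeps: int = 10

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not (self.psf_fwhm > 0 and np.isfinite(self.psf_fwhm)):
            raise ValueError(f"psf_fwhm must be positive, got {self.psf_fwhm}")
        if not (0 < self.exposure <= self.frame_interval):
            raise ValueError(
                f"need 0 < exposure <= frame_interval, got exposure={self.exposure}, "
                f"frame_interval={self.frame_interval}"
            )
        if self.n_blur_substeps < 1:
            raise ValueError("n_blur_substeps must be >= 1")

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm / _FWHM_PER_SIGMA

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size


@dataclass(frozen=True)
class CameraModel:
    """sCMOS/EMCCD-style camera abstraction (counts = gain * photons + noise)."""

    offset: float = 100.0
    read_noise_sd: float = 1.5
    counts_per_photon: float = 1.0
    max_count: float = 65535.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.counts_per_photon <= 0:
            raise ValueError("counts_per_photon must be > 0")
        if self.max_count <= self.offset:
            raise ValueError("max_count must exceed offset")


@dataclass(frozen=True)
class CageSpec:
    """One nanocage construct: FP copy number, photon rate, photostability.

    ``photons_per_fp`` is the expected detected photon rate per FP molecule
    at the (fixed) benchmark irradiance; it is a free scale parameter of the
    simulation, not a physical irradiance mapping. ``bleach_half_life`` may
    be ``math.inf`` for a non-bleaching construct.
    """

    n_fp: int = 60
    photons_per_fp: float = 100.0
    bleach_half_life: float = math.inf

    def __post_init__(self) -> None:
        if self.n_fp < 1:
            raise ValueError("n_fp must be >= 1")
        if self.photons_per_fp < 0 or not np.isfinite(self.photons_per_fp):
            raise ValueError("photons_per_fp must be finite and >= 0")
        if not self.bleach_half_life > 0:
            raise ValueError("bleach_half_life must be > 0")


@dataclass(frozen=True)
class MotionSpec:
    """Brownian-motion parameters for intracellular nanocage diffusion."""

    diffusion_coefficient: float = 1.0  # um^2/s; ~1 for a 26 nm cage in cytoplasm
    field_size: tuple[int, int] = (64, 64)  # (height, width) px
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        d = self.diffusion_coefficient
        if not np.isfinite(d) or d < 0:
            raise ValueError(f"diffusion_coefficient must be finite and >= 0, got {d}")
        if min(self.field_size) < 16:
            raise ValueError("field dimensions must be >= 16 px")
        if self.boundary not in ("reflecting", "periodic"):
            raise ValueError("boundary must be 'reflecting' or 'periodic'")


@dataclass
class SimulationScene:
    """Everything needed to re-render one synthetic acquisition.

    ``tracks`` has shape (n_particles, n_frames, n_blur_substeps, 2) with the
    last axis ordered (y, x) in pixel units; ``times`` has shape
    (n_frames, n_blur_substeps) in seconds from the start of the first
    exposure. A fixed ``seed`` re-renders bit-identically.
    """

    tracks: np.ndarray
    times: np.ndarray
    cage: CageSpec
    optics: OpticsModel
    camera: CameraModel
    motion: MotionSpec
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.tracks, dtype=float)
        if t.ndim != 4 or t.shape[3] != 2:
            raise ValueError("tracks must have shape (n_particles, n_frames, n_substeps, 2)")
        if t.shape[1:3] != np.asarray(self.times).shape:
            raise ValueError("times must have shape (n_frames, n_substeps)")
        if not np.all(np.isfinite(t)):
            raise ValueError("every particle needs a finite position at every sub-step")

    @property
    def n_particles(self) -> int:
        return self.tracks.shape[0]

    @property
    def n_frames(self) -> int:
        return self.tracks.shape[1]


# Acquisition configurations used throughout the benchmark. Confocal: 27 nm
# effective pixels, 500 ms exposures; TIRF: 110 nm pixels at 85 frames/s.
CONFOCAL_OPTICS = OpticsModel(
    pixel_size=27.0, psf_fwhm=200.0, exposure=0.5, frame_interval=0.5
)
TIRF_OPTICS = OpticsModel(
    pixel_size=110.0, psf_fwhm=200.0, exposure=0.01, frame_interval=1.0 / 85.0
)
DEFAULT_CAMERA = CameraModel()

# Synthetic FP panel. Photon rates are expressed as folds of the channel
# reference (EGFP for green, mCherry for red) times a common base rate;
# half-lives are representative single-exponential photobleaching half-lives
# under the benchmark irradiance. These define the simulated conditions for
# the analysis scripts; they are inputs, not measurements.
_BASE_RATE = 100.0  # photons s^-1 per FP for the green reference


def _fp(fold: float, half_life: float) -> CageSpec:
    return CageSpec(n_fp=60, photons_per_fp=fold * _BASE_RATE, bleach_half_life=half_life)


FP_LIBRARY: dict[str, CageSpec] = {
    "EGFP": _fp(1.0, 23.0),
    "mEmerald": _fp(1.0, 25.0),
    "mStayGold": _fp(3.0, 60.0),
    "mBaoJin": _fp(2.8, 20.0),
    "StayGold-E138D": _fp(2.5, 55.0),
    # red channel, folds relative to mCherry (itself dimmer than EGFP here)
    "mCherry": _fp(0.6, 21.0),
    "mScarlet-I": _fp(0.6 * 1.6, 5.4),
    "mScarlet3": _fp(0.6 * 1.9, 6.5),
    "mScarlet3-H": _fp(0.6, 18.0),
    "mRuby3": _fp(0.6, 21.0),
}


def _apply_boundary(pos: np.ndarray, size: float, mode: str) -> np.ndarray:
    """Fold 1D positions back into [-0.5, size - 0.5) (pixel-center field)."""
    lo, hi = -0.5, size - 0.5
    span = hi - lo
    if mode == "periodic":
        return lo + np.mod(pos - lo, span)
    # reflecting: triangle-wave fold with period 2*span
    q = np.mod(pos - lo, 2.0 * span)
    return lo + np.where(q > span, 2.0 * span - q, q)


def simulate_tracks(
    motion: MotionSpec,
    n_particles: int,
    n_frames: int,
    optics: OpticsModel,
    seed: int,
    init_margin_px: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate Brownian nanocage trajectories on the sub-step time grid.

    Positions are sampled at ``n_blur_substeps`` instants within each
    exposure (at ``t_frame + (j + 1/2) * exposure / n_sub``); the gap to the
    next frame's first sub-step is covered by a single Brownian step of the
    appropriate duration, so displacements between *any* two sampled instants
    have the exact per-axis variance ``2 * D * dt``.

    Returns
    -------
    tracks : ndarray, shape (n_particles, n_frames, n_substeps, 2)
        Pixel coordinates, last axis (y, x).
    times : ndarray, shape (n_frames, n_substeps)
        Seconds from the start of the first exposure.

    Per-particle random sub-streams are derived from the master seed, so a
    particle's path does not depend on how many particles are simulated.
    """
    if n_particles < 1 or n_frames < 1:
        raise ValueError("n_particles and n_frames must be >= 1")
    d = motion.diffusion_coefficient  # validated by MotionSpec
    n_sub = optics.n_blur_substeps
    px_um = optics.pixel_size / 1000.0

    sub_offsets = (np.arange(n_sub) + 0.5) * (optics.exposure / n_sub)
    times = np.arange(n_frames)[:, None] * optics.frame_interval + sub_offsets[None, :]
    flat_t = times.ravel()
    dts = np.diff(flat_t)  # elapsed time between consecutive sampled instants
    step_sd_px = np.sqrt(2.0 * d * dts) / px_um  # per-axis, pixels

    h, w = motion.field_size
    tracks = np.empty((n_particles, n_frames * n_sub, 2), dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_particles)
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        y0 = rng.uniform(-0.5 + init_margin_px, h - 0.5 - init_margin_px)
        x0 = rng.uniform(-0.5 + init_margin_px, w - 0.5 - init_margin_px)
        steps = rng.standard_normal((flat_t.size - 1, 2)) * step_sd_px[:, None]
        path = np.concatenate([[[y0, x0]], steps]).cumsum(axis=0)
        path[:, 0] = _apply_boundary(path[:, 0], h, motion.boundary)
        path[:, 1] = _apply_boundary(path[:, 1], w, motion.boundary)
        tracks[p] = path
    return tracks.reshape(n_particles, n_frames, n_sub, 2), times


def _stamp_psf(
    frame: np.ndarray, y0: float, x0: float, sigma_px: float, photons: float
) -> None:
    """Add a pixel-integrated Gaussian of total mass ``photons`` in place."""
    h, w = frame.shape
    r = int(math.ceil(5.0 * sigma_px)) + 1
    iy0, ix0 = int(round(y0)), int(round(x0))
    ylo, yhi = max(0, iy0 - r), min(h, iy0 + r + 1)
    xlo, xhi = max(0, ix0 - r), min(w, ix0 + r + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    ys = np.arange(ylo, yhi)
    xs = np.arange(xlo, xhi)
    # mass of a unit Gaussian inside each pixel: product of 1D erf differences
    wy = ndtr((ys + 0.5 - y0) / sigma_px) - ndtr((ys - 0.5 - y0) / sigma_px)
    wx = ndtr((xs + 0.5 - x0) / sigma_px) - ndtr((xs - 0.5 - x0) / sigma_px)
    frame[ylo:yhi, xlo:xhi] += photons * np.outer(wy, wx)


def _apply_camera(
    expected_photons: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator | None,
    noise: bool,
) -> np.ndarray:
    if noise:
        assert rng is not None
        photons = rng.poisson(expected_photons).astype(float)
        counts = photons * camera.counts_per_photon + camera.offset
        if camera.read_noise_sd > 0:
            counts += rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    else:
        counts = expected_photons * camera.counts_per_photon + camera.offset
    return np.clip(counts, 0.0, camera.max_count)


def render_stack(
    scene: SimulationScene, noise: bool = True
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene into an image stack plus its ground-truth table.

    Each particle contributes, per frame, an exposure-averaged photon budget
    (its 60-or-so FPs times the per-FP rate, decayed by the photobleaching
    half-life) split evenly in time across the blur sub-steps and stamped as
    a pixel-integrated Gaussian PSF at each sub-step position. With
    ``noise=False`` the expectation image is returned (camera offset still
    added), which is the reference for photon-conservation checks.

    Returns
    -------
    stack : float64 ndarray, shape (n_frames, H, W)
        Counts, clipped to [0, camera.max_count].
    truth : DataFrame with columns frame, particle_id, x_px, y_px, photons
        Per-frame expected (pre-noise) photon count and photon-weighted mean
        position of every particle.
    """
    optics, camera, cage = scene.optics, scene.camera, scene.cage
    h, w = scene.motion.field_size
    sigma = optics.psf_sigma_px
    if min(h, w) < 6.0 * sigma:
        raise ValueError(
            f"field {h}x{w} px too small to contain the PSF support (sigma={sigma:.2f} px)"
        )
    n_sub = optics.n_blur_substeps
    # per-sub-step survival fraction 2^(-t/t_half); finite-half-life only
    if math.isinf(cage.bleach_half_life):
        surv = np.ones_like(scene.times)
    else:
        surv = np.exp2(-scene.times / cage.bleach_half_life)
    budget_per_frame = cage.n_fp * cage.photons_per_fp * optics.exposure
    sub_photons = budget_per_frame * surv / n_sub  # (n_frames, n_sub)

    stack = np.zeros((scene.n_frames, h, w), dtype=float)
    rows: list[tuple[int, int, float, float, float]] = []
    frame_children = np.random.SeedSequence(scene.seed).spawn(scene.n_frames)
    for f in range(scene.n_frames):
        frame = stack[f]
        for p in range(scene.n_particles):
            pos = scene.tracks[p, f]  # (n_sub, 2) as (y, x)
            for j in range(n_sub):
                _stamp_psf(frame, pos[j, 0], pos[j, 1], sigma, sub_photons[f, j])
            tot = sub_photons[f].sum()
            wts = sub_photons[f] / tot if tot > 0 else np.full(n_sub, 1.0 / n_sub)
            ybar, xbar = (pos * wts[:, None]).sum(axis=0)
            rows.append((f, p, xbar, ybar, float(sub_photons[f].sum())))
        rng = np.random.default_rng(frame_children[f]) if noise else None
        stack[f] = _apply_camera(frame, camera, rng, noise)
    truth = pd.DataFrame(rows, columns=["frame", "particle_id", "x_px", "y_px", "photons"])
    return stack, truth


def elliptical_cell_mask(shape: tuple[int, int], fill: float = 0.8) -> np.ndarray:
    """Boolean elliptical 'cell' ROI inscribed in ``fill`` of the frame."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((yy - cy) / (fill * h / 2.0)) ** 2 + ((xx - cx) / (fill * w / 2.0)) ** 2 <= 1.0


def simulate_bleach_movie(
    mask: np.ndarray,
    photons_per_pixel: float,
    half_life: float,
    optics: OpticsModel,
    camera: CameraModel,
    n_frames: int,
    seed: int,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-cell photobleaching movie: diffuse in-mask signal decaying as
    ``2^(-t/half_life)`` plus camera offset and noise; pure camera background
    outside the mask.

    ``photons_per_pixel`` is the expected in-mask photon count per pixel per
    frame at t = 0; ``half_life`` may be ``math.inf`` for a constant movie.
    Frame f is exposed starting at ``t = f * frame_interval`` and the decay is
    averaged over the exposure window.

    Returns the float64 stack and the frame-start times (s).
    """
    if not half_life > 0:
        raise ValueError("half_life must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a non-empty 2D boolean array")
    t_start = np.arange(n_frames) * optics.frame_interval
    if math.isinf(half_life):
        decay = np.ones(n_frames)
    else:
        # exact exposure-window average of 2^(-t/h)
        lam = math.log(2.0) / half_life
        decay = (
            np.exp(-lam * t_start)
            * (1.0 - math.exp(-lam * optics.exposure))
            / (lam * optics.exposure)
        )
    expected = decay[:, None, None] * (photons_per_pixel * mask)[None, :, :]
    frame_children = np.random.SeedSequence(seed).spawn(n_frames)
    stack = np.empty((n_frames,) + mask.shape, dtype=float)
    for f in range(n_frames):
        rng = np.random.default_rng(frame_children[f]) if noise else None
        stack[f] = _apply_camera(expected[f], camera, rng, noise)
    return stack, t_start
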