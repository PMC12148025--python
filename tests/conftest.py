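"""Shared fixtures: acquisition configurations and single-spot scenes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nanocage_bench.synthetic_data import (
    CONFOCAL_OPTICS,
    TIRF_OPTICS,
    CageSpec,
    CameraModel,
    MotionSpec,
    SimulationScene,
    render_stack,
    simulate_tracks,
)


@pytest.fixture
def confocal():
    """Spinning-disc-like optics: 27 nm pixels, 200 nm PSF FWHM, 500 ms."""
    return CONFOCAL_OPTICS


@pytest.fixture
def tirf():
    """TIRF-like optics: 110 nm pixels, 85 frames per second."""
    return TIRF_OPTICS


@pytest.fixture
def tirf_fast():
    """TIRF optics with a single blur sub-step, for trajectory-level work."""
    return dataclasses.replace(TIRF_OPTICS, n_blur_substeps=1)


@pytest.fixture
def quiet_camera():
    """Noise-free, offset-free, unit-gain camera for expectation checks."""
    return CameraModel(offset=0.0, read_noise_sd=0.0, counts_per_photon=1.0)


@pytest.fixture
def camera():
    return CameraModel()


def render_single_spot(optics, camera, seed, n_fp=60, photons_per_fp=100.0,
                       field=41, margin=18.0, noise=False, d_um2_s=0.0,
                       half_life=np.inf, n_frames=1):
    """One (by default stationary, noiseless) nanocage centered-ish in a
    small field; returns (stack, truth, scene)."""
    motion = MotionSpec(diffusion_coefficient=d_um2_s, field_size=(field, field))
    tracks, times = simulate_tracks(motion, 1, n_frames, optics, seed,
                                    init_margin_px=margin)
    scene = SimulationScene(
        tracks=tracks, times=times,
        cage=CageSpec(n_fp=n_fp, photons_per_fp=photons_per_fp,
                      bleach_half_life=half_life),
        optics=optics, camera=camera, motion=motion, seed=seed,
    )
    stack, truth = render_stack(scene, noise=noise)
    return stack, truth, scene
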