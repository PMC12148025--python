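"""Gaussian photometry: fit recovery, disc integration, QC, cage counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from nanocage_bench.spot_quant import (
    auto_seed,
    estimate_cage_count,
    fit_spot,
    gaussian_disc_fraction,
    integrate_cage_intensity,
    qc_filter,
    quantify_spots,
)

from conftest import render_single_spot


def sampled_gaussian(shape, x0, y0, sx, sy, amp, offset):
    """Model-true spot image: the fitted model evaluated at pixel centers."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return offset + amp * np.exp(
        -((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2))
    )


class TestDiscFraction:
    def test_two_sigma_disc_holds_86_percent(self):
        assert gaussian_disc_fraction(2.0) == pytest.approx(1 - math.exp(-2), abs=1e-15)
        assert gaussian_disc_fraction(2.0) == pytest.approx(0.8647, abs=5e-4)

    def test_matches_numerical_quadrature(self):
        # independent oracle: polar quadrature of the standard 2D Gaussian
        for r in (0.5, 1.0, 2.0, 3.0):
            oracle, _ = integrate.quad(
                lambda s: s * math.exp(-s * s / 2.0), 0.0, r
            )
            assert gaussian_disc_fraction(r) == pytest.approx(oracle, rel=1e-10)
        assert gaussian_disc_fraction(1.0) == pytest.approx(0.3935, abs=5e-5)

    def test_edge_values(self):
        assert gaussian_disc_fraction(0.0) == 0.0
        with pytest.raises(ValueError):
            gaussian_disc_fraction(-0.1)

    @given(st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_increasing_to_one(self, r):
        assert gaussian_disc_fraction(r + 0.1) > gaussian_disc_fraction(r)
        assert gaussian_disc_fraction(40.0) == pytest.approx(1.0, abs=1e-12)


class TestFitSpot:
    def test_recovers_model_true_spot(self):
        # noiseless sampled spot at (20.3, 17.8), sigma 3, amplitude 500
        img = sampled_gaussian((40, 44), 20.3, 17.8, 3.0, 3.0, 500.0, 10.0)
        fit = fit_spot(img, (20.0, 18.0), window=11, expected_sigma=3.0)
        assert fit.status == "ok"
        assert fit.x0 == pytest.approx(20.3, abs=0.01)
        assert fit.y0 == pytest.approx(17.8, abs=0.01)
        assert fit.sigma_x == pytest.approx(3.0, rel=0.005)
        assert fit.sigma_y == pytest.approx(3.0, rel=0.005)
        assert fit.amplitude == pytest.approx(500.0, rel=0.005)

    def test_uniform_image_is_degenerate(self):
        fit = fit_spot(np.full((30, 30), 7.0), (15.0, 15.0), window=10)
        assert fit.status == "rejected_degenerate"
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_constant_background_shifts_only_offset(self):
        img = sampled_gaussian((40, 40), 19.6, 20.4, 3.0, 3.0, 400.0, 5.0)
        fit0 = fit_spot(img, (20.0, 20.0), window=11, expected_sigma=3.0)
        fit1 = fit_spot(img + 200.0, (20.0, 20.0), window=11, expected_sigma=3.0)
        assert fit1.x0 == pytest.approx(fit0.x0, abs=1e-6)
        assert fit1.y0 == pytest.approx(fit0.y0, abs=1e-6)
        assert fit1.sigma_x == pytest.approx(fit0.sigma_x, rel=1e-6)
        assert fit1.amplitude == pytest.approx(fit0.amplitude, rel=1e-6)
        assert fit1.offset - fit0.offset == pytest.approx(200.0, abs=1e-6)

    def test_agrees_with_grid_search_oracle(self):
        # brute-force optimum over (x0, y0, sigma) on a dense grid agrees
        # with the least-squares optimum for noisy isotropic spots
        rng = np.random.default_rng(42)
        for _ in range(5):
            x0, y0 = rng.uniform(14, 16, 2)
            sig = rng.uniform(2.5, 3.5)
            img = sampled_gaussian((31, 31), x0, y0, sig, sig, 300.0, 20.0)
            img += rng.normal(0, 2.0, img.shape)
            fit = fit_spot(img, (15.0, 15.0), window=10, expected_sigma=3.0)

            yy, xx = np.mgrid[5:26, 5:26].astype(float)
            patch = img[5:26, 5:26]
            best, best_sse = None, np.inf
            for gx in np.arange(fit.x0 - 0.5, fit.x0 + 0.5, 0.05):
                for gy in np.arange(fit.y0 - 0.5, fit.y0 + 0.5, 0.05):
                    for gs in np.arange(2.0, 4.5, 0.05):
                        basis = np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * gs**2))
                        # profile out the linear parameters (amp, offset)
                        A = np.column_stack([basis.ravel(), np.ones(basis.size)])
                        coef, res, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
                        sse = float(res[0]) if res.size else np.inf
                        if sse < best_sse:
                            best_sse, best = sse, (gx, gy, gs)
            assert fit.x0 == pytest.approx(best[0], abs=0.05)
            assert fit.y0 == pytest.approx(best[1], abs=0.05)
            assert math.sqrt(fit.sigma_x * fit.sigma_y) == pytest.approx(best[2], abs=0.05)

    def test_seed_outside_image_rejected(self):
        with pytest.raises(ValueError):
            fit_spot(np.zeros((20, 20)), (25.0, 5.0), window=5)


class TestIntegrateCageIntensity:
    def test_two_sigma_disc_captures_86_percent_of_volume(self, confocal, quiet_camera):
        stack, truth, _ = render_single_spot(confocal, quiet_camera, seed=13)
        fit = fit_spot(stack[0], (truth["x_px"][0], truth["y_px"][0]), window=12,
                       expected_sigma=confocal.psf_sigma_px)
        total = integrate_cage_intensity(stack[0], fit)
        expected = 0.864665 * truth["photons"].iloc[0]
        assert total == pytest.approx(expected, rel=0.02)

    def test_invariant_under_constant_background(self, confocal, quiet_camera):
        stack, truth, _ = render_single_spot(confocal, quiet_camera, seed=14)
        xy = (truth["x_px"][0], truth["y_px"][0])
        fit0 = fit_spot(stack[0], xy, 12, confocal.psf_sigma_px)
        v0 = integrate_cage_intensity(stack[0], fit0)
        fit1 = fit_spot(stack[0] + 300.0, xy, 12, confocal.psf_sigma_px)
        v1 = integrate_cage_intensity(stack[0] + 300.0, fit1)
        assert v1 == pytest.approx(v0, rel=1e-3)

    def test_linear_in_amplitude(self, confocal, quiet_camera):
        s1, t1, _ = render_single_spot(confocal, quiet_camera, seed=15,
                                       photons_per_fp=100.0)
        s2, _, _ = render_single_spot(confocal, quiet_camera, seed=15,
                                      photons_per_fp=200.0)
        xy = (t1["x_px"][0], t1["y_px"][0])
        v1 = integrate_cage_intensity(s1[0], fit_spot(s1[0], xy, 12, 3.15))
        v2 = integrate_cage_intensity(s2[0], fit_spot(s2[0], xy, 12, 3.15))
        assert v2 / v1 == pytest.approx(2.0, rel=1e-6)

    def test_disc_fully_outside_errors(self):
        img = sampled_gaussian((40, 40), 20.0, 20.0, 3.0, 3.0, 400.0, 5.0)
        fit = fit_spot(img, (20.0, 20.0), 11, 3.0)
        fit.x0 = -50.0
        with pytest.raises(ValueError, match="outside"):
            integrate_cage_intensity(img, fit)


class TestQcFilter:
    def test_psf_consistent_spot_kept(self, confocal):
        img = sampled_gaussian((40, 40), 20.0, 20.0, 3.0, 3.1, 400.0, 5.0)
        fit = fit_spot(img, (20.0, 20.0), 11, 3.15)
        assert qc_filter(fit, confocal) == "ok"

    def test_motion_blurred_spot_rejected(self, confocal, quiet_camera):
        # a cage drifting several pixels during the 500 ms exposure renders
        # elongated and must be flagged, like the visually excluded cages
        stack, truth, _ = render_single_spot(
            confocal, quiet_camera, seed=30, d_um2_s=0.01, field=61, margin=25)
        fit = fit_spot(stack[0], (truth["x_px"][0], truth["y_px"][0]), window=14,
                       expected_sigma=confocal.psf_sigma_px)
        assert qc_filter(fit, confocal) == "rejected_blur"

    def test_aggregate_width_rejected(self, confocal):
        img = sampled_gaussian((60, 60), 30.0, 30.0, 9.4, 9.4, 400.0, 5.0)
        fit = fit_spot(img, (30.0, 30.0), 25, 9.4)
        assert qc_filter(fit, confocal) == "rejected_blur"


class TestCageCount:
    def test_formula(self):
        assert estimate_cage_count(1000.0, 10.0) == pytest.approx(86.0)
        assert estimate_cage_count(10.0, 10.0) == pytest.approx(0.86)

    def test_zero_mean_intensity_errors(self):
        with pytest.raises(ValueError):
            estimate_cage_count(1000.0, 0.0)


class TestCellSummary:
    def test_estimated_cage_count_recovers_true_count(self, confocal, quiet_camera):
        # noiseless field of 5 cages: total cell signal / (mean disc signal)
        # x 0.86 must give back ~5 cages
        from nanocage_bench.spot_quant import summarize_cell
        from nanocage_bench.synthetic_data import (
            CageSpec, MotionSpec, SimulationScene, render_stack, simulate_tracks,
        )

        # well-separated cages, as the user-selected particles would be
        motion = MotionSpec(diffusion_coefficient=0.0, field_size=(96, 96))
        centers = np.array([(20.3, 20.7), (20.6, 70.2), (70.4, 20.1),
                            (70.8, 70.5), (45.5, 45.2)])
        tracks = np.broadcast_to(
            centers[:, None, None, :], (5, 1, confocal.n_blur_substeps, 2)).copy()
        times = (np.arange(confocal.n_blur_substeps) * confocal.exposure
                 / confocal.n_blur_substeps)[None, :]
        scene = SimulationScene(tracks=tracks, times=times, cage=CageSpec(),
                                optics=confocal, camera=quiet_camera,
                                motion=motion, seed=55)
        stack, truth = render_stack(scene, noise=False)
        seeds = truth[["x_px", "y_px"]].round().astype(int)
        spots = quantify_spots(stack[0], seeds, confocal)
        summary = summarize_cell("cell0", spots, stack[0],
                                 np.ones(stack[0].shape, bool), 0.0)
        assert summary.n_spots == 5
        assert summary.estimated_cage_count == pytest.approx(5.0, rel=0.05)


class TestQuantifyPipeline:
    def test_auto_seed_and_quantify_roundtrip(self, confocal, quiet_camera):
        stack, truth, _ = render_single_spot(confocal, quiet_camera, seed=17)
        seeds = auto_seed(stack[0], confocal)
        assert len(seeds) == 1
        spots = quantify_spots(stack, seeds, confocal)
        assert list(spots["status"]) == ["ok"]
        assert spots["x0"].iloc[0] == pytest.approx(truth["x_px"][0], abs=0.02)
        # FWHM of a 200 nm-FWHM PSF lands near the resolution limit
        assert 195.0 <= spots["fwhm_nm"].iloc[0] <= 210.0
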