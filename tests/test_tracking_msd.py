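"""Detection, linking, track filtering, MSD and diffusion fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nanocage_bench.synthetic_data import (
    CageSpec,
    MotionSpec,
    SimulationScene,
    render_stack,
    simulate_tracks,
)
from nanocage_bench.tracking_msd import (
    MSDCurve,
    Track,
    default_max_disp,
    detect_spots,
    filter_tracks,
    fit_diffusion,
    link_tracks,
    msd_per_cell,
    tracks_from_positions,
)


def make_track(xs, ys, start=0, tid=0):
    n = len(xs)
    return Track(track_id=tid, frames=np.arange(start, start + n),
                 x=np.asarray(xs, float), y=np.asarray(ys, float))


class TestDetectSpots:
    def test_blank_noise_frames_rarely_fire(self, tirf, camera):
        rng = np.random.default_rng(0)
        fired = 0
        for _ in range(30):
            frame = camera.offset + rng.normal(0, camera.read_noise_sd, (64, 64))
            fired += len(detect_spots(frame, min_snr=5.0, optics=tirf)) > 0
        assert fired == 0

    def test_rendered_particles_found_within_subpixel(self, tirf, camera):
        # 20 well-separated bright particles: all detected within 0.2 px
        motion = MotionSpec(diffusion_coefficient=0.0, field_size=(128, 128))
        rng = np.random.default_rng(4)
        # place on a jittered grid to guarantee separation
        grid = np.array([(y, x) for y in np.linspace(12, 116, 5)
                         for x in np.linspace(12, 116, 4)])
        grid += rng.uniform(-1, 1, grid.shape)
        tracks = np.broadcast_to(
            grid[:, None, None, :], (20, 1, tirf.n_blur_substeps, 2)).copy()
        times = (np.arange(tirf.n_blur_substeps) * tirf.exposure
                 / tirf.n_blur_substeps)[None, :]
        scene = SimulationScene(
            tracks=tracks, times=times,
            cage=CageSpec(n_fp=60, photons_per_fp=3000.0),
            optics=tirf, camera=camera, motion=motion, seed=8)
        stack, truth = render_stack(scene)
        det = detect_spots(stack[0], min_snr=10.0, optics=tirf)
        assert len(det) == 20
        for _, row in truth.iterrows():
            d = np.hypot(det["x"] - row["x_px"], det["y"] - row["y_px"]).min()
            assert d < 0.2

    def test_nearby_detections_merge(self, tirf):
        sigma = tirf.psf_sigma_px
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        img = np.zeros((40, 40))
        for (y0, x0) in [(20.0, 20.0), (20.0, 20.0 + 0.5 * sigma)]:
            img += 500 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))
        det = detect_spots(img + 100.0, min_snr=5.0, optics=tirf)
        assert len(det) == 1


class TestLinkTracks:
    def test_single_slow_particle_single_track(self):
        rows = [(f, 10.0 + 0.1 * f, 12.0) for f in range(30)]
        det = pd.DataFrame(rows, columns=["frame", "x", "y"])
        tracks = link_tracks(det, max_disp=2.0)
        assert len(tracks) == 1
        assert tracks[0].length == 30

    def test_matches_brute_force_assignment_oracle(self, tirf_fast):
        # well-separated particles: the linker must recover the ground-truth
        # identities; oracle = exhaustive permutation matching per frame
        motion = MotionSpec(diffusion_coefficient=0.05, field_size=(200, 200))
        pos, _ = simulate_tracks(motion, 5, 15, tirf_fast, seed=42,
                                 init_margin_px=25.0)
        pts = pos[:, :, 0, :]  # (5, 15, 2) (y, x)
        # enforce pairwise separation > 4*max_disp by spreading starts
        offsets = np.array([(0, 0), (0, 100), (100, 0), (100, 100), (50, 50)])
        pts = pts * 0.05 + offsets[:, None, :]
        rows = [(f, pts[p, f, 1], pts[p, f, 0], p) for p in range(5)
                for f in range(15)]
        det = pd.DataFrame(rows, columns=["frame", "x", "y", "true_id"])
        max_disp = 5.0
        tracks = link_tracks(det[["frame", "x", "y"]], max_disp)
        assert len(tracks) == 5
        assert all(t.length == 15 for t in tracks)
        # oracle: per frame pair, the best permutation links true id to itself
        for f in range(14):
            a = pts[:, f, :]
            b = pts[:, f + 1, :]
            best = min(itertools.permutations(range(5)),
                       key=lambda perm: sum(((a[i] - b[perm[i]]) ** 2).sum()
                                            for i in range(5)))
            assert best == (0, 1, 2, 3, 4)
        # every recovered track follows one true particle throughout
        for t in tracks:
            d = np.hypot(t.x[:, None] - pts[:, :, 1].T[t.frames - t.frames[0]],
                         t.y[:, None] - pts[:, :, 0].T[t.frames - t.frames[0]])
            assert (d.min(axis=1) < 1e-9).all()

    def test_detection_gap_splits_track(self):
        rows = [(f, 10.0, 10.0) for f in range(10) if f != 5]
        det = pd.DataFrame(rows, columns=["frame", "x", "y"])
        tracks = link_tracks(det, max_disp=2.0)
        assert sorted(t.length for t in tracks) == [4, 5]

    def test_gate_forbids_long_links(self):
        det = pd.DataFrame([(0, 10.0, 10.0), (1, 30.0, 10.0)],
                           columns=["frame", "x", "y"])
        assert link_tracks(det, max_disp=5.0) == []

    def test_default_gate_scale(self, tirf):
        # 5 sigma of the 2D Brownian step at D = 1 um^2/s, in pixels
        gate = default_max_disp(tirf, d_prior=1.0)
        assert gate == pytest.approx(
            5 * math.sqrt(4 * 1.0 * tirf.frame_interval) * 1000 / 110, rel=1e-12)


class TestFilterTracks:
    def test_boundaries_are_strict(self):
        tracks = [make_track([0.0] * n, [0.0] * n, tid=i)
                  for i, n in enumerate([20, 21, 100, 249, 250])]
        kept = filter_tracks(tracks)
        assert sorted(t.length for t in kept) == [21, 100, 249]

    def test_empty_and_all_short(self):
        assert filter_tracks([]) == []
        tracks = [make_track([0.0] * 10, [0.0] * 10)]
        assert filter_tracks(tracks) == []


class TestMsd:
    def test_stationary_track_zero_msd(self, tirf):
        t = make_track([5.0] * 30, [7.0] * 30)
        curve = msd_per_cell([t], tirf)
        np.testing.assert_allclose(curve.msd, 0.0)
        assert (np.diff(curve.lags) > 0).all()
        assert (np.diff(curve.n_pairs) <= 0).all()

    def test_ballistic_track_quadratic_msd(self, tirf):
        # straight line, step s px/frame: MSD(n dt) = (n s px_um)^2
        s = 0.4
        n = 25
        t = make_track(np.arange(n) * s, np.zeros(n))
        curve = msd_per_cell([t], tirf)
        px_um = tirf.pixel_size / 1000.0
        lags_frames = np.arange(1, n)
        np.testing.assert_allclose(curve.msd, (lags_frames * s * px_um) ** 2,
                                   rtol=1e-12)

    def test_brownian_msd_first_lag(self, tirf_fast):
        d = 1.0
        motion = MotionSpec(diffusion_coefficient=d, field_size=(2048, 2048))
        pos, _ = simulate_tracks(motion, 200, 52, tirf_fast, seed=31,
                                 init_margin_px=500.0)
        tracks = tracks_from_positions(pos[:, :, 0, :])
        curve = msd_per_cell(tracks, tirf_fast)
        assert curve.n_pairs[0] >= 10**4
        assert curve.msd[0] == pytest.approx(4 * d * tirf_fast.frame_interval,
                                             rel=0.03)

    def test_no_tracks_errors(self, tirf):
        with pytest.raises(ValueError):
            msd_per_cell([], tirf)


class TestFitDiffusion:
    def test_exact_line_recovers_d(self):
        lags = np.arange(1, 41) * 0.01
        d = 0.5
        curve = MSDCurve(lags=lags, msd=4 * d * lags,
                         n_pairs=np.full(40, 100), n_tracks=10)
        est = fit_diffusion(curve)
        assert est.D == pytest.approx(d, rel=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.n_lags_fit == 10  # ceil(0.25 * 40)

    def test_localization_noise_shifts_intercept_not_slope(self, tirf_fast):
        # static localization error adds a constant MSD offset; the free
        # intercept absorbs it and D stays unbiased
        d = 1.0
        motion = MotionSpec(diffusion_coefficient=d, field_size=(2048, 2048))
        pos, _ = simulate_tracks(motion, 300, 40, tirf_fast, seed=17,
                                 init_margin_px=500.0)
        rng = np.random.default_rng(5)
        noise_px = 0.3
        noisy = pos[:, :, 0, :] + rng.normal(0, noise_px, pos[:, :, 0, :].shape)
        est_clean = fit_diffusion(msd_per_cell(
            tracks_from_positions(pos[:, :, 0, :]), tirf_fast))
        est_noisy = fit_diffusion(msd_per_cell(
            tracks_from_positions(noisy), tirf_fast))
        px_um = tirf_fast.pixel_size / 1000.0
        expected_offset = 4 * (noise_px * px_um) ** 2
        assert est_noisy.D == pytest.approx(est_clean.D, rel=0.05)
        assert est_noisy.intercept - est_clean.intercept == pytest.approx(
            expected_offset, rel=0.3)

    def test_stokes_einstein_ratio_recovery(self, tirf_fast):
        # doubling the particle radius halves D; the recovered Ds must keep
        # that ratio
        est = {}
        for label, d in (("small", 1.0), ("large", 0.5)):
            motion = MotionSpec(diffusion_coefficient=d, field_size=(2048, 2048))
            pos, _ = simulate_tracks(motion, 300, 40, tirf_fast, seed=23,
                                     init_margin_px=500.0)
            curve = msd_per_cell(tracks_from_positions(pos[:, :, 0, :]), tirf_fast)
            est[label] = fit_diffusion(curve).D
        assert est["small"] / est["large"] == pytest.approx(2.0, rel=0.1)

    def test_negative_slope_flagged(self):
        lags = np.arange(1, 9) * 0.01
        curve = MSDCurve(lags=lags, msd=np.linspace(1.0, 0.5, 8),
                         n_pairs=np.full(8, 10), n_tracks=1)
        assert fit_diffusion(curve).status == "negative_slope"

    def test_too_few_lags_errors(self):
        curve = MSDCurve(lags=np.array([0.01]), msd=np.array([0.04]),
                         n_pairs=np.array([5]), n_tracks=1)
        with pytest.raises(ValueError):
            fit_diffusion(curve)
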