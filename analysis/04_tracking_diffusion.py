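#!/usr/bin/env python
"""Nanocage diffusion from fast TIRF-regime tracking.

Two analyses:

1. Image-level validation (small scale): renders short TIRF movies
   (110 nm pixels, 85 frames/s) of freely diffusing cages, detects and
   links particles, and compares the recovered per-cell diffusion
   coefficient with ground truth.
2. Trajectory-level benchmark: 25 synthetic cells per construct with
   hundreds of length-filtered tracks each, comparing a single-tagged cage
   (D = 1.0 um^2/s) against a tandem-tagged cage whose extra FP layer
   enlarges it (~25% slower, D = 0.75 um^2/s) — at low Reynolds number D
   scales inversely with particle size.

Output: results/analysis/diffusion_per_cell.csv, diffusion_summary.csv
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from nanocage_bench.synthetic_data import (
    CageSpec,
    DEFAULT_CAMERA,
    MotionSpec,
    SimulationScene,
    TIRF_OPTICS,
    render_stack,
    simulate_tracks,
)
from nanocage_bench.tracking_msd import (
    default_max_disp,
    detect_spots,
    filter_tracks,
    fit_diffusion,
    link_tracks,
    msd_per_cell,
    tracks_from_positions,
)

OUT = Path("results/analysis")
SEED = 404


def image_level_check() -> None:
    optics = TIRF_OPTICS
    motion = MotionSpec(diffusion_coefficient=1.0, field_size=(96, 96),
                        boundary="reflecting")
    tracks_gt, times = simulate_tracks(motion, 12, 80, optics, SEED,
                                       init_margin_px=10.0)
    scene = SimulationScene(
        tracks=tracks_gt, times=times,
        cage=CageSpec(n_fp=60, photons_per_fp=3000.0),
        optics=optics, camera=DEFAULT_CAMERA, motion=motion, seed=SEED)
    stack, _ = render_stack(scene)
    dets = pd.concat(
        [detect_spots(stack[f], min_snr=6.0, optics=optics, frame_index=f)
         for f in range(stack.shape[0])], ignore_index=True)
    linked = link_tracks(dets, default_max_disp(optics))
    kept = filter_tracks(linked)
    if kept:
        est = fit_diffusion(msd_per_cell(kept, optics))
        print(f"[image-level] {len(dets)} detections -> {len(linked)} tracks, "
              f"{len(kept)} pass the 20<L<250 filter; "
              f"D = {est.D:.2f} um^2/s (truth 1.0)")
    else:
        print(f"[image-level] no tracks passed the length filter "
              f"({len(linked)} linked)")


def trajectory_benchmark() -> pd.DataFrame:
    optics = dataclasses.replace(TIRF_OPTICS, n_blur_substeps=1)
    rows = []
    for construct, d_true in (("mStayGold-1x", 1.0), ("mStayGold-2x", 0.75)):
        for cell in range(25):
            seed = int(np.random.SeedSequence([SEED, round(100 * d_true), cell])
                       .generate_state(1)[0] % 2**31)
            motion = MotionSpec(diffusion_coefficient=d_true,
                                field_size=(512, 512), boundary="reflecting")
            pos, _ = simulate_tracks(motion, 420, 40, optics, seed,
                                     init_margin_px=40.0)
            tracks = filter_tracks(tracks_from_positions(pos[:, :, 0, :]))
            est = fit_diffusion(msd_per_cell(tracks, optics),
                                cell_id=f"{construct}_cell{cell}")
            rows.append({"construct": construct, "cell_id": est.cell_id,
                         "D_um2_s": est.D, "slope_um2_s": est.slope,
                         "intercept_um2": est.intercept,
                         "n_tracks": len(tracks), "true_D_um2_s": d_true})
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    image_level_check()
    per_cell = trajectory_benchmark()
    per_cell.to_csv(OUT / "diffusion_per_cell.csv", index=False)
    summary = (per_cell.groupby("construct")
               .agg(mean_D_um2_s=("D_um2_s", "mean"),
                    sd_D_um2_s=("D_um2_s", "std"),
                    true_D_um2_s=("true_D_um2_s", "first"),
                    n_cells=("cell_id", "count")).reset_index())
    summary.to_csv(OUT / "diffusion_summary.csv", index=False)
    for _, r in summary.iterrows():
        print(f"[trajectory] {r['construct']}: D = {r['mean_D_um2_s']:.3f} "
              f"+/- {r['sd_D_um2_s']:.3f} um^2/s over {r['n_cells']} cells "
              f"(truth {r['true_D_um2_s']:.2f})")
    s = summary.set_index("construct")
    drop = 1 - s.loc["mStayGold-2x", "mean_D_um2_s"] / s.loc["mStayGold-1x", "mean_D_um2_s"]
    print(f"[trajectory] tandem tagging slows diffusion by {100 * drop:.0f}% "
          "(consistent with the larger hydrodynamic radius)")


if __name__ == "__main__":
    main()
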