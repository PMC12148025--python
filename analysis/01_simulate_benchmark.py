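#!/usr/bin/env python
"""Simulate the confocal nanocage fields for the FP brightness benchmark.

For each FP in the green and red panels, renders mannitol-slowed (nearly
stationary) nanocage fields under the spinning-disc configuration (27 nm
pixels, 500 ms exposure) with shot noise, read noise and camera offset, and
writes per-cell TIFF stacks with JSON sidecars plus the ground-truth tables.

Output: results/analysis/stacks/<fp>_cell<k>.tif (+ .json, + _truth.csv)
"""

import zlib
from pathlib import Path

import numpy as np

from nanocage_bench.pipeline_io import StackMetadata, write_stack
from nanocage_bench.synthetic_data import (
    CONFOCAL_OPTICS,
    DEFAULT_CAMERA,
    FP_LIBRARY,
    MotionSpec,
    SimulationScene,
    render_stack,
    simulate_tracks,
)

GREEN = ["EGFP", "mEmerald", "mStayGold", "mBaoJin"]
RED = ["mCherry", "mScarlet-I", "mScarlet3", "mRuby3"]
N_CELLS = 6
N_CAGES = 8
FIELD = (96, 96)
D_SLOWED = 0.005  # um^2/s; hypertonic treatment nearly stops the cages
SEED = 2024

OUT = Path("results/analysis/stacks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    optics, camera = CONFOCAL_OPTICS, DEFAULT_CAMERA
    n_written = 0
    for panel, fps in (("green", GREEN), ("red", RED)):
        for fp in fps:
            cage = FP_LIBRARY[fp]
            for cell in range(N_CELLS):
                seed = int(np.random.SeedSequence(
                    [SEED, zlib.crc32(fp.encode()), cell]).generate_state(1)[0] % 2**31)
                motion = MotionSpec(diffusion_coefficient=D_SLOWED, field_size=FIELD)
                tracks, times = simulate_tracks(motion, N_CAGES, 1, optics, seed,
                                                init_margin_px=10.0)
                scene = SimulationScene(tracks=tracks, times=times, cage=cage,
                                        optics=optics, camera=camera,
                                        motion=motion, seed=seed)
                stack, truth = render_stack(scene)
                name = fp.replace("(", "").replace(")", "")
                path = OUT / f"{name}_cell{cell}.tif"
                write_stack(path, stack, StackMetadata(
                    pixel_size_nm=optics.pixel_size,
                    frame_interval_s=optics.frame_interval,
                    exposure_s=optics.exposure,
                    channel=panel, source=fp, seed=seed))
                truth.to_csv(OUT / f"{name}_cell{cell}_truth.csv", index=False)
                n_written += 1
    print(f"rendered {n_written} cells "
          f"({len(GREEN)} green + {len(RED)} red FPs x {N_CELLS} cells, "
          f"{N_CAGES} cages each) into {OUT}")


if __name__ == "__main__":
    main()
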