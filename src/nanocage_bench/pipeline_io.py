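"""Shared I/O, configuration and the end-to-end synthetic benchmark pipeline.

Image stacks travel as multi-page 16-bit grayscale TIFFs with a JSON
metadata sidecar (``<stack>.json``) holding pixel size, frame interval,
exposure, channel, seed and any scene parameters — TIFF tag dialects vary
too much to be trusted with quantitative metadata. All tabular outputs are
UTF-8 comma-separated CSV with units in the column names.

:func:`run_pipeline` chains simulate -> quantify -> bleach -> track ->
compare on synthetic data from a single YAML config and a master seed;
outputs land in a subdirectory named by a hash of the config, so a changed
parameter never overwrites an earlier run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import compare_stats, photobleach, spot_quant, synthetic_data, tracking_msd
from .synthetic_data import (
    CameraModel,
    MotionSpec,
    OpticsModel,
    SimulationScene,
)

logger = logging.getLogger("nanocage_bench")

__all__ = [
    "StackMetadata",
    "read_stack",
    "write_stack",
    "load_config",
    "config_hash",
    "run_pipeline",
]

_REQUIRED_META = ("pixel_size_nm", "frame_interval_s", "exposure_s")


@dataclass
class StackMetadata:
    """Acquisition metadata carried in the JSON sidecar of every stack."""

    pixel_size_nm: float
    frame_interval_s: float
    exposure_s: float
    channel: str = ""
    source: str = ""
    seed: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not 0 < self.exposure_s <= self.frame_interval_s:
            raise ValueError("need 0 < exposure_s <= frame_interval_s")

    def to_optics(self, psf_fwhm_nm: float = 200.0, n_blur_substeps: int = 10) -> OpticsModel:
        return OpticsModel(
            pixel_size=self.pixel_size_nm,
            psf_fwhm=psf_fwhm_nm,
            exposure=self.exposure_s,
            frame_interval=self.frame_interval_s,
            n_blur_substeps=n_blur_substeps,
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: np.ndarray, metadata: StackMetadata) -> Path:
    """Write a stack as multi-page 16-bit grayscale TIFF plus JSON sidecar.

    Float stacks are rounded and clipped to the uint16 range; the sidecar is
    written next to the TIFF as ``<name>.tif.json``.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be 2D or 3D")
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = asdict(metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, StackMetadata]:
    """Read a multi-page grayscale TIFF and its JSON sidecar.

    Raises ``ValueError`` naming any absent required metadata field, and a
    ``ValueError`` (not a crash) for unreadable/RGB TIFFs.
    """
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot read {path} as TIFF: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"{path} is not a multi-page grayscale stack (shape {stack.shape}); "
            "RGB/multichannel TIFFs are not supported"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"metadata sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"metadata field {key!r} missing from {sidecar}")
    known = {k: meta[k] for k in ("pixel_size_nm", "frame_interval_s", "exposure_s",
                                  "channel", "source", "seed") if k in meta}
    extra = {k: v for k, v in meta.items() if k not in known and k != "extra"}
    md = StackMetadata(**known, extra=meta.get("extra") or (extra or None))
    return stack, md


# ------------------------------------------------------------------ config

_CONFIG_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "fps", "reference_fp", "optics", "camera", "simulate",
         "quantify", "bleach", "track", "compare"},
    "optics": {"pixel_size_nm", "psf_fwhm_nm", "exposure_s", "frame_interval_s",
               "n_blur_substeps"},
    "camera": {"offset", "read_noise_sd", "counts_per_photon", "max_count"},
    "simulate": {"n_cells", "n_cages_per_cell", "field_size_px", "diffusion_um2_s"},
    "quantify": {"window", "anisotropy_max", "sigma_band", "min_snr"},
    "bleach": {"n_frames", "photons_per_pixel", "with_plateau"},
    "track": {"n_cells", "n_particles", "n_frames", "min_snr", "max_disp_px",
              "min_frames", "max_frames", "fit_fraction", "diffusion_um2_s"},
    "compare": {"alpha"},
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected so a
    typo cannot silently disable a stage parameter."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(cfg, "")
    return cfg


def _check_keys(section: dict, name: str) -> None:
    allowed = _CONFIG_SCHEMA[name]
    unknown = set(section) - allowed
    if unknown:
        where = name or "top level"
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in {where}")
    for key, sub in section.items():
        if key in _CONFIG_SCHEMA and key and isinstance(sub, dict):
            _check_keys(sub, key)


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------- pipeline

def _optics_from_cfg(cfg: dict) -> OpticsModel:
    o = cfg.get("optics", {})
    return OpticsModel(
        pixel_size=o.get("pixel_size_nm", 27.0),
        psf_fwhm=o.get("psf_fwhm_nm", 200.0),
        exposure=o.get("exposure_s", 0.5),
        frame_interval=o.get("frame_interval_s", 0.5),
        n_blur_substeps=o.get("n_blur_substeps", 10),
    )


def _camera_from_cfg(cfg: dict) -> CameraModel:
    c = cfg.get("camera", {})
    return CameraModel(
        offset=c.get("offset", 100.0),
        read_noise_sd=c.get("read_noise_sd", 1.5),
        counts_per_photon=c.get("counts_per_photon", 1.0),
        max_count=c.get("max_count", 65535.0),
    )


def run_pipeline(cfg: dict, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Run the full synthetic benchmark described by ``cfg``.

    For every FP in ``cfg['fps']`` (names from the built-in panel), the
    pipeline simulates confocal fields of slowed nanocages, quantifies cage
    intensities, simulates whole-cell bleaching movies and fits half-lives,
    simulates fast tracking data and fits diffusion coefficients, and
    finally assembles the comparison table and group statistics.

    Outputs are written under ``out_dir/<config_hash>/`` and never
    overwrite a different configuration's results. Returns a dict with the
    result DataFrames and the output path.
    """
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    fps = list(cfg.get("fps", ["EGFP", "mStayGold"]))
    reference = cfg.get("reference_fp", fps[0])
    optics = _optics_from_cfg(cfg)
    camera = _camera_from_cfg(cfg)
    sim = cfg.get("simulate", {})
    n_cells = int(sim.get("n_cells", 5))
    n_cages = int(sim.get("n_cages_per_cell", 10))
    field = tuple(sim.get("field_size_px", (64, 64)))
    d_slow = float(sim.get("diffusion_um2_s", 0.005))  # mannitol-slowed cages
    bl = cfg.get("bleach", {})
    trk = cfg.get("track", {})

    out_root = Path(out_dir if out_dir is not None else cfg.get("out_dir", "results"))
    h = config_hash(cfg)
    out = out_root / h
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    spot_rows, hl_by_fp, int_by_fp, d_rows = [], {}, {}, []
    for fp_i, fp in enumerate(fps):
        cage = synthetic_data.FP_LIBRARY[fp]
        logger.info("simulating %s (%d cells)", fp, n_cells)
        cell_ints, cell_hls = [], []
        for cell in range(n_cells):
            cell_seed = int(np.random.SeedSequence([seed, fp_i, cell]).generate_state(1)[0] % (2**31))
            motion = MotionSpec(diffusion_coefficient=d_slow, field_size=field)
            tracks, times = synthetic_data.simulate_tracks(
                motion, n_cages, 1, optics, cell_seed, init_margin_px=8.0
            )
            scene = SimulationScene(tracks=tracks, times=times, cage=cage,
                                    optics=optics, camera=camera, motion=motion,
                                    seed=cell_seed)
            stack, truth = synthetic_data.render_stack(scene)
            seeds = truth[truth["frame"] == 0][["x_px", "y_px"]].round().astype(int)
            seeds = seeds.assign(cell_id=f"{fp}_cell{cell}")
            q = cfg.get("quantify", {})
            spots = spot_quant.quantify_spots(
                stack[0], seeds, optics,
                window=q.get("window"),
                anisotropy_max=q.get("anisotropy_max", 1.3),
                sigma_band=tuple(q.get("sigma_band", (0.7, 1.6))),
            )
            spots.insert(0, "fp", fp)
            spot_rows.append(spots)
            ok = spots[spots["status"] == "ok"]
            if len(ok):
                cell_ints.append(float(ok["integrated_intensity_counts"].mean()))
            # whole-cell bleaching movie for this cell
            mask = synthetic_data.elliptical_cell_mask(field)
            movie, _ = synthetic_data.simulate_bleach_movie(
                mask, float(bl.get("photons_per_pixel", 200.0)),
                cage.bleach_half_life, optics, camera,
                int(bl.get("n_frames", 60)), cell_seed + 1,
            )
            curve = photobleach.roi_mean_trace(movie, mask, camera.offset,
                                               optics.frame_interval, roi_id=f"{fp}_cell{cell}")
            bfit = photobleach.fit_decay(curve, with_plateau=bool(bl.get("with_plateau", True)))
            if bfit.status == "ok":
                cell_hls.append(bfit.half_life)
        int_by_fp[fp] = cell_ints
        hl_by_fp[fp] = cell_hls

        # fast tracking regime (TIRF-like), per-cell diffusion
        tirf = synthetic_data.TIRF_OPTICS
        for cell in range(int(trk.get("n_cells", 3))):
            cell_seed = int(np.random.SeedSequence([seed, 1000 + fp_i, cell]).generate_state(1)[0] % (2**31))
            # reflecting walls + inset starts: wrap-free paths for the MSD
            motion = MotionSpec(diffusion_coefficient=float(trk.get("diffusion_um2_s", 1.0)),
                                field_size=(128, 128), boundary="reflecting")
            positions, _ = synthetic_data.simulate_tracks(
                motion, int(trk.get("n_particles", 30)), int(trk.get("n_frames", 60)),
                tirf, cell_seed, init_margin_px=16.0,
            )
            tracks = tracking_msd.tracks_from_positions(positions[:, :, 0, :])
            tracks = tracking_msd.filter_tracks(
                tracks, int(trk.get("min_frames", 20)), int(trk.get("max_frames", 250))
            )
            if not tracks:
                continue
            curve = tracking_msd.msd_per_cell(tracks, tirf)
            est = tracking_msd.fit_diffusion(curve, float(trk.get("fit_fraction", 0.25)),
                                             cell_id=f"{fp}_cell{cell}")
            d_rows.append({"fp": fp, "cell_id": est.cell_id, "D_um2_s": est.D,
                           "slope_um2_s": est.slope, "intercept_um2": est.intercept,
                           "n_tracks": curve.n_tracks})

    spots_df = pd.concat(spot_rows, ignore_index=True)
    comparison = compare_stats.build_comparison(int_by_fp, hl_by_fp, reference)
    test = compare_stats.anova_tukey(int_by_fp, alpha=float(cfg.get("compare", {}).get("alpha", 0.05))) \
        if len(fps) >= 2 and all(len(v) >= 3 for v in int_by_fp.values()) else None
    diffusion = pd.DataFrame(d_rows)

    provenance = {"config_hash": h, "seed": seed}
    spots_df.to_csv(out / "spots.csv", index=False)
    comparison.to_csv(out / "comparison.csv", index=False)
    diffusion.to_csv(out / "diffusion.csv", index=False)
    summary = {
        **provenance,
        "n_spots_fit": int((spots_df["status"] == "ok").sum()),
        "fps": fps,
        "half_lives_s": {fp: list(map(float, v)) for fp, v in hl_by_fp.items()},
    }
    if test is not None:
        summary["anova_F"] = test.anova_F
        summary["anova_p"] = test.anova_p
        summary["letters"] = test.letters
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline outputs written to %s", out)
    return {"out_dir": out, "spots": spots_df, "comparison": comparison,
            "diffusion": diffusion, "stats": test, "summary": summary}
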