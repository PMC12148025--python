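# nanocage-bench

Benchmarking fluorescent proteins (FPs) one molecule at a time is hard:
whole-cell intensity mostly measures expression level, and ratiometric
2A-peptide assays are confounded by cleavage, maturation and FRET. A cleaner
readout comes from self-assembling I3-01 protein nanocages — 60-subunit,
~26 nm dodecahedrons that present exactly 60 (or, with tandem tags, 120) FP
copies as a single sub-diffraction particle. Comparing the integrated
intensity of individual nanocages then compares FPs molecule-by-molecule in
live cytoplasm, on the very microscope that will be used for experiments;
the same cages report photostability (whole-cell bleaching curves) and
intracellular biophysics (their Brownian diffusion).

`nanocage-bench` implements that analysis as a tested Python library with a
synthetic-microscopy generator standing in for raw image data:

- **`synthetic_data`** — ground-truth-annotated image stacks: Brownian
  nanocages (D ~ 1 µm² s⁻¹, optionally slowed to mimic hypertonic
  D-mannitol treatment), pixel-integrated Gaussian PSF (~200 nm FWHM) at
  27 nm (confocal) or 110 nm (TIRF) pixels, exposure-integrated motion
  blur, exponential photobleaching, Poisson shot noise, Gaussian read noise,
  camera offset and saturation.
- **`spot_quant`** — sub-pixel elliptical 2D Gaussian fits of seeded
  particles; background-corrected signal integrated in a disc of radius 2σ,
  which holds 1 − e⁻² ≈ 86% of a 2D Gaussian's volume; QC rejection of
  motion-blurred/aggregate spots; cages-per-cell estimate
  (total/mean × 0.86).
- **`photobleach`** — ROI mean traces and single-exponential fits
  I(t) = (1 − c)e^(−kt) + c, half-life t₁/₂ = ln 2 / k.
- **`tracking_msd`** — detection, gated optimal-assignment linking (no gap
  closing), the 20 < length < 250 frames track filter, pair-weighted
  time-averaged MSD per cell, and D = slope/4 from an OLS fit of the
  initial 25% of the MSD curve.
- **`compare_stats`** — relative brightness, the *relative emission yield*
  (brightness fold × half-life), one-way ANOVA + Tukey–Kramer HSD with
  compact letter display, Fibonacci-lattice FP spacing on the cage sphere,
  and generic excitation/emission spectral-throughput overlap.
- **`pipeline_io`** — TIFF + JSON-sidecar stack I/O, validated YAML config,
  a hash-provenanced `run_pipeline`, and the `nanocage-bench` CLI.

## Worked example

The numbered scripts under `analysis/` run the full synthetic benchmark
(each regenerates what it needs; run them in order from the repo root):

```bash
python analysis/01_simulate_benchmark.py   # render confocal nanocage fields
python analysis/02_quantify_brightness.py  # per-cage photometry + ANOVA/Tukey
python analysis/03_photobleaching.py       # whole-cell half-life fits
python analysis/04_tracking_diffusion.py   # TIRF tracking + MSD diffusion
python analysis/05_compare_fps.py          # combined FP comparison table
```

Output of `05_compare_fps.py` (seeds fixed in the scripts):

```
   fp_name  mean_cage_intensity_counts  relative_brightness_fold  half_life_s  emission_yield_fold_s  n_cells channel
      EGFP                 2906.770913                  1.000000    22.923912              22.923912        6   green
   mBaoJin                10156.771239                  3.494177    19.985888              69.834226        6   green
  mEmerald                 2689.492572                  0.925251    24.981483              23.114141        6   green
 mStayGold                 9221.811236                  3.172528    59.799346             189.715080        6   green
   mCherry                 1936.240064                  1.000000    20.935159              20.935159        6     red
    mRuby3                 1654.527668                  0.854505    20.901844              17.860740        6     red
mScarlet-I                 2668.628528                  1.378253     5.400846               7.443732        6     red
 mScarlet3                 2854.726923                  1.474366     6.494342               9.575039        6     red

[green] best emission yield: mStayGold (190 fold*s, 8.3x the EGFP yield)
[red] best emission yield: mCherry (21 fold*s, 1.0x the mCherry yield)
[geometry] 60 FPs on the 35 nm nanocage sphere: mean nearest-neighbor spacing 7.48 nm
```

Reading the table: `relative_brightness_fold` is the mean per-cage
integrated intensity divided by the channel reference's (EGFP or mCherry);
`half_life_s` is the fitted photobleaching half-life under continuous
illumination; their product, `emission_yield_fold_s`, is the figure of
merit — the simulated mStayGold-like FP (3× brighter, t₁/₂ ≈ 60 s)
delivers ~8× the usable photons of the EGFP-like reference, while the
mScarlet-like reds trade a 1.4–1.5× brightness gain for a ~4× faster
bleach and end up *below* the mCherry-like reference. The diffusion script
prints D = 1.005 ± 0.021 µm² s⁻¹ for the single-tagged cage and
0.745 ± 0.019 for the tandem cage (26% slower — the Stokes–Einstein
signature of the larger particle).

The same stages are scriptable via the CLI
(`nanocage-bench {simulate,quantify,bleach,track,compare,run}`), e.g.
`nanocage-bench run --config cfg.yaml --seed 7 --out results/`.

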