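# Methods

This note documents the models behind `nanocage-bench`, the defaults and
why they were chosen, and what the synthetic benchmark does and does not
demonstrate about real microscopy data.

## The measurement model

An I3-01 nanocage carries a fixed number of FP copies (`n_fp`, 60 for a
single tag, 120 for a tandem tag) and images as a sub-diffraction particle:
an approximately Gaussian spot of FWHM near the optical resolution limit.
Three quantities are extracted per construct:

1. **Per-cage brightness.** An elliptical 2D Gaussian
   `offset + A·exp(−((x−x₀)²/2σₓ² + (y−y₀)²/2σᵧ²))` is fitted to each
   seeded particle by bounded nonlinear least squares (initialized from the
   window-border median, peak-minus-offset, the intensity centroid and the
   expected PSF σ). The cage signal is the sum of *original* pixel values
   whose centers lie within radius 2σ (geometric-mean σ) of the fitted
   center, minus `offset × n_pixels`. A 2σ disc contains
   `1 − exp(−r²/2)|_{r=2} = 1 − e⁻² ≈ 0.8647` of a 2D Gaussian's volume, so
   whole-cell intensity divided by mean cage signal times 0.86 estimates
   cages per cell.
2. **Photostability.** The mean intensity of a whole-cell ROI,
   camera-offset-subtracted and normalized to the first frame, is fitted
   with `I(t) = (1−c)·e^(−kt) + c`; the half-life is `ln 2 / k`. The
   plateau c (bounded to [0, 0.5], optional) absorbs non-bleaching
   background; on plateau-free data it converges to 0.
3. **Diffusion.** Particles in fast time-lapse series are detected
   (robust-threshold local maxima, Gaussian sub-pixel refinement, 1σ
   duplicate merging), linked frame-to-frame by optimal bipartite
   assignment under a hard displacement gate (no gap closing, merging or
   splitting), and filtered to lengths strictly between 20 and 250 frames.
   Each track contributes its time-averaged MSD over all overlapping pairs;
   the per-cell curve averages tracks with pair-count weights. For 2D
   Brownian motion MSD(Δt) = 4DΔt, so D is slope/4 of an OLS line through
   the first ⌈0.25 × n_lags⌉ lags (minimum 2), with a free intercept that
   absorbs static localization error and motion-blur offsets (both shift
   the curve without changing its slope).

Brightness and photostability combine into the **relative emission yield**:
relative brightness (fold of a named reference FP) × half-life (s). The
metric is configuration-specific — it compares FPs only within one
excitation/emission channel at one irradiance — so tables carry a channel
label and the reference FP is always stated.

## Synthetic data generator

The generator renders the two acquisition regimes used by the analyses:

| parameter | confocal | TIRF | rationale |
|---|---|---|---|
| pixel size | 27 nm | 110 nm | typical SoRa-style and EMCCD-TIRF effective pixels |
| PSF FWHM | 200 nm | 200 nm | near the green-emission resolution limit |
| exposure | 500 ms | 10 ms | long exposures blur moving cages; short ones freeze them |
| frame interval | 500 ms | 1/85 s | continuous illumination vs 85 frames/s tracking |

Particles perform Brownian motion (per-axis step variance 2DΔt) sampled at
`n_blur_substeps` (default 10) instants within each exposure; the PSF — the
pixel-integrated (erf) Gaussian, so photon mass is conserved exactly — is
stamped at every sub-step with 1/n of the frame's photon budget, which
reproduces the blurred appearance of moving cages at long exposures without
an analytic blur kernel. The expected photon budget per particle per frame
is `n_fp × photons_per_fp × exposure × 2^(−t/t₁/₂)` averaged over the
exposure window; bleaching acts on the expected rate continuously (at 60
FPs per cage the ensemble expectation is what the fits measure; single-FP
blinking is out of scope). Poisson noise is applied to photons, then gain,
Gaussian read noise, offset, and clipping at the camera's saturation. The
default camera (gain 1 count/photon, read noise 1.5 counts, offset 100
counts, 16-bit range) is generic sCMOS-like; all values are configurable.

Rendering returns float64 counts; quantization to uint16 happens only at
TIFF export, so noiseless expectation images are exact.

Reproducibility: one master seed; per-particle and per-frame sub-streams
are spawned deterministically (`numpy.random.SeedSequence`), so a
particle's path does not depend on how many particles are simulated and a
fixed seed re-renders bit-identically.

Boundaries: `reflecting` (default; a confined cytoplasm patch) or
`periodic`. Wrapped periodic coordinates contain field-sized jumps, so
MSD analyses use reflecting fields large enough (and particle starts inset
far enough) that no wall is reached within a track's duration.

### The synthetic FP panel

`FP_LIBRARY` defines the simulated conditions for the analysis scripts.
Half-lives are representative values for the common green/red FPs under
benchmark-style continuous illumination (EGFP 23 s, mEmerald 25 s,
mStayGold 60 s, mBaoJin 20 s, mCherry 21 s, mScarlet-I 5.4 s, mScarlet3
6.5 s, mRuby3 21 s); photon rates are folds of the channel reference
(mStayGold 3.0× and mBaoJin 2.8× the EGFP rate; mScarlet-I 1.6× and
mScarlet3 1.9× the mCherry rate). The absolute scale (100 photons s⁻¹ per
FP for the green reference, red reference at 0.6× it) is a free parameter
chosen to give realistic single-cage signal-to-noise at 500 ms exposures;
physical irradiance (W cm⁻²) is not convertible to photon rates without
molecular cross-sections, and no such mapping is claimed.

For the confocal brightness fields the cages diffuse at 0.005 µm² s⁻¹,
emulating hypertonic (D-mannitol) slowing: rms drift during a 500 ms
exposure is then ~0.1 µm, within one PSF σ, so most cages are analyzably
stationary while occasional excursions still exercise the blur-rejection
QC. Free cytoplasmic diffusion for tracking runs is 1.0 µm² s⁻¹, a
realistic value for a ~30 nm particle in mammalian cytoplasm.

## Numerical choices

- **Gaussian model.** Elliptical without rotation (5 shape parameters):
  single-σ reporting matches standard FWHM summaries while the two widths
  support motion-blur rejection; adding rotation destabilizes fits of
  near-circular spots. The fitter evaluates the model at pixel centers; the
  renderer integrates it over pixels. At σ ≈ 3.15 px the mismatch inflates
  fitted σ by ~0.4% and leaves positions unbiased (verified in tests), well
  inside every tolerance used.
- **Disc membership.** A pixel belongs to the 2σ disc iff its center lies
  inside — simple, deterministic, and within the tolerance of the 0.86
  correction. Discs clipped by the image edge are flagged
  (`partial_disc`); fully outside raises.
- **QC defaults.** Anisotropy max(σₓ,σᵧ)/min > 1.3, or geometric-mean σ
  outside (0.7, 1.6)× the expected PSF σ, rejects a spot as
  blurred/aggregate. The original analysis excluded blurred cages by eye;
  these thresholds make the rule explicit and configurable.
- **Degenerate fits.** A flat window, a non-positive amplitude, or an
  amplitude under 3× the residual RMS is `rejected_degenerate`;
  non-convergence is `failed`. Neither raises.
- **Best focus.** For short Z-stacks, the frame (among the first three)
  with the highest fitted amplitude is used per spot.
- **Decay fitting.** Rate initialized from a log-linear fit of the early
  trace; plateau bounded to [0, 0.5]. A fit with k·t_span < 0.01 (< 1%
  decay over the observation) is reported `failed` as unidentifiable.
- **Track filter boundaries.** "Longer than 20, shorter than 250 frames"
  is read strictly: lengths 20 and 250 are excluded, 21 and 249 kept;
  both bounds are arguments.
- **Linking gate.** Default 5·sqrt(4·D_prior·Δt)/pixel_size with
  D_prior = 1 µm² s⁻¹ — five sigma of the expected 2D Brownian step.
- **MSD averaging.** Pair-count weighting (the overlapping-pairs time
  average); unweighted per-track averaging is a documented alternative but
  not the default.
- **Tukey–Kramer.** Pairwise p-values from the studentized-range
  distribution (`scipy.stats.tukey_hsd`, Kramer correction for unequal n);
  ANOVA from `scipy.stats.f_oneway`. The compact letter display uses
  insert-and-absorb with alphabetical tie-breaking for deterministic
  reports. Box-plot statistics: median, linear-interpolation quartiles,
  whiskers at the last observation within 1.5 IQR.
- **Fibonacci spacing.** "Average spacing" is the mean nearest-neighbor 3D
  distance over golden-angle lattice points — the conservative reading
  (lattice-neighbor definitions give slightly larger values). For 60
  points on a 35 nm sphere this gives 7.48 nm.
- **Spectral throughput.** Excitation efficiency = unit-peak-normalized
  excitation amplitude at the laser line; emission capture = trapezoidal
  integral of the unit-area emission spectrum over the filter band
  (bandpass or long-pass edge). Only this generic overlap is implemented;
  no specific FP spectra ship with the package.

## Problem sizes

The test suite and analysis scripts run at desk scale: brightness fields of
8 cages × 6 cells per FP; 20 bleaching movies per condition (48×48 px, 100
frames at 500 ms, half-lives 5.4–60 s); diffusion benchmarks of 25 cells ×
~410 tracks × 40 frames at 85 frames/s; 100 noiseless spots for fit
recovery; 1000 null datasets (5 groups × 20 cells) for the Tukey–Kramer
calibration. These sizes give Monte-Carlo precision comfortably inside the
asserted tolerances.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the estimators recover the generator's
ground truth: sub-0.01 px localization on noiseless spots, disc integration
at 86% ± 2% of emitted photons, half-lives within 5% and diffusion
coefficients within 10% at realistic noise, exact 2.00× scaling from 60 to
120 FPs, and a calibrated 5% family-wise error. They do **not** certify
performance on real data, where the generator's idealizations break down:
no FP maturation kinetics or blinking, no dimerization/aggregation (the
observed ~10% sub-linearity of tandem-tagged bright FPs is a biological
effect the simulator deliberately does not reproduce), no spatially varying
background or cytoplasmic autofluorescence, no anomalous/confined
diffusion, no TIRF evanescent-field depth or SoRa optics, no chromatic
effects. Detection-and-linking equivalence with full-featured trackers
(gap closing, merge/split) is likewise not claimed.
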