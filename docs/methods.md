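# Methods

This note records the models implemented in `dslox`, the assumptions
behind the synthetic data generator, and the numerical choices made where
the design was genuinely open.

## Forward spectral model (`dslox.blood_optics`)

Single-scattering Beer's-law transport:
`I(sO₂|λ,z) = I₀(λ) √(R₀ A λ^(−α)) exp(−μ z)` with
`μ = μ_a + W μ_s` mixed linearly between oxygenated and deoxygenated
whole blood. Conventions:

- `z` is the *effective one-way-equivalent* path (mm). Double-pass
  geometry is expressed by the caller: a spectrum from the bottom wall of
  a vessel of lumen depth D uses `z = 2D`, a mid-lumen spectrum `z = D`.
  The default `z = 0.1 mm` corresponds to a ~50 µm lumen.
- sO₂ is a fraction in [0, 1] everywhere inside the package; percentages
  appear only at rendering/reporting boundaries.
- Coefficient tables are linearly interpolated in wavelength;
  out-of-range queries raise rather than extrapolate.
- The bundled table (`data/hemoglobin_synthetic.csv`, regenerable with
  `scripts/make_coefficient_table.py`) is a smooth *synthetic* analytic
  approximation to published whole-blood spectra (HbO₂ bands at 542 and
  576 nm, Hb band at 555 nm, magnitudes implied by molar extinction at
  150 g/L haemoglobin, power-law μ_s). It provides realistic spectral
  contrast for simulation but is not a measurement; every test that
  asserts exact numbers uses a small toy table instead.

## Spectral extraction (`dslox.preprocessing`)

- Window bank: 14 Gaussian windows equally spaced in k = 2π/λ with first
  and last centres at 523.4 and 604.5 nm, FWHM 0.32 µm⁻¹ — a wavelength
  bandwidth Δλ = λ²Δk/2π ≈ 17 nm at 585 nm.
- STFT: Gaussian window multiplication in uniformly sampled k followed by
  the **magnitude** of the FFT (a `power=True` switch gives squared
  magnitude; whether intensity-like fitting should use magnitude or power
  is not settled, and magnitude is consistent with fitting the model
  intensity directly).
- Depth is measured in µm from the aligned retinal surface, increasing
  downward; averaging windows are closed intervals. The bottom spectrum
  averages wall ± 16.6 µm; "centre" and "top" average 16.6 µm-wide
  windows centred 25 and 41.6 µm *above* the wall (offset ± 8.31 µm
  half-width, matching the bottom window's total width).
- Windows clipped by the volume edge are errors, never silently
  truncated, so depth averages stay unbiased.
- Rolling averages use window/step 100/50 or 250/125 depending on the
  emulated acquisition protocol; output count is ⌊(N−w)/s⌋+1.
- The network input is (bottom ⊕ centre) normalized by the mean of the
  combined bottom ⊕ centre ⊕ top signal — a 1×28 vector invariant under
  global intensity rescaling.

## Synthetic data (`dslox.synthetic`)

The generator emulates the statistical structure of two separate in vivo
study designs, which are the fixed study conditions of every benchmark:

- **Setup 1**: 4 rats × 6 ventilation states (normoxia + five step-wise
  hypoxia challenges), labels drawn truncated-normal per state with means
  descending 0.95 → 0.64.
- **Setup 2**: 8 rats × 5 states (normoxia, hyperoxia, 5 % CO₂, hypoxia,
  return), means 0.80 / 0.98 / 0.85 / 0.70 / 0.80. Hyperoxia at 0.98 and
  hypoxia near 0.70 follow typical pulse-oximeter readings under these
  challenges.
- Totals: 2779 training and 502 testing spectra (849+248 from setup 1,
  1930+254 from setup 2), split **by animal** — the last rat of each
  setup is the held-out test animal.
- The two setups differ by a smooth multiplicative spectral bias
  `exp(c₁u + c₂u²)`, `u = (λ−λ̄)/span`, with coefficients (0, 0) and
  (0.25, −0.20): a minimal parameterization of a systemic inter-setup
  bias, which is named but never quantified in the literature the
  generator emulates.
- Noise: unit-mean gamma speckle per band, additive Gaussian noise
  proportional to the band mean, and a per-sample factor h ~ U(1, 2)
  scaling both the spectral noise and the label jitter (sd 0.02·h of the
  sO₂ actually used to synthesize the spectrum around the recorded
  label). h also attenuates the bottom spectrum by `exp(−0.5(h−1))`,
  emulating the loss of deep signal on low-SNR peripheral A-lines — and
  making the per-sample noise level identifiable from the input, which is
  what lets a heteroscedastic regressor learn meaningful σ.
- Volumes: ribbon vessels with bright top/bottom wall layers, lumen
  signal following the forward model at path 2(z−top), weak lumen
  backscatter relative to the wall interfaces, a constant noise floor and
  an optional parabolic vignetting ramp.

What the generator does **not** emulate: interferogram-level OCT physics
(dispersion, sensitivity roll-off), speckle decorrelation, eye motion,
realistic vessel cross-sections, or the real covariate shift between
laboratories. Consequently, passing benchmarks show the estimators behave
correctly *under the stated noise model*, not that real-data accuracy
figures transfer. In particular, the real-data observation that predicted
σ roughly doubles on data from a completely unseen source does not
reproduce here: a smooth multiplicative bias moves the inputs too gently
off the training manifold to inflate the σ head, so that behaviour is
left undemonstrated rather than engineered in.

## Least-squares inversion (`dslox.lsf`)

After the log transform, `0.5·log(R₀A)` and `α` enter the objective
affinely and μ is affine in sO₂, so for fixed sO₂ the nuisance parameters
have a closed-form profile (ordinary least squares against
[1, −0.5 log λ]) and the profiled residual is **exactly quadratic** in
sO₂. The fit evaluates a 101-point sO₂ grid and refines with the
quadratic vertex, which for this objective is the exact global minimizer
on [0, 1]; the grid keeps boundary cases and degenerate (flat) objectives
deterministic. A is recovered through `exp` of the profiled intercept
(R₀ = 1 convention; only relative spectra matter after the log, so any
flat factor — including per-sample normalization — is absorbed into A).
α is unbounded. The fitting range must cover the 550–585 nm haemoglobin
contrast region and keep ≥ 3 bands; defaults are W = 0.12 with 548–586
nm. Hyperparameter optimization grids (W, range) and picks the labelled
MSE argmin; cells whose fits fail are excluded.

## Spectral regressors (`dslox.dsl`, `dslox._net`)

The two networks are small enough (1346 / 4292 parameters) that the
package carries its own dense/conv1d layers, backprop and Adam in numpy
(`dslox._net`), keeping training exactly reproducible with no framework
dependency.

- FNN: 28 → 24 ReLU → 24 ReLU → 2 sigmoid. CNN: two valid 1-D
  convolutions (kernel 3, 30 filters, ReLU), flatten, dense → 2 sigmoid.
  Both output channels are raw sigmoid values interpreted as fractions:
  the mean sO₂ and σ.
- Loss: heteroscedastic Gaussian NLL. **Mean** reduction over the batch
  during optimization (sum and mean differ only by a scale the learning
  rate absorbs; the likelihood-form sum is the `gaussian_nll_loss`
  default for analysis). σ is clamped at a floor of 10⁻³ inside the loss
  (with zero gradient when clamped) purely for numerical stability.
- Protocol: Adam (β₁ 0.9, β₂ 0.999; a plain-SGD switch exists), initial
  learning rate 2.5×10⁻³ decayed as lr₀/(1 + 0.01·N) with N the epoch
  index, 2000 epochs, batch 50, validation split 0.2, and the epoch
  checkpoint with minimum validation loss is returned. Weight
  initialization is Glorot-uniform, seeded.
- The validation split holds out whole animals when rat/setup ids are
  available, so validation-based model selection cannot leak
  within-animal correlations.
- The epoch's training loss is logged as the running average of
  minibatch losses (pre-update), and the validation loss from one full
  pass per epoch.

## Calibration (`dslox.calibration`)

The indicator uses a strict `<` (so η = 0 gives exactly P = 0; ties have
measure zero under continuous errors but the convention is fixed for
determinism). Bins are relaxed to σ₀ ± 1 % and may overlap; a prediction
can contribute to several bins, and the coverage fraction counts each
prediction once (membership in ≥ 1 bin). The η grid defaults to 0.1–3.0
in steps of 0.1. The calibration line is OLS of P against the theoretical
confidence erf(η/√2) — the diagonal-comparison axis — rather than against
η. Empty bins are a distinct signal (`EmptyBinError` / n = 0 rows), never
P = 0.

## En face maps (`dslox.enface`)

Per-pixel spectra are averaged over the k nearest in-vessel pixels
(2-D Euclidean distance in pixel units; the query pixel is included in
its own neighbourhood), background-subtracted using the per-band median
of out-of-vessel voxels, normalized into the 1×28 vector and passed
through any object with a `predict` method. Undefined pixels (failed
normalization, off-mask) stay NaN. Rendering maps values onto a
configurable hue arc (default red → yellow for low → high) with
saturation and value taken from the normalized intensity image, so
background renders grey and zero intensity renders black.

## Problem sizes and reproducibility

Benchmarks and the acceptance script use the default study sizes (2779
training / 502 testing spectra) with the full 2000-epoch protocol for
both networks; the hyperparameter optimization subsamples 400 labelled
training spectra (the MSE surface is smooth in W and range, and the
subsample keeps the grid search proportionate). Unit tests use
structurally identical scaled-down configurations
(`SyntheticDatasetConfig.small`). One global seed fans out to per-stage
seeds through `numpy.random.SeedSequence([seed, stage])`, making every
stage individually reproducible; fixed seed ⇒ identical dataset, weights,
report.

## Known limitations

- The bundled optical coefficients are an analytic stand-in; absolute
  sO₂ accuracy on real spectra is out of scope.
- LSF and the generator share the same forward family, so LSF failures
  in the benchmark come only from noise, normalization and inter-setup
  bias — a conservative comparison that, if anything, favours LSF.
- The σ head cannot signal out-of-distribution inputs under the smooth
  synthetic setup bias (see the generator section).
- Training is CPU-only by design; the networks are small enough that a
  full benchmark runs in minutes.
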