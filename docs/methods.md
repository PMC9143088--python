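# Methods

This note documents the models and algorithms in `seatherm`, the
defaults and why they were chosen, and what the synthetic experiments
do and do not demonstrate.

## Problem setting

Two channels observe the same quantity — the temperature of the
body–seat interface during a one-hour sitting trial, sampled at 1 Hz
(3600 samples):

* **DCTM** (direct contact): a probe in the interface; treated as
  ground truth.
* **NCTM** (non-contact): an infrared sensor under the cushion, reading
  through the foam. The foam attenuates and delays the signal, and the
  sensor adds impulsive spikes, white noise and slow ambient drift.

The pipeline denoises NCTM and regresses it (with foam covariates) onto
DCTM.

## Synthetic trial generator

No public recordings exist for this setting, so the generator produces
trial pairs with the statistical structure the analysis assumes. One
batch covers foam density {10.8, 22.1} kg/m³ × thickness 0.5–8 cm in
0.5 cm steps (32 trials). Every stochastic element is seeded; a trial's
seed derives deterministically from (master seed, density, thickness),
so batches are bit-reproducible.

**Contact channel.** A single-exponential saturation
`T(t) = T_eq − (T_eq − T_0)·exp(−t/τ)` with ambient start
`T_0 = 26.8 °C`, equilibrium `T_eq = 35.5 °C` and `τ = 900 s` — the
simplest physically plausible model of skin-contact warming. A smooth
zero-mean fluctuation (SD 0.02 °C, ≈120 s correlation) emulates
physiological variability; it keeps the curve monotone in expectation.

**Foam attenuation.** The time-averaged deficit Δ(thickness, density)
below the contact trace interpolates linearly in thickness between the
measured anchors (0.5 cm: 0.49 °C low / 0.84 °C intermediate; 8 cm:
4.09 °C low / 8.84 °C intermediate) — linearity is the minimal
assumption given only endpoint values. A first-order lag with time
constant 60 s per cm of foam emulates conduction delay; after the lag a
constant offset is set so the time-mean deficit equals Δ exactly.
Without the lag, NCTM would be a pure offset of DCTM and estimation
would be trivial.

**Sensor noise** (infrared channel only): Poisson-timed spikes at
20 events/hour with Laplace-distributed signed amplitudes (scale
0.75 °C), white Gaussian noise of SD 0.05 °C matching the sensor's
measured window-to-window reliability in chamber tests, and a
sinusoidal ambient drift bounded by 0.03 °C (period 20–40 min) —
consistent with a climate-controlled room. The spike scale follows an
energy-budget argument: an EMD-threshold filter removes at best the
fast dyadic bands (~15/16 of impulse energy), so the scale is set so
that the leaked impulse share stays below half of the white/drift
residual floor.

**Calibration sweeps.** Ascending then descending setpoints 20–50 °C in
5 °C steps, 20 samples per setpoint, response
`gain·setpoint + offset + N(0, σ²)` with an optional hysteresis shift
on the descending branch.

## EMD–FSI filter

**Sifting.** Extrema are strict three-point extrema; plateaus count
once at their midpoint (lower-index tie-break); endpoints are excluded.
Upper/lower envelopes are natural cubic splines through the extrema,
with the two extrema nearest each end mirrored about the endpoints to
suppress spline end-swings. One sift subtracts the envelope mean;
sifting stops by the envelope-amplitude criterion (|mean envelope| /
local envelope amplitude below θ₁ = 0.05 on all but a fraction
α = 0.05 of samples and below θ₂ = 0.5 everywhere, max 100 iterations).
This criterion was chosen over the simpler Cauchy relative-change rule
(still available via `sd_tol`) because the latter terminates after ~2
sifts and merges adjacent dyadic bands: white noise then splits into
~8 IMFs at N = 4096 instead of the ~log₂N expected from the dyadic
filter-bank behaviour of EMD. With the amplitude criterion the
decomposition recovers 10 IMFs at N = 4096 and 8 at N = 1024, a pure
sine sifts in one iteration, and reconstruction (sum of IMFs plus
residue) is exact to < 1e-9 by construction. Decomposition ends when
the remainder is monotone or has fewer than three extrema (max 12
IMFs).

**Fractal scaling index.** Each component (IMFs and residue alike) is
scored by first-order detrended fluctuation analysis: mean-removed
cumulative sum, non-overlapping boxes covering the profile from both
ends, per-box linear detrend, and the least-squares slope of
log₁₀ F(n) versus log₁₀ n over ≥ 10 log-spaced box sizes from 8 to N/4.
The estimator is calibrated: white noise scores 0.50 ± 0.02 and a
random walk 1.50 ± 0.04 (N = 4096, 25 seeds). Components scoring
strictly above the threshold (default 0.5) are retained and summed;
components too short (< 64 samples) or of zero variance default to
retained — the filter never silently deletes signal it cannot score.

**Interpretation caveat.** The scaling index of the source method is
not fully specified in the literature it draws on; DFA-1 is adopted
because its exponents match the interpretive frame (noise < 0.5,
trend-like residue ≥ 1). Absolute index values are therefore
implementation-specific; only the threshold classification is
meaningful across implementations.

## Network estimation

A single hidden layer of 10 tansig units with linear output; inputs
[filtered NCTM (°C), thickness (cm), density (kg/m³)] and the target
are min-max scaled to [−1, 1] on the training set (constant features
map to 0 so single-condition training works). One network is trained
across the whole batch — the covariates let it absorb the
thickness/density-dependent deficit — with a per-condition
single-feature mode available.

Training is Levenberg–Marquardt: the residual Jacobian is assembled
analytically by backpropagation; each step solves
`(JᵀJ + λI)δ = Jᵀr` with λ₀ = 1e-3, ×0.1 on accepted steps and ×10 on
rejections (stop at λ > 1e10 or max gradient < 1e-7, max 1000 epochs).
Samples are split 70/15/15 (uniform random, seeded; a contiguous-block
split is selectable because per-sample splits of a time series leak
autocorrelation between train and validation sets). Training stops
after six consecutive validation failures and returns the weights with
the best validation MSE. Weight init is uniform in [−0.5, 0.5], seeded;
identical seeds give bit-identical fits. Hidden widths 5–20 gave
similar batch errors in pilot sweeps; 10 is the default.

## Evaluation

RMSE, `NSE = 1 − Σ(T_d−T_e)²/Σ(T_d−T̄_d)²`, and MAE, with the exact
algebraic identity `NSE = 1 − N·RMSE²/Σ(T_d−T̄_d)²` used as a test
oracle. NSE on (near-)constant targets is refused rather than clamped.
Pearson ρ carries a two-sided t-test p-value (N−2 df); the thickness
effect on the DCTM−NCTM difference uses the classical one-way F test.
Calibration sweeps are summarised by window means versus setpoints:
maximum absolute error (accuracy), maximum within-window SD
(reliability), per-direction OLS lines with R² (linearity) and the
maximum ascending/descending difference at a setpoint (hysteresis).

## Problem sizes and runtime

Default experiments use the full 32-trial, 3600-sample batch
(decomposition ≈ 1 s/trial, training ≈ 1 min for ~115k samples and 51
weights); property suites use N = 512–4096 signals and 20–50 seeds.
A full batch runs in roughly 2–4 minutes on one CPU.

## What the synthetic experiments show — and don't

Passing tests demonstrate that the pipeline recovers the contact
temperature to a few hundredths of a degree *under the generator's
assumptions*: an exponential warming curve, linear-in-thickness
attenuation, stationary white + impulsive + sinusoidal noise. Real
recordings add effects deliberately out of scope: sweat and humidity
coupling, posture shifts and load redistribution, subject-to-subject
physiology, radiative interference. Results here bound the algorithmic,
not the physiological, error.

Known limitations:

* A single large spike (≳ 2 °C) occasionally lifts the DFA exponent of
  the noise IMF containing it just above the 0.5 threshold; the whole
  band is then retained and that trial's RMSE rises to ~0.1 °C. This
  false-retention mode is intrinsic to single-exponent thresholding
  under impulsive noise with an unbounded amplitude tail; ensemble EMD
  or adaptive thresholds would mitigate it but are out of scope.
* The attenuation model is static apart from a first-order lag; real
  foam conduction is distributed and nonlinear.
* One network per batch assumes the deficit varies smoothly with the
  covariates; unseen foam types require retraining.
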