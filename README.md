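# seatherm

Non-contact monitoring of the body–seat interface temperature.

Prolonged sitting warms and humidifies the occluded interface between a
person and their seat cushion — a microclimate implicated in sitting
discomfort and pressure-ulcer risk. The gold standard is a contact probe
placed in the interface (DCTM), but the probe itself perturbs the
microclimate it measures. An alternative is an infrared sensor reading
the interface *through* the foam cushion from below (NCTM): unobtrusive,
but attenuated by the foam (more with thicker and denser cushions) and
contaminated by spikes, sensor noise and ambient drift.

`seatherm` implements the full analysis chain for recovering the contact
temperature from the through-foam reading, together with a synthetic
trial generator so that every stage is testable without access to human
recordings:

1. **Synthetic trials** — one-hour 1 Hz trial pairs over a 2-density
   (10.8 / 22.1 kg/m³) × 16-thickness (0.5–8 cm) grid: an exponential
   warming curve toward skin equilibrium for the contact channel, a
   thickness/density-dependent attenuation with conduction lag for the
   infrared channel, plus impulsive spikes, white sensor noise and slow
   drift. Chamber calibration sweeps (20–50 °C in 5 °C steps) for sensor
   performance assessment.
2. **EMD–FSI filter** — empirical mode decomposition by cubic-spline
   sifting splits the raw trace into intrinsic mode functions (IMFs) and
   a residue; each component receives a fractal scaling index (FSI,
   computed by first-order detrended fluctuation analysis); components
   with FSI ≤ 0.5 (noise-like: white noise scores ≈ 0.5, trends score
   ≥ 1) are discarded and the rest are summed back.
3. **Neural estimation** — a three-layer network
   `y = w_out · tanh(W_in x + b) + b_out` with inputs
   [filtered NCTM, thickness, density], trained by Levenberg–Marquardt
   on a 70/15/15 split, maps the denoised reading to the contact
   temperature.
4. **Evaluation** — RMSE, Nash–Sutcliffe efficiency
   `NSE = 1 − Σ(T_d−T_e)²/Σ(T_d−T̄_d)²`, MAE, Pearson correlation,
   one-way ANOVA of the thickness effect, and calibration statistics
   (linearity, accuracy, reliability, hysteresis).

## Worked example

A single low-density 5 cm trial, end to end:

```python
import seatherm as st

cond = st.TrialCondition(density=10.8, thickness=5.0)
trial = st.generate_trial(cond, master_seed=1)

filtered, report = st.denoise(trial.nctm_raw)
print("FSI:", [round(f, 3) for f in report.component_fsi])
print("raw  RMSE vs noise-free:", st.rmse(trial.nctm_noise_free.values, trial.nctm_raw.values))
print("filt RMSE vs noise-free:", st.rmse(trial.nctm_noise_free.values, filtered.values))

res = st.TemperatureANN.from_trials([filtered], [trial.dctm], n_hidden=10).fit(
    split_seed=1, init_seed=1)
est = res.estimate_trial(filtered, cond)
rep = st.MetricsReport.from_series(trial.dctm.values, est.values)
print("estimate vs DCTM: RMSE %.3f  MAE %.3f  NSE %.4f" % (rep.rmse, rep.mae, rep.nse))
```

prints

```
FSI: [0.312, 0.303, 0.224, 0.287, 0.381, 0.594, 0.967, 1.153, 2.002, 2.01]
raw  RMSE vs noise-free: 0.095
filt RMSE vs noise-free: 0.034
estimate vs DCTM: RMSE 0.028  MAE 0.020  NSE 0.9998
```

The decomposition yields nine IMFs plus a residue; the first five score
below the 0.5 threshold (noise-like) and are discarded, the filter cuts
the error against the noise-free truth by two thirds, and the fitted
network tracks the contact warming curve to within 0.03 °C with NSE
essentially 1. The classic component-selection illustration — nine
components whose printed scaling indices split 4 discarded / 5 retained
at threshold 0.5 — is available as
`st.run_worked_example()`.

The full 32-trial experiment (simulate → denoise → train one network
across all trials → per-trial metrics tables) is one call,
`st.run_batch(st.BatchConfig(master_seed=1))`, or from the shell:

```sh
seatherm run-all --seed 1 --out results/batch
```

which writes per-trial trace CSVs (`time_s,temp_C`), FSI reports (JSON),
and the summary tables (per-trial RMSE/MAE/NSE, raw-correlation and
mean-deficit tables) as CSV.

## Documentation

`docs/methods.md` describes the generator's assumptions, the filter and
training algorithms, parameter defaults with units, and known
limitations.
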