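"""Synthetic generator for paired contact / through-foam thermal traces.

The generator emulates the structure of one-hour sitting trials: the
contact probe (DCTM) warms from ambient toward skin equilibrium along a
single-exponential saturation curve; the infrared channel (NCTM) sees the
same signal attenuated by the foam — a thickness- and density-dependent
temperature deficit plus a first-order conduction lag — and corrupted by
impulsive spikes, white sensor noise and a slow ambient drift.  Chamber
calibration sweeps (20-50 degC, 5 degC steps, 20 samples per setpoint) are
generated for the sensor-performance analyses.

Every stochastic operation takes an explicit seed; a trial's seed is
derived deterministically from (master_seed, density, thickness) so a full
32-trial batch is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .traces import (
    DENSITIES,
    INTERMEDIATE_DENSITY,
    LOW_DENSITY,
    THICKNESS_GRID,
    TRIAL_SAMPLES,
    CalibrationRun,
    ParameterError,
    ThermalTrace,
    TrialCondition,
)

# Time-averaged DCTM-NCTM deficit anchors, degC, at the thickness extremes.
# The deficit interpolates linearly in thickness between them, per density.
DEFICIT_ANCHORS = {
    LOW_DENSITY: {0.5: 0.49, 8.0: 4.09},
    INTERMEDIATE_DENSITY: {0.5: 0.84, 8.0: 8.84},
}

#: Default warming-curve parameters.
DEFAULT_EQUIL_C = 35.5
DEFAULT_TAU_S = 900.0
#: Smooth physiological fluctuation superposed on the warming curve.
DEFAULT_FLUCT_SD = 0.02
FLUCT_SMOOTH_S = 120.0
#: Conduction lag time constant per cm of foam.
LAG_S_PER_CM = 60.0
#: NCTM sensor-noise defaults.
DEFAULT_SPIKE_RATE = 20.0   # events/hour
DEFAULT_SPIKE_AMP = 0.75    # Laplace scale, degC
DEFAULT_WHITE_SD = 0.05     # degC, matches the sensor's documented reliability
DEFAULT_DRIFT_AMP = 0.03    # degC


def mean_deficit(thickness: float, density: float) -> float:
    """Interpolated DCTM-NCTM deficit Delta(thickness, density) in degC.

    Linear in thickness between the 0.5 cm and 8 cm anchors of the given
    density class; strictly increasing in thickness and larger for the
    intermediate density at every thickness.
    """
    if density not in DENSITIES:
        raise ParameterError(f"unknown foam density {density}; expected one of {DENSITIES}")
    anchors = DEFICIT_ANCHORS[density]
    t0, t1 = 0.5, 8.0
    d0, d1 = anchors[t0], anchors[t1]
    return d0 + (d1 - d0) * (thickness - t0) / (t1 - t0)


def _smooth_fluctuation(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth fluctuation with the requested sample SD."""
    if sd <= 0:
        return np.zeros(n)
    raw = rng.standard_normal(n + 4 * int(FLUCT_SMOOTH_S))
    kernel = np.exp(-0.5 * ((np.arange(-3 * FLUCT_SMOOTH_S, 3 * FLUCT_SMOOTH_S + 1))
                            / FLUCT_SMOOTH_S) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[2 * int(FLUCT_SMOOTH_S):][:n]
    smooth -= smooth.mean()
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def generate_dctm(
    condition: TrialCondition,
    equil_temp: float = DEFAULT_EQUIL_C,
    time_constant: float = DEFAULT_TAU_S,
    seed: int = 0,
    n_samples: int = TRIAL_SAMPLES,
    fluct_sd: float = DEFAULT_FLUCT_SD,
) -> ThermalTrace:
    """Simulate the contact-probe warming curve for one trial.

    T(t) = equil - (equil - T0) * exp(-t / tau) with T0 the ambient
    temperature, plus a small smooth fluctuation (SD ``fluct_sd`` <= 0.05
    degC) emulating physiological variability.
    """
    if time_constant <= 0:
        raise ParameterError(f"time_constant must be positive, got {time_constant}")
    t0 = condition.ambient_temp
    if equil_temp <= t0:
        raise ParameterError(
            f"equil_temp ({equil_temp}) must exceed ambient ({t0})"
        )
    if fluct_sd > 0.05:
        raise ParameterError("fluctuation SD must not exceed 0.05 degC")
    t = np.arange(n_samples, dtype=float)
    values = equil_temp - (equil_temp - t0) * np.exp(-t / time_constant)
    rng = np.random.default_rng(seed)
    values = values + _smooth_fluctuation(n_samples, fluct_sd, rng)
    return ThermalTrace(values=values, channel="DCTM", condition=condition)


def apply_foam_attenuation(
    dctm: ThermalTrace,
    condition: TrialCondition | None = None,
    lag_s_per_cm: float = LAG_S_PER_CM,
) -> ThermalTrace:
    """Attenuate a contact trace into the noise-free through-foam channel.

    A first-order exponential lag (time constant ``lag_s_per_cm`` x
    thickness) emulates conduction delay through the foam; a constant
    offset is then chosen so the time-averaged deficit below the contact
    trace equals the interpolated Delta(thickness, density).
    """
    if dctm.channel != "DCTM":
        raise ParameterError(f"expected a DCTM trace, got channel {dctm.channel!r}")
    condition = condition or dctm.condition
    if condition is None:
        raise ParameterError("a trial condition is required")
    delta = mean_deficit(condition.thickness, condition.density)
    tau = lag_s_per_cm * condition.thickness
    x = dctm.values
    if tau > 0:
        alpha = 1.0 - np.exp(-1.0 / tau)  # 1 Hz first-order smoother
        lagged = lfilter([alpha], [1.0, alpha - 1.0], x, zi=[(1 - alpha) * x[0]])[0]
    else:
        lagged = x.copy()
    offset = delta - float(np.mean(x - lagged))
    out = lagged - offset
    return ThermalTrace(values=out, channel="NCTM_noise_free", condition=condition)


def add_sensor_noise(
    trace: ThermalTrace,
    spike_rate: float = DEFAULT_SPIKE_RATE,
    spike_amp: float = DEFAULT_SPIKE_AMP,
    white_sd: float = DEFAULT_WHITE_SD,
    drift_amp: float = DEFAULT_DRIFT_AMP,
    seed: int = 0,
) -> ThermalTrace:
    """Corrupt a noise-free NCTM trace with the infrared sensor's artefacts.

    Adds Poisson-timed impulsive spikes with Laplace-distributed signed
    amplitudes (scale ``spike_amp``), white Gaussian noise of SD
    ``white_sd``, and a slow sinusoidal ambient drift bounded by
    ``drift_amp``.  The result carries channel ``NCTM_raw``.
    """
    for name, v in [("spike_rate", spike_rate), ("spike_amp", spike_amp),
                    ("white_sd", white_sd), ("drift_amp", drift_amp)]:
        if v < 0:
            raise ParameterError(f"{name} must be non-negative, got {v}")
    rng = np.random.default_rng(seed)
    n = len(trace)
    out = trace.values.copy()

    hours = n / 3600.0
    n_spikes = rng.poisson(spike_rate * hours)
    if n_spikes > 0 and spike_amp > 0:
        idx = rng.integers(0, n, size=n_spikes)
        amps = rng.laplace(0.0, spike_amp, size=n_spikes)
        np.add.at(out, idx, amps)

    if white_sd > 0:
        out += rng.normal(0.0, white_sd, size=n)

    if drift_amp > 0:
        period = rng.uniform(1200.0, 2400.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        t = np.arange(n, dtype=float)
        out += drift_amp * np.sin(2 * np.pi * t / period + phase)

    return ThermalTrace(values=out, channel="NCTM_raw", condition=trace.condition)


def generate_calibration_run(
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    hysteresis_offset: float = 0.0,
    sensor_id: str = "IRs",
) -> CalibrationRun:
    """Simulate an ascending/descending chamber calibration sweep.

    Each setpoint window holds 20 samples of ``gain * setpoint + offset``
    plus Gaussian noise; descending windows are additionally shifted by
    ``hysteresis_offset`` to emulate sensor hysteresis.
    """
    if gain <= 0:
        raise ParameterError(f"gain must be positive, got {gain}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    up = np.arange(20.0, 50.01, 5.0)
    down = up[::-1]
    windows_up = [gain * s + offset + rng.normal(0.0, noise_sd, CalibrationRun.WINDOW)
                  for s in up]
    windows_down = [gain * s + offset + hysteresis_offset
                    + rng.normal(0.0, noise_sd, CalibrationRun.WINDOW)
                    for s in down]
    return CalibrationRun(setpoints_up=up, setpoints_down=down,
                          windows_up=windows_up, windows_down=windows_down,
                          sensor_id=sensor_id)


@dataclass(frozen=True)
class Trial:
    """One generated trial: condition, ground truth and all NCTM channels."""

    condition: TrialCondition
    dctm: ThermalTrace
    nctm_noise_free: ThermalTrace
    nctm_raw: ThermalTrace
    seed: int


def trial_seed(master_seed: int, density: float, thickness: float) -> int:
    """Stable per-trial seed below 2**31 derived from the batch master seed."""
    d_idx = DENSITIES.index(density)
    t_idx = int(round(thickness / 0.5)) - 1
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(d_idx, t_idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def generate_trial(
    condition: TrialCondition,
    master_seed: int = 0,
    *,
    equil_temp: float = DEFAULT_EQUIL_C,
    time_constant: float = DEFAULT_TAU_S,
    fluct_sd: float = DEFAULT_FLUCT_SD,
    lag_s_per_cm: float = LAG_S_PER_CM,
    spike_rate: float = DEFAULT_SPIKE_RATE,
    spike_amp: float = DEFAULT_SPIKE_AMP,
    white_sd: float = DEFAULT_WHITE_SD,
    drift_amp: float = DEFAULT_DRIFT_AMP,
    n_samples: int = TRIAL_SAMPLES,
) -> Trial:
    """Generate one full trial (DCTM, noise-free NCTM, raw NCTM)."""
    seed = trial_seed(master_seed, condition.density, condition.thickness)
    dctm = generate_dctm(condition, equil_temp, time_constant, seed=seed,
                         n_samples=n_samples, fluct_sd=fluct_sd)
    clean = apply_foam_attenuation(dctm, condition, lag_s_per_cm=lag_s_per_cm)
    raw = add_sensor_noise(clean, spike_rate=spike_rate, spike_amp=spike_amp,
                           white_sd=white_sd, drift_amp=drift_amp,
                           seed=seed + 1)
    return Trial(condition=condition, dctm=dctm, nctm_noise_free=clean,
                 nctm_raw=raw, seed=seed)


def standard_conditions(ambient_temp: float = 26.8,
                        ambient_rh: float = 64.6) -> list[TrialCondition]:
    """The full 2-density x 16-thickness grid in deterministic order."""
    return [
        TrialCondition(density=d, thickness=t, ambient_temp=ambient_temp,
                       ambient_rh=ambient_rh)
        for d in DENSITIES
        for t in THICKNESS_GRID
    ]


def generate_batch(master_seed: int = 0, conditions: list[TrialCondition] | None = None,
                   **trial_kwargs) -> list[Trial]:
    """Generate the full (default 32-trial) batch reproducibly."""
    conditions = conditions if conditions is not None else standard_conditions()
    return [generate_trial(c, master_seed, **trial_kwargs) for c in conditions]
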