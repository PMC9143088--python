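"""Core data containers for body-seat interface temperature trials.

A trial pairs a direct contact temperature measurement (DCTM, a probe in
the body-seat interface) with a non-contact measurement (NCTM, an infrared
sensor reading taken through the foam cushion from below).  Both are
uniformly sampled 1 Hz series in degrees Celsius over a one-hour sitting
trial (3600 samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Foam densities studied, kg/m^3.
LOW_DENSITY = 10.8
INTERMEDIATE_DENSITY = 22.1
DENSITIES = (LOW_DENSITY, INTERMEDIATE_DENSITY)

#: Cushion thickness grid, cm: 0.5 to 8.0 in 0.5 cm steps (16 levels).
THICKNESS_GRID = tuple(np.round(np.arange(0.5, 8.01, 0.5), 1))

#: Channel roles a trace can carry.
CHANNELS = ("DCTM", "NCTM_raw", "NCTM_filtered", "NCTM_noise_free", "estimate")

SAMPLE_RATE_HZ = 1.0
TRIAL_SAMPLES = 3600


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


@dataclass(frozen=True)
class TrialCondition:
    """Foam and ambient context for one one-hour sitting trial.

    Parameters
    ----------
    density : float
        Foam density in kg/m^3; 10.8 ("low") or 22.1 ("intermediate").
    thickness : float
        Cushion thickness in cm, a positive multiple of 0.5 up to 8.0.
    ambient_temp : float
        Room temperature in degrees C (20-35).
    ambient_rh : float
        Relative humidity, percent.
    label : str
        Short tag such as "A1" (low density, 0.5 cm).
    """

    density: float
    thickness: float
    ambient_temp: float = 26.8
    ambient_rh: float = 64.6
    label: str = ""

    def __post_init__(self) -> None:
        if self.density not in DENSITIES:
            raise ParameterError(
                f"density must be one of {DENSITIES} kg/m^3, got {self.density}"
            )
        t = self.thickness
        if not (0 < t <= 8.0) or abs(round(t / 0.5) * 0.5 - t) > 1e-9:
            raise ParameterError(
                f"thickness must be a positive multiple of 0.5 cm <= 8.0, got {t}"
            )
        if not (20.0 <= self.ambient_temp <= 35.0):
            raise ParameterError(
                f"ambient_temp must lie in [20, 35] degC, got {self.ambient_temp}"
            )
        if not self.label:
            prefix = "A" if self.density == LOW_DENSITY else "B"
            object.__setattr__(
                self, "label", f"{prefix}{int(round(self.thickness / 0.5))}"
            )

    @property
    def density_class(self) -> str:
        return "low" if self.density == LOW_DENSITY else "intermediate"

    def to_dict(self) -> dict:
        return {
            "density_kg_m3": self.density,
            "thickness_cm": self.thickness,
            "ambient_c": self.ambient_temp,
            "ambient_rh": self.ambient_rh,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialCondition":
        return cls(
            density=d["density_kg_m3"],
            thickness=d["thickness_cm"],
            ambient_temp=d.get("ambient_c", 26.8),
            ambient_rh=d.get("ambient_rh", 64.6),
            label=d.get("label", ""),
        )


@dataclass
class ThermalTrace:
    """A uniformly sampled 1 Hz temperature series with a channel role."""

    values: np.ndarray
    channel: str
    condition: TrialCondition | None = None
    rate: float = SAMPLE_RATE_HZ
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_offset + np.arange(len(self.values)) / self.rate

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "ThermalTrace":
        return replace(self, values=np.asarray(values, dtype=float),
                       channel=channel or self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "temp_C": self.values})

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as ``time_s,temp_C`` CSV (UTF-8, '.' decimal)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, channel: str,
                 condition: TrialCondition | None = None) -> "ThermalTrace":
        df = pd.read_csv(path)
        if not {"time_s", "temp_C"}.issubset(df.columns):
            raise ParameterError(f"{path}: expected columns time_s,temp_C")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0]):
                raise ParameterError(f"{path}: non-uniform sampling")
            rate = 1.0 / dt[0]
        else:
            rate = SAMPLE_RATE_HZ
        return cls(values=df["temp_C"].to_numpy(dtype=float), channel=channel,
                   condition=condition, rate=rate, start_offset=float(t[0]) if len(t) else 0.0)


@dataclass
class CalibrationRun:
    """Ascending/descending chamber calibration sweep, 20-50 degC in 5 degC steps.

    Each setpoint holds a block of 20 one-second sensor readings.
    """

    setpoints_up: np.ndarray
    setpoints_down: np.ndarray
    windows_up: list[np.ndarray]
    windows_down: list[np.ndarray]
    sensor_id: str = "IRs"

    WINDOW = 20

    def __post_init__(self) -> None:
        self.setpoints_up = np.asarray(self.setpoints_up, dtype=float)
        self.setpoints_down = np.asarray(self.setpoints_down, dtype=float)
        expected_up = np.arange(20.0, 50.01, 5.0)
        if not (np.array_equal(self.setpoints_up, expected_up)
                and np.array_equal(self.setpoints_down, expected_up[::-1])):
            raise ParameterError("setpoints must run 20..50 degC in 5 degC steps, up then down")
        for w in [*self.windows_up, *self.windows_down]:
            if len(w) != self.WINDOW:
                raise ParameterError(f"each setpoint window must hold {self.WINDOW} samples")


def write_trial(directory: str | Path, condition: TrialCondition,
                traces: dict[str, ThermalTrace], seed: int | None = None) -> None:
    """Write one trial: a `<label>_<channel>.csv` per trace plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel, trace in traces.items():
        trace.to_csv(directory / f"{condition.label}_{channel}.csv")
    meta = condition.to_dict()
    if seed is not None:
        meta["seed"] = int(seed)
    (directory / f"{condition.label}.json").write_text(json.dumps(meta, indent=1))


def read_trial(directory: str | Path, label: str) -> tuple[TrialCondition, dict[str, ThermalTrace]]:
    """Round-trip reader for :func:`write_trial` output."""
    directory = Path(directory)
    meta = json.loads((directory / f"{label}.json").read_text())
    condition = TrialCondition.from_dict(meta)
    traces = {}
    for channel in CHANNELS:
        path = directory / f"{label}_{channel}.csv"
        if path.exists():
            traces[channel] = ThermalTrace.from_csv(path, channel, condition)
    return condition, traces
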