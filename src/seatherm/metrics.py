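"""Estimation, association and sensor-calibration metrics.

Estimation quality of an estimate Te against the contact ground truth Td:

    RMSE = sqrt( (1/N) sum (Td - Te)^2 )
    NSE  = 1 - sum (Td - Te)^2 / sum (Td - mean(Td))^2
    MAE  = (1/N) sum |Td - Te|

NSE (Nash-Sutcliffe efficiency) is 1 for a perfect estimate and 0 for
predicting the target mean.  Association uses the Pearson product-moment
coefficient; the thickness effect on the contact/non-contact difference
uses classical one-way ANOVA.  Calibration sweeps are summarised by
window-mean errors, per-direction OLS lines and hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import CalibrationRun, ParameterError


class UndefinedMetricError(ValueError):
    """Metric undefined for degenerate inputs (e.g. constant target)."""


def _as_pair(td, te) -> tuple[np.ndarray, np.ndarray]:
    td = np.asarray(td, dtype=float).ravel()
    te = np.asarray(te, dtype=float).ravel()
    if len(td) != len(te):
        raise ParameterError(f"length mismatch: {len(td)} vs {len(te)}")
    if len(td) == 0:
        raise ParameterError("empty series")
    return td, te


def rmse(td, te) -> float:
    """Root mean square error in degC."""
    td, te = _as_pair(td, te)
    return float(np.sqrt(np.mean((td - te) ** 2)))


def nse(td, te) -> float:
    """Nash-Sutcliffe efficiency (dimensionless, <= 1)."""
    td, te = _as_pair(td, te)
    denom = float(np.sum((td - td.mean()) ** 2))
    if denom == 0:
        raise UndefinedMetricError("NSE undefined for a constant target")
    return float(1.0 - np.sum((td - te) ** 2) / denom)


def mae(td, te) -> float:
    """Mean absolute error in degC."""
    td, te = _as_pair(td, te)
    return float(np.mean(np.abs(td - te)))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment rho with a two-sided t-test p-value."""
    x, y = _as_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova_thickness(differences_by_group: dict) -> tuple[float, float]:
    """One-way ANOVA of per-sample (DCTM - NCTM) differences across thicknesses.

    Returns the classical F statistic with its p-value from F(k-1, N-k).
    All-identical-constant groups make F undefined and raise.
    """
    groups = [np.asarray(v, dtype=float) for v in differences_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise UndefinedMetricError("ANOVA undefined: all values identical")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class MetricsReport:
    """Estimation metrics for one trial (or pooled trial set)."""

    rmse: float
    nse: float
    mae: float
    pearson_rho: float
    pearson_p: float
    n: int
    mean_target: float

    @classmethod
    def from_series(cls, td, te) -> "MetricsReport":
        td_a, te_a = _as_pair(td, te)
        rho, p = pearson(td_a, te_a)
        return cls(rmse=rmse(td_a, te_a), nse=nse(td_a, te_a), mae=mae(td_a, te_a),
                   pearson_rho=rho, pearson_p=p, n=len(td_a),
                   mean_target=float(np.mean(td_a)))


@dataclass
class LineFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class CalibrationReport:
    """Linearity, accuracy, reliability and hysteresis of a chamber sweep."""

    line_up: LineFit
    line_down: LineFit
    max_abs_error: float
    max_window_sd: float
    max_hysteresis: float


def assess_calibration(run: CalibrationRun) -> CalibrationReport:
    """Window means vs setpoints: OLS lines per direction, worst-case errors."""
    means_up = np.array([np.mean(w) for w in run.windows_up])
    means_down = np.array([np.mean(w) for w in run.windows_down])
    sds = np.array([np.std(w, ddof=1) for w in [*run.windows_up, *run.windows_down]])

    def _fit(setpoints, means) -> LineFit:
        res = stats.linregress(setpoints, means)
        return LineFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))

    errors = np.concatenate([means_up - run.setpoints_up,
                             means_down - run.setpoints_down])
    # Hysteresis pairs ascending/descending means at the same setpoint.
    down_at = {s: m for s, m in zip(run.setpoints_down, means_down)}
    hysteresis = max(abs(m - down_at[s]) for s, m in zip(run.setpoints_up, means_up))
    return CalibrationReport(
        line_up=_fit(run.setpoints_up, means_up),
        line_down=_fit(run.setpoints_down, means_down),
        max_abs_error=float(np.max(np.abs(errors))),
        max_window_sd=float(np.max(sds)),
        max_hysteresis=float(hysteresis),
    )
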