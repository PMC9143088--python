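"""Feed-forward estimation of the contact-surface temperature.

A three-layer network maps the denoised through-foam reading plus foam
covariates (thickness, density) to the contact temperature:

    y = w_out . tanh(W_in x + b_hidden) + b_out

with inputs and target min-max scaled to [-1, 1].  Weights are trained by
Levenberg-Marquardt: the Jacobian of the per-sample residuals with
respect to all weights is assembled by backpropagation and each step
solves (J'J + lambda I) d = J'r, with the damping lambda decreased on
improvement and increased on rejection.  Samples are split 70/15/15 into
training/validation/test sets; the weights with the best validation error
are returned (early stopping on validation patience).

The public surface follows the Model / Results convention: build a
:class:`TemperatureANN` from features and targets (or from denoised
trials via :meth:`TemperatureANN.from_trials`), call :meth:`fit`, and
read estimates and diagnostics off the returned
:class:`TemperatureANNResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import ParameterError, ThermalTrace, TrialCondition

DEFAULT_N_HIDDEN = 10


class TrainingFailure(RuntimeError):
    """Levenberg-Marquardt could not take any valid step."""


class ScalingError(ValueError):
    """A feature or target range is degenerate where it must not be."""


@dataclass(frozen=True)
class LMConfig:
    """Levenberg-Marquardt schedule and stopping rules."""

    lambda0: float = 1e-3
    lambda_increase: float = 10.0
    lambda_decrease: float = 0.1
    lambda_max: float = 1e10
    max_epochs: int = 1000
    patience: int = 6          # consecutive validation-MSE increases tolerated
    grad_tol: float = 1e-7
    init_scale: float = 0.5    # uniform weight init in [-init_scale, init_scale]


@dataclass
class MinMaxScaler:
    """Per-column min-max map to [-1, 1]; constant columns map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return cls(lo=x.min(axis=0), hi=x.max(axis=0))

    @property
    def span(self) -> np.ndarray:
        return self.hi - self.lo

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.span
        out = np.zeros_like(x, dtype=float)
        ok = span > 0
        out[..., ok] = 2.0 * (x[..., ok] - self.lo[ok]) / span[ok] - 1.0
        return out

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        span = self.span
        mid = (self.lo + self.hi) / 2.0
        return np.where(span > 0, (z + 1.0) / 2.0 * span + self.lo, mid)


@dataclass
class ANNModel:
    """Weights, transfer functions and scalings of a fitted network."""

    w_in: np.ndarray       # (n_hidden, n_features)
    b_hidden: np.ndarray   # (n_hidden,)
    w_out: np.ndarray      # (n_hidden,)
    b_out: float
    input_scaling: MinMaxScaler
    target_scaling: MinMaxScaler
    hidden_transfer: str = "tansig"
    output_transfer: str = "linear"

    @property
    def n_hidden(self) -> int:
        return len(self.b_hidden)

    @property
    def n_features(self) -> int:
        return self.w_in.shape[1]


def build_features(nctm_filtered: ThermalTrace,
                   condition: TrialCondition | None = None,
                   include_condition: bool = True) -> np.ndarray:
    """Per-sample feature matrix [NCTM_filtered degC, thickness cm, density kg/m3].

    With ``include_condition=False`` only the temperature column is used
    (per-condition single-feature mode).
    """
    if nctm_filtered.channel != "NCTM_filtered":
        raise ParameterError(
            f"expected NCTM_filtered trace, got {nctm_filtered.channel!r}")
    condition = condition or nctm_filtered.condition
    n = len(nctm_filtered)
    cols = [nctm_filtered.values]
    if include_condition:
        if condition is None:
            raise ParameterError("condition required for covariate features")
        cols += [np.full(n, condition.thickness), np.full(n, condition.density)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class DataSplit:
    """70/15/15 train/validation/test index partition."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0


def split_data(n_samples: int, seed: int = 0,
               fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
               method: str = "random") -> DataSplit:
    """Seeded 70/15/15 partition into train/validation/test sets.

    ``method="random"`` draws a uniform per-sample partition.
    ``method="blocks"`` assigns three contiguous index blocks in a
    seeded random order — for time series this avoids leaking
    autocorrelated neighbours between training and validation.
    """
    if n_samples < 20:
        raise ParameterError(f"need at least 20 samples to split, got {n_samples}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_train = int(round(fractions[0] * n_samples))
    n_val = int(round(fractions[1] * n_samples))
    if method == "random":
        perm = rng.permutation(n_samples)
        parts = {"train": perm[:n_train], "val": perm[n_train:n_train + n_val],
                 "test": perm[n_train + n_val:]}
    elif method == "blocks":
        sizes = {"train": n_train, "val": n_val,
                 "test": n_samples - n_train - n_val}
        order = [list(sizes)[i] for i in rng.permutation(3)]
        parts, start = {}, 0
        for name in order:
            parts[name] = np.arange(start, start + sizes[name])
            start += sizes[name]
    else:
        raise ParameterError(f"unknown split method {method!r}")
    return DataSplit(train_idx=np.sort(parts["train"]),
                     val_idx=np.sort(parts["val"]),
                     test_idx=np.sort(parts["test"]),
                     fractions=fractions, seed=seed)


def _forward_scaled(w_in, b_hidden, w_out, b_out, xs: np.ndarray) -> np.ndarray:
    z = np.tanh(xs @ w_in.T + b_hidden)
    return z @ w_out + b_out


def forward(model: ANNModel, x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; accepts one sample or a matrix, returns degC."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xm = np.atleast_2d(x)
    if xm.shape[1] != model.n_features:
        raise ParameterError(
            f"expected {model.n_features} features, got {xm.shape[1]}")
    xs = model.input_scaling.transform(xm)
    ys = _forward_scaled(model.w_in, model.b_hidden, model.w_out, model.b_out, xs)
    y = model.target_scaling.inverse(ys[:, None])[:, 0]
    return float(y[0]) if single else y


def _unpack(theta: np.ndarray, n_hidden: int, n_features: int):
    k = n_hidden * n_features
    w_in = theta[:k].reshape(n_hidden, n_features)
    b_hidden = theta[k:k + n_hidden]
    w_out = theta[k + n_hidden:k + 2 * n_hidden]
    b_out = theta[-1]
    return w_in, b_hidden, w_out, b_out


def _jacobian(theta: np.ndarray, xs: np.ndarray, n_hidden: int) -> tuple[np.ndarray, np.ndarray]:
    """Network output and d(output)/d(theta) for scaled inputs, by backprop."""
    n, n_features = xs.shape
    w_in, b_hidden, w_out, b_out = _unpack(theta, n_hidden, n_features)
    z = np.tanh(xs @ w_in.T + b_hidden)          # (n, H)
    y = z @ w_out + b_out
    dz = (1.0 - z ** 2) * w_out                  # (n, H): dy/d(pre-activation)
    j_win = dz[:, :, None] * xs[:, None, :]      # (n, H, F)
    jac = np.concatenate([
        j_win.reshape(n, n_hidden * n_features),
        dz,                                      # d/db_hidden
        z,                                       # d/dw_out
        np.ones((n, 1)),                         # d/db_out
    ], axis=1)
    return y, jac


@dataclass
class TrainingHistory:
    """Per-epoch record of the LM run (accepted steps only for MSE columns)."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    stop_reason: str = ""
    epochs: int = 0


def train_lm(features: np.ndarray, targets: np.ndarray, split: DataSplit,
             n_hidden: int = DEFAULT_N_HIDDEN, lm_config: LMConfig | None = None,
             seed: int = 0) -> tuple[ANNModel, TrainingHistory]:
    """Fit the network weights by Levenberg-Marquardt with early stopping.

    Scalings are fitted on the training set only; constant features map
    to 0 so single-condition training works.  Returns the weights with
    the best validation MSE seen.
    """
    cfg = lm_config or LMConfig()
    if n_hidden < 1:
        raise ParameterError(f"n_hidden must be >= 1, got {n_hidden}")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if len(x) != len(y):
        raise ParameterError("features and targets length mismatch")

    in_scaler = MinMaxScaler.fit(x[split.train_idx])
    t_scaler = MinMaxScaler.fit(y[split.train_idx, None])
    if not np.any(in_scaler.span > 0):
        raise ScalingError("all features are constant on the training set")
    if t_scaler.span[0] <= 0:
        raise ScalingError("target has zero range on the training set")

    xs = in_scaler.transform(x)
    ys = t_scaler.transform(y[:, None])[:, 0]
    xs_tr, ys_tr = xs[split.train_idx], ys[split.train_idx]
    xs_val, ys_val = xs[split.val_idx], ys[split.val_idx]

    n_features = xs.shape[1]
    n_params = n_hidden * n_features + 2 * n_hidden + 1
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-cfg.init_scale, cfg.init_scale, size=n_params)

    lam = cfg.lambda0
    pred, jac = _jacobian(theta, xs_tr, n_hidden)
    resid = ys_tr - pred
    train_mse = float(np.mean(resid ** 2))
    best_theta = theta.copy()
    best_val = float(np.mean((ys_val - _forward_scaled(
        *_unpack(theta, n_hidden, n_features), xs_val)) ** 2)) if len(ys_val) else np.inf
    history = TrainingHistory()
    bad_val_steps = 0
    ever_accepted = False

    for epoch in range(cfg.max_epochs):
        history.epochs = epoch + 1
        grad = jac.T @ resid
        if float(np.max(np.abs(grad))) < cfg.grad_tol:
            history.stop_reason = "gradient tolerance"
            break
        jtj = jac.T @ jac
        try:
            delta = np.linalg.solve(jtj + lam * np.eye(n_params), grad)
        except np.linalg.LinAlgError:
            if not ever_accepted:
                raise TrainingFailure("singular normal equations at start")
            history.stop_reason = "singular normal equations"
            break
        theta_new = theta + delta
        pred_new, jac_new = _jacobian(theta_new, xs_tr, n_hidden)
        resid_new = ys_tr - pred_new
        mse_new = float(np.mean(resid_new ** 2))

        if mse_new < train_mse:
            theta, pred, jac, resid = theta_new, pred_new, jac_new, resid_new
            train_mse = mse_new
            lam = max(lam * cfg.lambda_decrease, 1e-15)
            ever_accepted = True
            history.train_mse.append(train_mse)
            history.lambdas.append(lam)
            if len(ys_val):
                val_mse = float(np.mean((ys_val - _forward_scaled(
                    *_unpack(theta, n_hidden, n_features), xs_val)) ** 2))
                history.val_mse.append(val_mse)
                if val_mse < best_val:
                    best_val = val_mse
                    best_theta = theta.copy()
                    bad_val_steps = 0
                else:
                    bad_val_steps += 1
                    if bad_val_steps >= cfg.patience:
                        history.stop_reason = "validation patience"
                        break
            else:
                best_theta = theta.copy()
        else:
            lam *= cfg.lambda_increase
            if lam > cfg.lambda_max:
                history.stop_reason = "lambda overflow"
                break
    else:
        history.stop_reason = "max epochs"

    w_in, b_hidden, w_out, b_out = _unpack(best_theta, n_hidden, n_features)
    model = ANNModel(w_in=w_in, b_hidden=b_hidden, w_out=w_out, b_out=float(b_out),
                     input_scaling=in_scaler, target_scaling=t_scaler)
    return model, history


def estimate_trial(model: ANNModel, nctm_filtered: ThermalTrace,
                   condition: TrialCondition | None = None,
                   include_condition: bool | None = None) -> ThermalTrace:
    """Per-sample forward pass over a whole filtered trace, in degC."""
    if include_condition is None:
        include_condition = model.n_features > 1
    x = build_features(nctm_filtered, condition, include_condition=include_condition)
    est = forward(model, x)
    return ThermalTrace(values=est, channel="estimate",
                        condition=condition or nctm_filtered.condition,
                        rate=nctm_filtered.rate,
                        start_offset=nctm_filtered.start_offset)


class TemperatureANN:
    """Model object: contact-temperature estimation from through-foam readings.

    Parameters
    ----------
    features : ndarray (n_samples, n_features)
        Typically [filtered NCTM degC, thickness cm, density kg/m3].
    targets : ndarray (n_samples,)
        Contact (DCTM) temperature in degC.
    n_hidden : int
        Hidden-layer width.
    """

    def __init__(self, features: np.ndarray, targets: np.ndarray,
                 n_hidden: int = DEFAULT_N_HIDDEN):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.targets = np.asarray(targets, dtype=float).ravel()
        if len(self.features) != len(self.targets):
            raise ParameterError("features and targets length mismatch")
        self.n_hidden = n_hidden

    @classmethod
    def from_trials(cls, filtered_traces: list[ThermalTrace],
                    dctm_traces: list[ThermalTrace],
                    n_hidden: int = DEFAULT_N_HIDDEN,
                    include_condition: bool = True) -> "TemperatureANN":
        """Stack per-trial features/targets from paired filtered/contact traces."""
        feats = [build_features(f, include_condition=include_condition)
                 for f in filtered_traces]
        targs = [d.values for d in dctm_traces]
        return cls(np.vstack(feats), np.concatenate(targs), n_hidden=n_hidden)

    def fit(self, split_seed: int = 0, init_seed: int = 0,
            lm_config: LMConfig | None = None,
            split: DataSplit | None = None) -> "TemperatureANNResults":
        split = split or split_data(len(self.targets), seed=split_seed)
        model, history = train_lm(self.features, self.targets, split,
                                  n_hidden=self.n_hidden, lm_config=lm_config,
                                  seed=init_seed)
        return TemperatureANNResults(self, model, history, split)


class TemperatureANNResults:
    """Fitted-network results: weights, split-wise errors, diagnostics."""

    def __init__(self, model_spec: TemperatureANN, network: ANNModel,
                 history: TrainingHistory, split: DataSplit):
        self.model = model_spec
        self.network = network
        self.history = history
        self.split = split

    def predict(self, features: np.ndarray | None = None) -> np.ndarray:
        x = self.model.features if features is None else features
        return forward(self.network, x)

    def estimate_trial(self, nctm_filtered: ThermalTrace,
                       condition: TrialCondition | None = None) -> ThermalTrace:
        return estimate_trial(self.network, nctm_filtered, condition)

    def mse(self, which: str = "train") -> float:
        idx = getattr(self.split, f"{which}_idx")
        pred = forward(self.network, self.model.features[idx])
        return float(np.mean((self.model.targets[idx] - pred) ** 2))

    def summary(self) -> pd.DataFrame:
        """Split-wise RMSE/MAE table plus fit metadata, statsmodels-style."""
        rows = []
        for which in ("train", "val", "test"):
            idx = getattr(self.split, f"{which}_idx")
            pred = forward(self.network, self.model.features[idx])
            err = self.model.targets[idx] - pred
            rows.append({"set": which, "n": len(idx),
                         "rmse_C": float(np.sqrt(np.mean(err ** 2))),
                         "mae_C": float(np.mean(np.abs(err)))})
        df = pd.DataFrame(rows)
        df.attrs["n_hidden"] = self.network.n_hidden
        df.attrs["epochs"] = self.history.epochs
        df.attrs["stop_reason"] = self.history.stop_reason
        return df
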