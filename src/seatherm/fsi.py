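"""Fractal-scaling-index denoising of decomposed thermal traces.

Each EMD component (IMFs and residue) is scored with a fractal scaling
index (FSI) computed by first-order detrended fluctuation analysis (DFA-1):
the component is mean-removed and cumulatively summed, the profile is cut
into non-overlapping boxes, a straight line is removed per box, and the
index is the log-log slope of the fluctuation function versus box size.
White noise scores about 0.5, Brownian motion about 1.5, and a smooth
trend above 1 — so thresholding at 0.5 separates noise-dominated fast
components from signal-carrying slow ones.  Components scoring strictly
above the threshold are summed back into the denoised trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .emd import DEFAULT_MAX_IMFS, IMFDecomposition, decompose
from .traces import ParameterError, ThermalTrace

DEFAULT_THRESHOLD = 0.5
MIN_DFA_LENGTH = 64


class UndefinedFSIError(ValueError):
    """FSI is undefined for a zero-variance or too-short component."""


def dfa_box_sizes(n: int, min_size: int = 8, n_sizes: int = 20) -> np.ndarray:
    """Log-spaced integer box sizes from ``min_size`` to n//4 (>= 10 sizes)."""
    max_size = max(n // 4, min_size + 1)
    sizes = np.unique(np.round(np.logspace(
        np.log10(min_size), np.log10(max_size), max(n_sizes, 10))).astype(int))
    return sizes[(sizes >= 4) & (sizes <= n // 2)]


def compute_fsi(component: np.ndarray, box_sizes: np.ndarray | None = None) -> float:
    """DFA-1 scaling exponent of one component.

    Least-squares slope of log10 F(n) against log10 n, where F(n) is the
    RMS of linearly detrended, box-wise fluctuations of the cumulatively
    summed, mean-removed component.
    """
    x = np.asarray(component, dtype=float)
    if len(x) < MIN_DFA_LENGTH:
        raise UndefinedFSIError(f"component too short for DFA ({len(x)} < {MIN_DFA_LENGTH})")
    if np.ptp(x) == 0:
        raise UndefinedFSIError("zero-variance component has no scaling exponent")
    profile = np.cumsum(x - x.mean())
    n = len(profile)
    sizes = dfa_box_sizes(n) if box_sizes is None else np.asarray(box_sizes, dtype=int)
    log_n, log_f = [], []
    t_cache: dict[int, np.ndarray] = {}
    for s in sizes:
        n_boxes = n // s
        if n_boxes < 2:
            continue
        # Cover the profile from both ends so no tail is wasted.
        segs = np.vstack([profile[: n_boxes * s].reshape(n_boxes, s),
                          profile[n - n_boxes * s:].reshape(n_boxes, s)])
        t = t_cache.setdefault(s, np.arange(s, dtype=float))
        # Vectorised per-box linear detrend.
        tc = t - t.mean()
        denom = float(np.dot(tc, tc))
        seg_mean = segs.mean(axis=1, keepdims=True)
        slopes = (segs @ tc)[:, None] / denom
        resid = segs - seg_mean - slopes * tc
        f = np.sqrt(np.mean(resid ** 2))
        if f > 0:
            log_n.append(np.log10(s))
            log_f.append(np.log10(f))
    if len(log_n) < 3:
        raise UndefinedFSIError("too few valid box sizes for a slope fit")
    slope = np.polyfit(log_n, log_f, 1)[0]
    return float(slope)


def select_components(fsi_values, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean retain-mask: strictly greater than the threshold survives."""
    if not np.isfinite(threshold):
        if threshold == -np.inf:
            return np.ones(len(list(fsi_values)), dtype=bool)
        raise ParameterError("threshold must be finite or -inf")
    return np.asarray([v > threshold for v in fsi_values], dtype=bool)


def reconstruct(decomposition: IMFDecomposition, mask) -> np.ndarray:
    """Pointwise sum of the retained components."""
    return decomposition.reconstruct(mask)


@dataclass
class FSIReport:
    """Audit record of one denoising pass: per-component FSI and the verdict."""

    component_fsi: list[float]
    threshold: float
    retained_mask: list[bool]
    fit_ranges: list[int] = field(default_factory=list)

    @property
    def n_discarded(self) -> int:
        return int(np.sum(~np.asarray(self.retained_mask)))

    @property
    def n_retained(self) -> int:
        return int(np.sum(self.retained_mask))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "threshold": self.threshold,
            "components": [
                {"index": i, "fsi": None if not np.isfinite(f) else f,
                 "retained": bool(r)}
                for i, (f, r) in enumerate(zip(self.component_fsi, self.retained_mask))
            ],
            "fit_ranges": [int(s) for s in self.fit_ranges],
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def denoise(trace: ThermalTrace, threshold: float = DEFAULT_THRESHOLD,
            sd_tol: float | None = None, max_imfs: int = DEFAULT_MAX_IMFS,
            ) -> tuple[ThermalTrace, FSIReport]:
    """EMD-FSI filter: decompose, score, threshold, reconstruct.

    Components too short or degenerate for DFA are retained (fail-safe:
    signal is never silently deleted).  Returns the filtered trace
    (channel ``NCTM_filtered``) and an :class:`FSIReport` for audit.
    """
    if trace.channel not in ("NCTM_raw", "NCTM_noise_free"):
        raise ParameterError(
            f"denoise expects a raw NCTM trace, got channel {trace.channel!r}")
    decomposition = decompose(trace.values, sd_tol=sd_tol, max_imfs=max_imfs)
    fsi_values: list[float] = []
    mask: list[bool] = []
    for comp in decomposition.components:
        try:
            f = compute_fsi(comp)
            keep = f > threshold
        except UndefinedFSIError:
            f, keep = float("nan"), True
        fsi_values.append(f)
        mask.append(keep)
    filtered = decomposition.reconstruct(mask)
    report = FSIReport(component_fsi=fsi_values, threshold=threshold,
                       retained_mask=mask,
                       fit_ranges=list(dfa_box_sizes(decomposition.source_length)))
    out = ThermalTrace(values=filtered, channel="NCTM_filtered",
                       condition=trace.condition, rate=trace.rate,
                       start_offset=trace.start_offset)
    return out, report
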