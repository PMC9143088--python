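"""Empirical mode decomposition by iterative cubic-spline sifting.

EMD adaptively separates a 1-D signal into oscillatory intrinsic mode
functions (IMFs, fastest first) plus a slow residue.  Each sift subtracts
the mean of the upper and lower cubic-spline envelopes through the local
maxima and minima, iterating until the envelope mean is negligible —
judged by the envelope-amplitude ratio criterion (default) or a
Cauchy-style relative-change criterion (``sd_tol``).  The decomposition
is a telescoping subtraction, so the components sum back to the input to
floating-point precision.

Boundary handling mirrors the two extrema nearest each end about the
signal endpoints to suppress spline end-swings; splines use natural
(zero second derivative) boundary conditions at the extended knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .traces import ParameterError

DEFAULT_MAX_ITER = 100
DEFAULT_MAX_IMFS = 12
# Envelope-amplitude stopping thresholds (Rilling-style): sifting stops when
# |envelope mean| / envelope amplitude is below THETA1 on all but a fraction
# ALPHA of samples and below THETA2 everywhere.
DEFAULT_THETA1 = 0.05
DEFAULT_THETA2 = 0.5
DEFAULT_ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Signal too short or flat for the requested operation."""


class ResidueReached(Exception):
    """Raised internally when too few extrema remain to build envelopes."""


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residue whose pointwise sum reproduces the input."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int]

    @property
    def source_length(self) -> int:
        return len(self.residue)

    @property
    def n_components(self) -> int:
        """IMF count plus one for the residue."""
        return len(self.imfs) + 1

    @property
    def components(self) -> list[np.ndarray]:
        return [*self.imfs, self.residue]

    def reconstruct(self, mask=None) -> np.ndarray:
        """Sum the components selected by ``mask`` (all, by default)."""
        comps = self.components
        if mask is None:
            mask = [True] * len(comps)
        if len(mask) != len(comps):
            raise ParameterError(
                f"mask length {len(mask)} != component count {len(comps)}"
            )
        out = np.zeros(self.source_length)
        for keep, c in zip(mask, comps):
            if keep:
                out += c
        return out


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima by three-point comparison.

    Plateaus of equal values count once, at the plateau midpoint (ties
    broken toward the lower index).  Endpoints are never extrema.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise DegenerateInputError("need a 1-D signal of length >= 3")

    # Collapse plateaus: compare each run of equal values with neighbours.
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))           # run start indices
    ends = np.concatenate((change, [len(x) - 1]))        # run end indices
    vals = x[starts]
    maxima, minima = [], []
    for k in range(1, len(starts) - 1):
        left, right = vals[k - 1], vals[k + 1]
        mid = (starts[k] + ends[k]) // 2
        if vals[k] > left and vals[k] > right:
            maxima.append(mid)
        elif vals[k] < left and vals[k] < right:
            minima.append(mid)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirrored_knots(idx: np.ndarray, values: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by mirroring the two nearest each end about the endpoints."""
    pos = idx.astype(float)
    val = values[idx]
    left_pos = -pos[:2][::-1]
    left_val = val[:2][::-1]
    right_pos = 2 * (n - 1) - pos[-2:][::-1]
    right_val = val[-2:][::-1]
    xs = np.concatenate([left_pos, pos, right_pos])
    ys = np.concatenate([left_val, val, right_val])
    keep = np.concatenate([[True], np.diff(xs) > 0])  # guard duplicate knots
    return xs[keep], ys[keep]


def envelopes(signal: np.ndarray, maxima: np.ndarray, minima: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower natural cubic splines through the (mirrored) extrema."""
    x = np.asarray(signal, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise ResidueReached("fewer than two maxima or minima")
    n = len(x)
    t = np.arange(n)
    ux, uy = _mirrored_knots(np.sort(maxima), x, n)
    lx, ly = _mirrored_knots(np.sort(minima), x, n)
    upper = CubicSpline(ux, uy, bc_type="natural")(t)
    lower = CubicSpline(lx, ly, bc_type="natural")(t)
    return upper, lower


def mean_envelope(signal: np.ndarray, maxima: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """(upper + lower)/2 from natural cubic splines through the extrema."""
    upper, lower = envelopes(signal, maxima, minima)
    return (upper + lower) / 2.0


def _is_imf_like(h: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    maxima, minima = find_extrema(h)
    n_ext = len(maxima) + len(minima)
    n_zc = int(np.count_nonzero(np.diff(np.signbit(h))))
    return abs(n_ext - n_zc) <= 1


def sift(signal: np.ndarray, sd_tol: float | None = None,
         max_iter: int = DEFAULT_MAX_ITER,
         theta1: float = DEFAULT_THETA1, theta2: float = DEFAULT_THETA2,
         alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate by repeated envelope-mean subtraction.

    Iterates ``h <- h - mean_envelope(h)`` until the averaged envelope is
    negligible.  By default "negligible" is the envelope-amplitude
    criterion: |mean envelope| / local envelope amplitude stays below
    ``theta1`` on all but a fraction ``alpha`` of samples and below
    ``theta2`` everywhere — the rule that preserves the dyadic
    filter-bank behaviour on broadband signals.  Passing ``sd_tol``
    switches to the simpler Cauchy relative-change criterion
    ``sum((h_prev - h)**2) / sum(h_prev**2) < sd_tol`` instead.
    Non-convergence at ``max_iter`` is reported as a warning, never
    raised.
    """
    if sd_tol is not None and sd_tol <= 0:
        raise ParameterError(f"sd_tol must be positive, got {sd_tol}")
    h = np.asarray(signal, dtype=float).copy()
    iterations = 0
    for _ in range(max_iter):
        maxima, minima = find_extrema(h)
        try:
            upper, lower = envelopes(h, maxima, minima)
        except ResidueReached:
            break
        env = (upper + lower) / 2.0
        iterations += 1
        if sd_tol is not None:
            denom = float(np.sum(h ** 2))
            sd = float(np.sum(env ** 2)) / denom if denom > 0 else 0.0
            converged = sd < sd_tol
        else:
            amplitude = np.maximum((upper - lower) / 2.0, 1e-12)
            ratio = np.abs(env) / amplitude
            converged = (float(np.mean(ratio > theta1)) < alpha
                         and bool(np.all(ratio < theta2)))
        h = h - env
        if converged:
            break
    else:
        if not _is_imf_like(h):
            warnings.warn(
                "sifting hit max_iter without reaching IMF shape "
                "(|#extrema - #zero-crossings| > 1)", stacklevel=2,
            )
    return h, iterations


def is_residue(signal: np.ndarray) -> bool:
    """True when a remainder is monotone or has fewer than 3 local extrema."""
    x = np.asarray(signal, dtype=float)
    d = np.diff(x)
    if np.all(d >= 0) or np.all(d <= 0):
        return True
    try:
        maxima, minima = find_extrema(x)
    except DegenerateInputError:
        return True
    return len(maxima) + len(minima) < 3


def decompose(signal: np.ndarray, sd_tol: float | None = None,
              max_imfs: int = DEFAULT_MAX_IMFS,
              max_iter: int = DEFAULT_MAX_ITER) -> IMFDecomposition:
    """Full EMD: peel IMFs off the running remainder until it is a residue."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise DegenerateInputError("need a 1-D signal of length >= 8")
    remainder = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    while len(imfs) < max_imfs and not is_residue(remainder):
        imf, n_it = sift(remainder, sd_tol=sd_tol, max_iter=max_iter)
        if n_it == 0:
            break  # envelopes unavailable; remainder is the residue
        imfs.append(imf)
        counts.append(n_it)
        remainder = remainder - imf
    return IMFDecomposition(imfs=imfs, residue=remainder, sift_counts=counts)
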