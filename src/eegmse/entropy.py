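"""Multiscale sample entropy (MSE).

Sample entropy of a series ``Y`` is the negative log of the conditional
probability that two templates matching for ``m`` points (Chebyshev
distance strictly below the tolerance ``r``) also match for ``m + 1``
points.  The multiscale variant first coarse-grains the raw series at a
scale factor ``tau``; here the default coarse-graining is a sliding
(moving-average) window of length ``tau``, which preserves sequence
length up to ``tau - 1`` samples — unlike the classical non-overlapping
block average, which is also provided.

Counting conventions, spelled out because variants abound:

* templates are ``Y_i = (y_i, ..., y_{i+m-1})`` for ``i = 1 .. N-m+1``;
* self-matches are excluded (``j != i``) and matching is strict
  (``d < r``);
* each template's match count is divided by ``N - m`` and the per-scale
  similarity ``B^m`` is the average over all ``N - m + 1`` templates
  (for dimension ``m + 1``: division by ``N - m - 1``, average over
  ``N - m`` templates);
* ``MSE = -ln(B^{m+1} / B^m)``, with ``r = r_factor * std`` computed on
  the *original* (pre-coarse-graining) series using the sample standard
  deviation, so the tolerance is fixed across scales.

A segment whose match counts vanish (e.g. a constant segment, where
``r = 0.2 * std = 0``) is *degenerate*: these functions return ``nan``
rather than raising, and the caller decides how to impute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EntropyParams",
    "coarse_grain",
    "sample_entropy",
    "mse",
    "mse_from_params",
]

_COARSE_MODES = ("moving_average", "nonoverlapping")


@dataclass(frozen=True)
class EntropyParams:
    """MSE parameters.

    Attributes
    ----------
    m
        Embedding (template) dimension; 2 is the standard choice for EEG.
    r_factor
        Tolerance as a multiple of the series' sample standard
        deviation; 0.2 is the standard choice.
    tau
        Scale factor (>= 1).  The pipeline default is 2, the scale at
        which the hybrid classifier performs best.
    coarse_grain_mode
        ``"moving_average"`` (sliding window, default) or
        ``"nonoverlapping"`` (classical block average).
    """

    m: int = 2
    r_factor: float = 0.2
    tau: int = 2
    coarse_grain_mode: str = "moving_average"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValueError(f"r_factor must be > 0, got {self.r_factor}")
        if self.tau < 1 or int(self.tau) != self.tau:
            raise ValueError(f"tau must be a positive integer, got {self.tau}")
        if self.coarse_grain_mode not in _COARSE_MODES:
            raise ValueError(
                f"coarse_grain_mode must be one of {_COARSE_MODES}, "
                f"got {self.coarse_grain_mode!r}"
            )


def coarse_grain(
    x: np.ndarray, tau: int, mode: str = "moving_average"
) -> np.ndarray:
    """Coarse-grain a series at scale ``tau``.

    In ``"moving_average"`` mode element ``j`` of the output is the mean
    of ``x[j : j + tau]`` and the output has length ``N - tau + 1``; at
    ``tau = 1`` the raw series is returned unchanged.  In
    ``"nonoverlapping"`` mode the output holds ``floor(N / tau)``
    non-overlapping block means.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    tau = int(tau)
    if tau > n:
        raise ValueError(f"scale factor tau={tau} exceeds series length {n}")
    if mode not in _COARSE_MODES:
        raise ValueError(
            f"mode must be one of {_COARSE_MODES}, got {mode!r}"
        )
    if tau == 1:
        return x.copy()
    if mode == "moving_average":
        return sliding_window_view(x, tau).mean(axis=1)
    nblocks = n // tau
    return x[: nblocks * tau].reshape(nblocks, tau).mean(axis=1)


def _counts_small(y: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-template match counts for dimensions m and m+1.

    Builds the full |y_i - y_j| matrix and folds it with shifted
    maxima, so the Chebyshev template distances for successive
    dimensions cost one elementwise maximum each.  Intended for short
    segments (memory is O(N^2)).
    """
    d = np.abs(y[:, None] - y[None, :])
    cur = d
    for k in range(1, m):
        cur = np.maximum(cur[:-1, :-1], d[k:, k:])
    match_m = cur < r
    np.fill_diagonal(match_m, False)
    counts_m = match_m.sum(axis=1)
    cur = np.maximum(cur[:-1, :-1], d[m:, m:])
    match_m1 = cur < r
    np.fill_diagonal(match_m1, False)
    return counts_m, match_m1.sum(axis=1)


def _counts_large(
    y: np.ndarray, m: int, r: float, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Row-chunked variant of :func:`_counts_small` for long series.

    Identical counting (float64, strict inequality); pairwise distance
    blocks are bounded to ``chunk`` template rows at a time.
    """
    n = y.size
    nt_m, nt_m1 = n - m + 1, n - m
    counts_m = np.empty(nt_m, dtype=np.int64)
    counts_m1 = np.empty(nt_m1, dtype=np.int64)
    for s in range(0, nt_m, chunk):
        e = min(s + chunk, nt_m)
        cur = np.abs(y[s:e, None] - y[None, :nt_m])
        for k in range(1, m):
            np.maximum(
                cur, np.abs(y[s + k : e + k, None] - y[None, k : k + nt_m]),
                out=cur,
            )
        # subtract the self-match (distance 0 < r whenever r > 0)
        counts_m[s:e] = (cur < r).sum(axis=1) - 1
        e1 = min(e, nt_m1)
        if s < e1:
            cur1 = np.maximum(
                cur[: e1 - s, :nt_m1],
                np.abs(y[s + m : e1 + m, None] - y[None, m : m + nt_m1]),
            )
            counts_m1[s:e1] = (cur1 < r).sum(axis=1) - 1
    return counts_m, counts_m1


def sample_entropy(y: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of a (possibly coarse-grained) series.

    Parameters
    ----------
    y
        1-D series of length ``N >= m + 2``.
    m
        Template dimension.
    r
        Absolute similarity tolerance (> 0); required.

    Returns
    -------
    float
        ``-ln(B^{m+1} / B^m)``; ``nan`` when either match count is zero
        or the tolerance is not positive (degenerate segment).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < m + 2:
        raise ValueError(
            f"series length {n} too short for m={m} (need at least {m + 2})"
        )
    if r is None:
        raise ValueError("an absolute tolerance r must be given")
    if not (r > 0):
        return math.nan

    if n <= 2000:
        counts_m, counts_m1 = _counts_small(y, m, r)
    else:
        counts_m, counts_m1 = _counts_large(y, m, r)
    if counts_m.sum() == 0 or counts_m1.sum() == 0:
        return math.nan
    b_m = (counts_m / (n - m)).mean()
    b_m1 = (counts_m1 / (n - m - 1)).mean()
    return float(-math.log(b_m1 / b_m))


def mse(
    x: np.ndarray,
    m: int = 2,
    r_factor: float = 0.2,
    tau: int = 1,
    coarse_grain_mode: str = "moving_average",
) -> float:
    """Multiscale sample entropy of a raw series at scale ``tau``.

    The tolerance is ``r_factor`` times the sample standard deviation of
    the *raw* series; at ``tau = 1`` this is plain sample entropy.
    Returns ``nan`` for degenerate segments (see module docstring).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0.0:
        # constant series: std (hence r) is zero up to rounding noise
        return math.nan
    r = r_factor * float(np.std(x, ddof=1))
    if not (r > 0):
        return math.nan
    y = coarse_grain(x, tau, mode=coarse_grain_mode)
    if y.size < m + 2:
        raise ValueError(
            f"coarse-grained length {y.size} too short for m={m}"
        )
    return sample_entropy(y, m=m, r=r)


def mse_from_params(x: np.ndarray, params: EntropyParams) -> float:
    """Convenience overload of :func:`mse` taking :class:`EntropyParams`."""
    return mse(
        x,
        m=params.m,
        r_factor=params.r_factor,
        tau=params.tau,
        coarse_grain_mode=params.coarse_grain_mode,
    )
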