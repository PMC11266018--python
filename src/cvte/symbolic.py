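"""Four-level symbolic encoding and raw-value histogram binning.

Symbolization maps every sample of a real series to one of four codes using
thresholds placed at the mean of the positive samples (mu_p) and at
(1 +/- beta)·mu_p; negative samples use the mirrored rule around the mean of
the negative samples (mu_n).  The thresholds scale with the data, which makes
the encoding — and every estimator built on it — invariant to multiplication
of a series by a positive constant, and is what buys the noise robustness of
symbolic over histogram transfer entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SymbolSeries", "symbolize", "bin_raw", "N_SYMBOLS"]

#: size of the symbol alphabet
N_SYMBOLS = 4

#: default threshold control parameter
DEFAULT_BETA = 0.05


@dataclass(frozen=True)
class SymbolSeries:
    """Integer codes in {0,1,2,3} plus the thresholds that produced them."""

    codes: np.ndarray
    beta: float
    mu_p: float | None
    mu_n: float | None

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.size and not ((codes >= 0) & (codes < N_SYMBOLS)).all():
            raise ValueError("symbol codes must lie in {0,1,2,3}")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return self.codes.size


def symbolize(x, beta: float = DEFAULT_BETA) -> SymbolSeries:
    """Encode a real series into the four-level alphabet.

    Non-negative samples (zeros included) are coded against mu_p, the mean
    of the strictly positive samples:

        0 : mu_p        < x <= (1+beta)·mu_p
        1 : (1+beta)·mu_p < x
        2 : (1-beta)·mu_p < x <= mu_p
        3 : 0 <= x <= (1-beta)·mu_p

    Negative samples are coded against mu_n, the mean of the negative
    samples (mu_n < 0, so (1+beta)·mu_n < mu_n < (1-beta)·mu_n < 0):

        0 : (1+beta)·mu_n <= x < mu_n
        1 :                 x < (1+beta)·mu_n
        2 : mu_n          <= x < (1-beta)·mu_n
        3 : (1-beta)·mu_n <= x < 0

    A series with no positive samples but some zeros maps the zeros to
    code 3 with a warning (mu_p is undefined; zero sits in the innermost
    non-negative band by convention).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN/Inf")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")

    codes = np.empty(x.size, dtype=np.int64)

    nonneg = x >= 0.0
    pos = x > 0.0
    if np.any(nonneg):
        if np.any(pos):
            mu_p = float(x[pos].mean())
        else:
            mu_p = None
            warnings.warn(
                "no positive samples: mu_p undefined, zeros coded 3",
                RuntimeWarning,
                stacklevel=2,
            )
        xs = x[nonneg]
        if mu_p is None:
            codes[nonneg] = 3
        else:
            hi, lo = (1.0 + beta) * mu_p, (1.0 - beta) * mu_p
            c = np.full(xs.size, 3, dtype=np.int64)     # 0 <= x <= (1-b)mu_p
            c[(lo < xs) & (xs <= mu_p)] = 2
            c[(mu_p < xs) & (xs <= hi)] = 0
            c[xs > hi] = 1
            codes[nonneg] = c
    else:
        mu_p = None

    neg = ~nonneg
    if np.any(neg):
        mu_n = float(x[neg].mean())
        xs = x[neg]
        lo, hi = (1.0 + beta) * mu_n, (1.0 - beta) * mu_n  # lo < mu_n < hi < 0
        c = np.full(xs.size, 3, dtype=np.int64)            # (1-b)mu_n <= x < 0
        c[(mu_n <= xs) & (xs < hi)] = 2
        c[(lo <= xs) & (xs < mu_n)] = 0
        c[xs < lo] = 1
        codes[neg] = c
    else:
        mu_n = None

    return SymbolSeries(codes, beta, mu_p, mu_n)


def bin_raw(x, y_context, n_bins: int | None = None) -> np.ndarray:
    """Histogram-bin a raw series for the non-symbolic (HTE) estimator.

    The bin width is (max - min)/T of the *joint* range of ``x`` and its
    context series, with T the series length (override the bin count with
    ``n_bins``); bins are anchored at the joint minimum and the last bin is
    closed, so indices run 0..n_bins-1.  Using the shared range means a
    pair of series is binned on one common grid.
    """
    x = np.asarray(x, dtype=float)
    ctx = np.asarray(y_context, dtype=float)
    if x.ndim != 1 or ctx.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 samples to define a bin width")
    if n_bins is None:
        n_bins = x.size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    joint_min = min(x.min(), ctx.min())
    joint_max = max(x.max(), ctx.max())
    span = joint_max - joint_min
    if span == 0.0:
        return np.zeros(x.size, dtype=np.int64)
    width = span / n_bins
    idx = np.floor((x - joint_min) / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)
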