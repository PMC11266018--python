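"""Core signal representation and data-driven time-delay selection.

A complex-valued signal z = a·exp(jθ) is carried around as its two real
component series (magnitude a, phase θ).  Phase is any real-valued series
standing in for the argument; no wrapping is assumed or enforced, and the
simulated benchmark signals deliberately use unbounded real series for both
channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComplexSeries",
    "DelayEstimate",
    "decompose",
    "select_delay",
    "select_pair_delay",
    "read_series_table",
    "write_series_table",
]


@dataclass(frozen=True)
class ComplexSeries:
    """Paired magnitude/phase vectors of one complex-valued signal.

    Both vectors must be finite, one-dimensional and of identical length
    T >= 3.  Magnitude is non-negative when produced by :func:`decompose`;
    signed series are accepted so that benchmark generators whose
    "magnitude" channel is a signed AR process can be represented exactly.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        mag = np.asarray(self.magnitude, dtype=float)
        ph = np.asarray(self.phase, dtype=float)
        if mag.ndim != 1 or ph.ndim != 1:
            raise ValueError("magnitude and phase must be 1-D vectors")
        if mag.shape != ph.shape:
            raise ValueError(
                f"magnitude/phase length mismatch: {mag.size} vs {ph.size}"
            )
        if mag.size < 3:
            raise ValueError("a ComplexSeries needs at least 3 time points")
        if not (np.all(np.isfinite(mag)) and np.all(np.isfinite(ph))):
            raise ValueError("magnitude and phase must be finite")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "phase", ph)

    @property
    def T(self) -> int:
        """Number of time points."""
        return self.magnitude.size

    def to_complex(self) -> np.ndarray:
        """Reassemble the complex samples a·exp(jθ)."""
        return self.magnitude * np.exp(1j * self.phase)

    def permuted(self, order: np.ndarray) -> "ComplexSeries":
        """Return a copy with time indices re-ordered (same order for both
        channels, so the per-sample magnitude/phase pairing is preserved)."""
        order = np.asarray(order)
        return ComplexSeries(self.magnitude[order], self.phase[order], self.name)


@dataclass(frozen=True)
class DelayEstimate:
    """Outcome of the lagged Pearson-correlation scan."""

    tau: int
    correlation: float
    scanned_range: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.scanned_range
        if not (1 <= lo <= self.tau <= hi):
            raise ValueError("tau must lie inside the scanned lag range")


def decompose(real_part, imag_part) -> ComplexSeries:
    """Split a complex signal given by real/imaginary parts into
    magnitude (elementwise modulus) and phase (argument in (-pi, pi]).

    Samples at the origin get phase 0 (with a warning): the argument is
    undefined there and zero is the conventional continuous completion.
    """
    re = np.asarray(real_part, dtype=float)
    im = np.asarray(imag_part, dtype=float)
    if re.shape != im.shape:
        raise ValueError(f"length mismatch: {re.shape} vs {im.shape}")
    if not (np.all(np.isfinite(re)) and np.all(np.isfinite(im))):
        raise ValueError("real/imaginary parts must be finite")
    mag = np.hypot(re, im)
    ph = np.arctan2(im, re)
    zero = mag == 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-modulus sample(s); phase set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        ph = np.where(zero, 0.0, ph)
    return ComplexSeries(mag, ph)


def _lagged_corr(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Pearson correlation of x(t) with y(t+lag); nan for constant slices."""
    xs = x[: x.size - lag]
    ys = y[lag:]
    sx = xs.std()
    sy = ys.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))


def select_delay(x, y, max_lag: int = 10, mode: str = "abs") -> DelayEstimate:
    """Pick the coupling delay from source ``x`` to target ``y``.

    Scans lags 1..max_lag and returns the lag whose Pearson correlation
    between x(1..T-l) and y(1+l..T) is maximal.  ``mode="abs"`` (default)
    maximizes |r| so that negative couplings are found; ``mode="signed"``
    maximizes the raw coefficient.  Ties break toward the smallest lag.
    Positive tau means the source leads the target by tau samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if x.size <= max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    if mode not in ("abs", "signed"):
        raise ValueError(f"unknown mode {mode!r}")

    corrs = np.array([_lagged_corr(x, y, l) for l in range(1, max_lag + 1)])
    if np.all(np.isnan(corrs)):
        warnings.warn(
            "constant input: lagged correlation undefined; returning tau=1",
            RuntimeWarning,
            stacklevel=2,
        )
        return DelayEstimate(1, 0.0, (1, max_lag))
    score = np.abs(corrs) if mode == "abs" else corrs
    score = np.where(np.isnan(score), -np.inf, score)
    best = int(np.argmax(score))  # argmax takes the first maximum: smallest lag
    return DelayEstimate(best + 1, float(corrs[best]), (1, max_lag))


def select_pair_delay(x, y, max_lag: int = 10, mode: str = "abs") -> DelayEstimate:
    """Single coupling delay for an unordered signal pair.

    Scans both orientations (x leading y and y leading x) and returns the
    lag of the globally maximal correlation, so the estimate is symmetric
    in its arguments — the delay of the dominant coupling, whichever way it
    points.  Used when one delay must serve both causal directions.
    """
    fwd = select_delay(x, y, max_lag, mode)
    rev = select_delay(y, x, max_lag, mode)
    if mode == "abs":
        better = fwd if abs(fwd.correlation) >= abs(rev.correlation) else rev
    else:
        better = fwd if fwd.correlation >= rev.correlation else rev
    return better


# ---------------------------------------------------------------------------
# delimited-text I/O: one column per component series, signals paired by the
# `<name>_mag` / `<name>_phase` suffix convention
# ---------------------------------------------------------------------------

MAG_SUFFIX = "_mag"
PHASE_SUFFIX = "_phase"


def read_series_table(path, sep: str = ",") -> dict[str, ComplexSeries]:
    """Read a delimited table of paired magnitude/phase columns.

    Columns named ``<name>_mag`` and ``<name>_phase`` are paired into one
    :class:`ComplexSeries` per signal name.  Raises on unpaired columns.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise ValueError(f"empty time-series table: {path}")
    mags = {c[: -len(MAG_SUFFIX)]: c for c in df.columns if c.endswith(MAG_SUFFIX)}
    phases = {
        c[: -len(PHASE_SUFFIX)]: c for c in df.columns if c.endswith(PHASE_SUFFIX)
    }
    if set(mags) != set(phases):
        odd = set(mags).symmetric_difference(phases)
        raise ValueError(f"unpaired magnitude/phase column(s) for: {sorted(odd)}")
    if not mags:
        raise ValueError("no *_mag/*_phase column pairs found")
    return {
        name: ComplexSeries(
            df[mags[name]].to_numpy(float),
            df[phases[name]].to_numpy(float),
            name=name,
        )
        for name in sorted(mags)
    }


def write_series_table(series: dict[str, ComplexSeries], path, sep: str = ",",
                       header_lines: list[str] | None = None) -> None:
    """Write signals as paired ``_mag``/``_phase`` columns (inverse of
    :func:`read_series_table`).  Optional ``header_lines`` are emitted as
    ``#``-prefixed comments before the table."""
    cols = {}
    for name, s in series.items():
        cols[f"{name}{MAG_SUFFIX}"] = s.magnitude
        cols[f"{name}{PHASE_SUFFIX}"] = s.phase
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)
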