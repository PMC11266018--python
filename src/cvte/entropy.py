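"""Plug-in transfer entropy, partial transfer entropy, and the
complex-valued estimators built from them.

All estimators are plug-in (maximum-likelihood) functionals of an empirical
joint PMF over discretized series.  Symbolic estimators count exact
categorical frequencies over the four-letter alphabet; the histogram (HTE)
estimator counts over data-driven equal-width bins.  With a single
conditioning lag tau, tuples are aligned as (v_t, v_{t-tau}, ...) for
t = tau+1..T, giving T-tau counted tuples.

Transfer entropy from source y to target x at lag tau is the conditional
mutual information of the empirical distribution,

    TE = I(x_t ; y_{t-tau} | x_{t-tau})
       = H(x_t, x_{t-tau}) + H(y_{t-tau}, x_{t-tau})
         - H(x_{t-tau}) - H(x_t, x_{t-tau}, y_{t-tau}),

and partial transfer entropy conditions additionally on a third series'
past.  Both are non-negative up to floating-point rounding.  Entropies are
computed in nats internally; results are reported in bits by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signals import ComplexSeries, select_delay
from .symbolic import DEFAULT_BETA, N_SYMBOLS, bin_raw, symbolize

__all__ = [
    "TEConfig",
    "JointPMF",
    "joint_pmf",
    "transfer_entropy",
    "partial_transfer_entropy",
    "cte",
    "scte",
    "cte_direct_magphase",
    "ste",
    "hte",
    "cte_components",
    "ESTIMATORS",
]

_LN2 = float(np.log(2.0))


def _to_unit(nats: float, unit: str) -> float:
    if unit == "nats":
        return nats
    if unit == "bits":
        return nats / _LN2
    raise ValueError(f"unknown unit {unit!r} (use 'bits' or 'nats')")


@dataclass(frozen=True)
class TEConfig:
    """Estimator knobs shared across the pipeline.

    tau
        Coupling lag (time points) for the magnitude terms; ``None`` selects
        it by the lagged-correlation scan on the magnitude series.
    tau_phase
        Per-term override: coupling lag for the phase terms.  ``None``
        (default) reuses the magnitude delay for all four terms.
    beta
        Symbolization control parameter (threshold half-width as a fraction
        of the positive/negative mean).
    max_lag, delay_mode
        Passed to :func:`cvte.signals.select_delay` when tau is automatic.
    unit
        'bits' (default) or 'nats' for reported entropy values.
    literal_eq
        Use the printed conditional-probability weighting for the partial
        terms instead of the standard joint-probability weighting (kept for
        comparison; see docs/methods.md).
    hte_bins
        Override for the histogram estimator's bin count (default: one bin
        per time point, i.e. width = joint range / T).
    """

    tau: int | None = None
    tau_phase: int | None = None
    beta: float = DEFAULT_BETA
    max_lag: int = 10
    delay_mode: str = "abs"
    unit: str = "bits"
    literal_eq: bool = False
    hte_bins: int | None = None

    def __post_init__(self):
        for t in (self.tau, self.tau_phase):
            if t is not None and t < 1:
                raise ValueError("delays must be >= 1")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        _to_unit(0.0, self.unit)  # validate

    def with_tau(self, tau: int, tau_phase: int | None = None) -> "TEConfig":
        return replace(self, tau=tau, tau_phase=tau_phase)


# ---------------------------------------------------------------------------
# empirical joint PMF
# ---------------------------------------------------------------------------


class JointPMF:
    """Empirical joint PMF of aligned discrete vectors.

    ``counts[i, j, ...]`` is the number of positions whose tuple equals
    (i, j, ...); ``total`` is the number of aligned tuples, so probabilities
    sum to one.  Marginalizing over any axis yields the PMF of the remaining
    variables, which is exactly how the conditional probabilities in the
    entropy sums are formed.
    """

    def __init__(self, counts: np.ndarray, total: int, dims: list[str]):
        counts = np.asarray(counts)
        if counts.ndim != len(dims):
            raise ValueError("counts rank must match number of dims")
        if np.any(counts < 0) or counts.sum() != total:
            raise ValueError("counts must be non-negative and sum to total")
        self.counts = counts
        self.total = int(total)
        self.dims = list(dims)

    @classmethod
    def from_vectors(cls, variables, dims=None, cardinalities=None) -> "JointPMF":
        arrays = [np.asarray(v, dtype=np.int64) for v in variables]
        if not arrays:
            raise ValueError("need at least one variable")
        n = arrays[0].size
        if n < 1 or any(a.size != n for a in arrays):
            raise ValueError("variables must share a common length >= 1")
        if any(a.min() < 0 for a in arrays):
            raise ValueError("discrete codes must be non-negative")
        if cardinalities is None:
            cardinalities = [int(a.max()) + 1 for a in arrays]
        shape = tuple(cardinalities)
        counts = np.zeros(shape, dtype=np.int64)
        np.add.at(counts, tuple(arrays), 1)
        if dims is None:
            dims = [f"v{i}" for i in range(len(arrays))]
        return cls(counts, n, dims)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total

    def marginal(self, keep: list[str]) -> "JointPMF":
        """Marginalize onto the named variables (order preserved)."""
        drop = tuple(i for i, d in enumerate(self.dims) if d not in keep)
        counts = self.counts.sum(axis=drop) if drop else self.counts
        return JointPMF(counts, self.total, [d for d in self.dims if d in keep])

    def entropy(self, unit: str = "nats") -> float:
        return _to_unit(_entropy_from_counts(self.counts, self.total), unit)


def joint_pmf(variables, dims=None) -> JointPMF:
    """Empirical joint PMF of aligned discrete vectors (see :class:`JointPMF`)."""
    return JointPMF.from_vectors(variables, dims=dims)


# ---------------------------------------------------------------------------
# entropy primitives on integer-coded arrays
# ---------------------------------------------------------------------------


def _entropy_from_counts(counts: np.ndarray, total: int) -> float:
    """Shannon entropy (nats) of counts/total; empty cells contribute 0."""
    c = counts[counts > 0]
    if c.size == 0:
        return 0.0
    p = c / float(total)
    return float(-(p * np.log(p)).sum())


def _h_codes(codes: np.ndarray) -> float:
    """Entropy (nats) of an integer-coded sample via sort-and-count."""
    _, cnt = np.unique(codes, return_counts=True)
    return _entropy_from_counts(cnt, codes.size)


def _h_counts_axes(counts: np.ndarray, total: int, axes) -> float:
    """Entropy (nats) of the marginal obtained by summing out ``axes``."""
    return _entropy_from_counts(counts.sum(axis=axes) if axes else counts,
                                total)


def _cmi_sym(x, y, z_cols) -> float:
    """Fast path of :func:`_cmi` for the four-letter alphabet: one bincount
    over packed base-4 codes, marginals by axis sums.  Supports one or two
    conditioning columns."""
    n = x.size
    code = x
    for col in (*z_cols, y):
        code = (code << 2) | col
    d = 2 + len(z_cols)
    counts = np.bincount(code, minlength=N_SYMBOLS**d).reshape((N_SYMBOLS,) * d)
    y_ax, x_ax = d - 1, 0
    return (
        _h_counts_axes(counts, n, (y_ax,))            # H(x, z)
        + _h_counts_axes(counts, n, (x_ax,))          # H(y, z)
        - _h_counts_axes(counts, n, (x_ax, y_ax))     # H(z)
        - _h_counts_axes(counts, n, None)             # H(x, y, z)
    )


def _cmi(x: np.ndarray, y: np.ndarray, z_cols: list[np.ndarray]) -> float:
    """Plug-in conditional mutual information I(x; y | z) in nats.

    Arrays are aligned integer codes.  The conditioning tuple z may span
    several columns.  Uses the four-entropy identity; codes are packed into
    a single integer per tuple so each entropy is one sort-and-count.
    """
    n = x.size
    kx = int(x.max()) + 1 if n else 1
    ky = int(y.max()) + 1 if n else 1
    zc = np.zeros(n, dtype=np.int64)
    for col in z_cols:
        zc = zc * (int(col.max()) + 1) + col
    xz = zc * kx + x
    yz = zc * ky + y
    xyz = xz * ky + y
    return _h_codes(xz) + _h_codes(yz) - _h_codes(zc) - _h_codes(xyz)


def _te_nats(source: np.ndarray, target: np.ndarray, tau: int,
             sym: bool = False) -> float:
    x = target[tau:]
    xp = target[:-tau]
    yp = source[:-tau]
    return _cmi_sym(x, yp, (xp,)) if sym else _cmi(x, yp, [xp])


def _pte_nats(source, target, conditioner, tau: int, sym: bool = False) -> float:
    x = target[tau:]
    yp = source[:-tau]
    z = (target[:-tau], conditioner[:-tau])
    return _cmi_sym(x, yp, z) if sym else _cmi(x, yp, list(z))


def _pte_literal_nats(source, target, conditioner, tau: int) -> float:
    """Partial term with the printed conditional-probability weighting:
    -sum p(x|z) log p(x|z) + sum p(x|y,z) log p(x|y,z), the sums running
    over occupied cells.  Not a conditional entropy difference and not
    sign-constrained; retained for comparison only."""
    x = target[tau:]
    yp = source[:-tau]
    z1 = target[:-tau]
    z2 = conditioner[:-tau]

    def cond_sum(cols_z, cols_xz):
        zc = np.zeros(x.size, dtype=np.int64)
        for col in cols_z:
            zc = zc * (int(col.max()) + 1) + col
        xzc = zc
        for col in cols_xz:
            xzc = xzc * (int(col.max()) + 1) + col
        z_vals, z_inv, z_cnt = np.unique(zc, return_inverse=True,
                                         return_counts=True)
        xz_vals, xz_idx, xz_cnt = np.unique(xzc, return_index=True,
                                            return_counts=True)
        # p(x|z) per occupied (x, z) cell
        pc = xz_cnt / z_cnt[z_inv[xz_idx]]
        return float((pc * np.log(pc)).sum())

    term1 = -cond_sum([z1, z2], [x])
    term2 = cond_sum([yp, z1, z2], [x])
    return term1 + term2


def _check_discrete_pair(source, target, tau):
    source = np.asarray(source, dtype=np.int64)
    target = np.asarray(target, dtype=np.int64)
    if source.shape != target.shape or source.ndim != 1:
        raise ValueError("source and target must be 1-D vectors of equal length")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if source.size <= tau + 2:
        raise ValueError("series too short for the requested tau")
    return source, target


def transfer_entropy(source, target, tau: int, unit: str = "bits") -> float:
    """Plug-in transfer entropy from ``source`` to ``target`` (discrete
    codes) at lag ``tau``.  Zero-probability cells contribute nothing; a
    constant target gives exactly 0."""
    source, target = _check_discrete_pair(source, target, tau)
    return _to_unit(_te_nats(source, target, tau), unit)


def partial_transfer_entropy(source, target, conditioner, tau: int,
                             unit: str = "bits",
                             literal_eq: bool = False) -> float:
    """Transfer entropy from ``source`` to ``target`` conditioned also on
    ``conditioner``'s past: I(target_t; source_{t-tau} | target_{t-tau},
    conditioner_{t-tau}) of the empirical distribution."""
    source, target = _check_discrete_pair(source, target, tau)
    conditioner = np.asarray(conditioner, dtype=np.int64)
    if conditioner.shape != source.shape:
        raise ValueError("conditioner length mismatch")
    fn = _pte_literal_nats if literal_eq else _pte_nats
    return _to_unit(fn(source, target, conditioner, tau), unit)


# ---------------------------------------------------------------------------
# pair preparation and named estimators
# ---------------------------------------------------------------------------

#: estimator registry: name -> (needs_phase, discretization)
ESTIMATORS = ("cte", "scte", "cte_direct", "ste", "hte")


def prepare_pair(z1: ComplexSeries, z2: ComplexSeries, estimator: str,
                 beta: float = DEFAULT_BETA, hte_bins: int | None = None):
    """Discretize a signal pair once for repeated estimator evaluation.

    Returns two dicts of integer-coded arrays (keys 'mag' and, for the
    complex estimators, 'phase').  Symbolization thresholds depend only on
    the sample means, so the encodings are invariant under time permutation
    of a series — surrogates can therefore permute these codes directly.
    HTE bins the two raw magnitude series on one shared equal-width grid.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if z1.T != z2.T:
        raise ValueError("signals must share the same length")
    if estimator == "hte":
        return (
            {"mag": bin_raw(z1.magnitude, z2.magnitude, hte_bins)},
            {"mag": bin_raw(z2.magnitude, z1.magnitude, hte_bins)},
        )
    if estimator == "ste":
        return (
            {"mag": symbolize(z1.magnitude, beta).codes},
            {"mag": symbolize(z2.magnitude, beta).codes},
        )
    return (
        {"mag": symbolize(z1.magnitude, beta).codes,
         "phase": symbolize(z1.phase, beta).codes},
        {"mag": symbolize(z2.magnitude, beta).codes,
         "phase": symbolize(z2.phase, beta).codes},
    )


def evaluate(estimator: str, src: dict, tgt: dict, tau: int,
             tau_phase: int | None = None, literal_eq: bool = False) -> float:
    """Evaluate a named estimator (nats) on prepared code dicts for the
    ordered direction src -> tgt.  ``tau`` drives the magnitude terms,
    ``tau_phase`` (default: same) the phase terms."""
    tp = tau if tau_phase is None else tau_phase
    if estimator == "hte":
        return _te_nats(src["mag"], tgt["mag"], tau)
    if estimator == "ste":
        return _te_nats(src["mag"], tgt["mag"], tau, sym=True)
    a, th = src["mag"], src["phase"]
    b, ph = tgt["mag"], tgt["phase"]
    value = _te_nats(a, b, tau, sym=True) + _te_nats(th, ph, tp, sym=True)
    if estimator == "scte":
        return value
    if estimator == "cte_direct":
        # direct magnitude-phase TE in place of the partial terms:
        # R_{b->theta} + R_{a->phi}
        return value + _te_nats(b, th, tp, sym=True) \
            + _te_nats(a, ph, tp, sym=True)
    if literal_eq:
        return value + _pte_literal_nats(a, b, th, tau) \
            + _pte_literal_nats(th, ph, a, tp)
    return value + _pte_nats(a, b, th, tau, sym=True) \
        + _pte_nats(th, ph, a, tp, sym=True)


def _resolve_taus(z1: ComplexSeries, z2: ComplexSeries,
                  config: TEConfig) -> tuple[int, int]:
    """(magnitude delay, phase delay) for the ordered direction z1 -> z2."""
    if config.tau is not None:
        tau = config.tau
    else:
        tau = select_delay(z1.magnitude, z2.magnitude, config.max_lag,
                           config.delay_mode).tau
    tau_p = config.tau_phase if config.tau_phase is not None else tau
    return tau, tau_p


def _run(estimator: str, z1, z2, config: TEConfig | None) -> float:
    config = config or TEConfig()
    tau, tau_p = _resolve_taus(z1, z2, config)
    src, tgt = prepare_pair(z1, z2, estimator, config.beta, config.hte_bins)
    return _to_unit(
        evaluate(estimator, src, tgt, tau, tau_p, config.literal_eq),
        config.unit,
    )


def cte(z1: ComplexSeries, z2: ComplexSeries, config: TEConfig | None = None) -> float:
    """Complex-valued transfer entropy z1 -> z2: magnitude TE + phase TE +
    the two partial cross terms (magnitude->magnitude given source phase,
    phase->phase given source magnitude)."""
    return _run("cte", z1, z2, config)


def scte(z1: ComplexSeries, z2: ComplexSeries, config: TEConfig | None = None) -> float:
    """Simplified complex-valued TE: magnitude TE + phase TE only."""
    return _run("scte", z1, z2, config)


def cte_direct_magphase(z1, z2, config: TEConfig | None = None) -> float:
    """Ablation variant replacing the partial terms with direct cross
    transfer entropies (target magnitude -> source phase and source
    magnitude -> target phase)."""
    return _run("cte_direct", z1, z2, config)


def ste(z1, z2, config: TEConfig | None = None) -> float:
    """Symbolic transfer entropy on the magnitude channel only."""
    return _run("ste", z1, z2, config)


def hte(z1, z2, config: TEConfig | None = None) -> float:
    """Histogram transfer entropy on raw magnitudes (no symbolization),
    bin width = joint range / T."""
    return _run("hte", z1, z2, config)


def cte_components(z1, z2, config: TEConfig | None = None) -> dict[str, float]:
    """The four additive terms of the complex-valued TE, in config.unit."""
    config = config or TEConfig()
    tau, tau_p = _resolve_taus(z1, z2, config)
    src, tgt = prepare_pair(z1, z2, "cte", config.beta)
    a, th = src["mag"], src["phase"]
    b, ph = tgt["mag"], tgt["phase"]
    pte = _pte_literal_nats if config.literal_eq else _pte_nats
    parts = {
        "mag_mag": _te_nats(a, b, tau),
        "phase_phase": _te_nats(th, ph, tau_p),
        "mag_mag_given_phase": pte(a, b, th, tau),
        "phase_phase_given_mag": pte(th, ph, a, tau_p),
    }
    return {k: _to_unit(v, config.unit) for k, v in parts.items()}
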