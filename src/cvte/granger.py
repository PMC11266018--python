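"""Granger causal test baseline on the magnitude channel.

Order-J autoregressions without intercept are fitted by ordinary least
squares in both directions; whether the candidate source's lags reduce the
residual variance of the target's own autoregression is judged by the
standard nested-model F-test (default) or by the raw variance comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signals import select_delay

__all__ = ["GrangerFit", "granger_fit", "granger_direction"]

A_TO_B = "a->b"
B_TO_A = "b->a"
NONE = "none"


@dataclass(frozen=True)
class GrangerFit:
    """Nested OLS fits for predicting one target series.

    ``var_restricted`` is the residual variance of the target's own-lags
    model, ``var_full`` of the model that adds the source's lags; nesting
    guarantees var_full <= var_restricted up to numerical rounding.
    """

    order_J: int
    var_restricted: float
    var_full: float
    coef_full_own: np.ndarray     # u_j: target's own-lag coefficients (full)
    coef_full_cross: np.ndarray   # v_j: source-lag coefficients (full)
    coef_restricted: np.ndarray   # c_j: own-lag coefficients (restricted)
    f_stat: float
    p_value: float
    n_obs: int

    def __post_init__(self):
        if self.order_J < 1:
            raise ValueError("order_J must be >= 1")
        if self.var_full > self.var_restricted + 1e-12:
            raise ValueError("full-model variance exceeds restricted (nesting)")


def _lag_matrix(x: np.ndarray, J: int) -> np.ndarray:
    """Columns x_{t-1}..x_{t-J} aligned with x_{J}..x_{T-1}."""
    T = x.size
    return np.column_stack([x[J - j: T - j] for j in range(1, J + 1)])


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit without intercept; ridge fallback if the design is
    rank deficient.  Returns (coefficients, residual variance)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient Granger design; using ridge fallback",
            RuntimeWarning,
            stacklevel=3,
        )
        lam = 1e-8 * np.trace(X.T @ X) / X.shape[1]
        coef = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def granger_fit(target, source, J: int) -> GrangerFit:
    """Fit the restricted (own lags only) and full (own + source lags)
    models for predicting ``target``, with the nested-model F statistic for
    the J added source lags."""
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.shape != source.shape or target.ndim != 1:
        raise ValueError("target and source must be 1-D vectors of equal length")
    if J < 1:
        raise ValueError("J must be >= 1")
    T = target.size
    if T <= 2 * J + 2:
        raise ValueError("series too short for order J")

    y = target[J:]
    X_own = _lag_matrix(target, J)
    X_full = np.hstack([X_own, _lag_matrix(source, J)])
    n = y.size

    coef_r, rss_r = _ols(X_own, y)
    coef_f, rss_f = _ols(X_full, y)
    rss_f = min(rss_f, rss_r)  # guard rounding in the nesting inequality

    df_denom = n - 2 * J
    if rss_f <= 0.0 or df_denom <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((rss_r - rss_f) / J) / (rss_f / df_denom)
        p_value = float(stats.f.sf(f_stat, J, df_denom))

    return GrangerFit(
        order_J=J,
        var_restricted=rss_r / n,
        var_full=rss_f / n,
        coef_full_own=coef_f[:J],
        coef_full_cross=coef_f[J:],
        coef_restricted=coef_r,
        f_stat=float(f_stat),
        p_value=p_value,
        n_obs=n,
    )


def granger_direction(a, b, J: int | None = None, p_th: float = 0.05,
                      method: str = "ftest", max_lag: int = 10) -> str:
    """Net Granger direction between two real series.

    Fits both prediction directions; with ``method='ftest'`` (default) a
    direction is only admitted when its added-lags F-test is significant at
    ``p_th``, and the net verdict is the significant direction with the
    larger F statistic.  ``method='raw'`` applies the bare variance
    comparison (any reduction counts), which declares a direction almost
    surely on finite data and is kept only for comparison.

    ``J=None`` uses the delay estimated by the lagged-correlation scan.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method not in ("ftest", "raw"):
        raise ValueError(f"unknown method {method!r}")
    if J is None:
        J = select_delay(a, b, max_lag=max_lag).tau

    fit_b = granger_fit(b, a, J)   # does a help predict b?  evidence a->b
    fit_a = granger_fit(a, b, J)   # does b help predict a?  evidence b->a

    if method == "raw":
        gain_ab = fit_b.var_restricted - fit_b.var_full
        gain_ba = fit_a.var_restricted - fit_a.var_full
        if gain_ab == gain_ba:
            return NONE
        return A_TO_B if gain_ab > gain_ba else B_TO_A

    sig_ab = fit_b.p_value < p_th
    sig_ba = fit_a.p_value < p_th
    if not sig_ab and not sig_ba:
        return NONE
    if sig_ab and not sig_ba:
        return A_TO_B
    if sig_ba and not sig_ab:
        return B_TO_A
    return A_TO_B if fit_b.f_stat >= fit_a.f_stat else B_TO_A
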