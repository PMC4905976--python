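"""Linear Granger causality baseline with F-test and BIC order selection.

The classical estimator: fit nested autoregressive models of the target
by ordinary least squares — restricted (own lags, plus conditioning
lags in the conditional variant) and unrestricted (adding the source
lags) — and report log(var_restricted / var_unrestricted).  Both models
are fit on the same aligned samples so the nested-model F-test applies
exactly.  Linear GC detects linear coupling only; it is kept here as
the side-by-side comparison for the nonparametric estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .causality import CausalityResult
from .embedding import embed_channel
from .timeseries import TimeSeriesSet

__all__ = ["ARModelFit", "linear_gc", "conditional_linear_gc", "select_order_bic"]


class BaselineError(ValueError):
    """Degenerate input to an AR fit."""


@dataclass(frozen=True)
class ARModelFit:
    """OLS fit of one lag-stacked AR design (intercept included)."""

    order: int
    coefficients: np.ndarray
    residual_variance: float
    n_obs: int
    bic: float


def _ols(y: np.ndarray, X: np.ndarray) -> tuple:
    """Least-squares fit with intercept; returns (coef, rss, residuals)."""
    Xc = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    if rank < Xc.shape[1]:
        raise BaselineError("singular AR design matrix")
    resid = y - Xc @ coef
    return coef, float(resid @ resid), resid


def conditional_linear_gc(
    ts: TimeSeriesSet,
    source: str,
    target: str,
    conditioning=(),
    order: int = 1,
    alpha: float = 0.05,
) -> CausalityResult:
    """Conditional linear GC(source -> target | conditioning) at lag
    order p, with nested-model F-test significance.

    The restricted model regresses the target on p lags of itself and
    of each conditioning channel; the unrestricted model adds p lags of
    the source.  ``value_raw = log(RSS_r / RSS_u)`` (the common sample
    size cancels), and the F statistic

        F = ((RSS_r - RSS_u) / p) / (RSS_u / (n - k_u))

    is referred to F(p, n - k_u).
    """
    conditioning = tuple(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    if order < 1:
        raise ValueError("order must be >= 1")
    T = ts.n_samples
    if T <= 3 * order + 3:
        raise BaselineError(f"record of length {T} too short for order {order}")

    y = ts.channel(target)[order:]
    restricted_blocks = [embed_channel(ts.channel(c), 1, order) for c in (target, *conditioning)]
    X_r = np.hstack(restricted_blocks)
    X_u = np.hstack([X_r, embed_channel(ts.channel(source), 1, order)])

    _, rss_r, _ = _ols(y, X_r)
    _, rss_u, _ = _ols(y, X_u)
    n = len(y)
    k_u = X_u.shape[1] + 1
    if rss_u <= 0.0:
        raise BaselineError("perfect unrestricted fit; GC undefined")
    f_stat = ((rss_r - rss_u) / order) / (rss_u / (n - k_u))
    p_value = float(stats.f.sf(max(f_stat, 0.0), order, n - k_u))
    raw = math.log(rss_r / rss_u)
    return CausalityResult(
        source=source,
        target=target,
        conditioning=conditioning,
        value_raw=raw,
        uni_variance=rss_r / n,
        multi_variance=rss_u / n,
        significant=bool(p_value < alpha),
        threshold=math.nan,
        params={"order": order, "alpha": alpha, "f_stat": float(f_stat), "p_value": p_value,
                "method": "linear_gc"},
    )


def linear_gc(
    ts: TimeSeriesSet,
    source: str,
    target: str,
    order: int = 1,
    alpha: float = 0.05,
) -> CausalityResult:
    """Pairwise linear GC(source -> target) at lag order p."""
    return conditional_linear_gc(ts, source, target, (), order=order, alpha=alpha)


def _var_fit(values: np.ndarray, order: int, t_start: int) -> ARModelFit:
    """Joint VAR(p) OLS fit on samples from ``t_start`` on (shared
    alignment across candidate orders)."""
    T, n_ch = values.shape
    y = values[t_start:]
    X = np.hstack([values[t_start - k : T - k] for k in range(1, order + 1)])
    Xc = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    if rank < Xc.shape[1]:
        raise BaselineError("singular VAR design matrix")
    resid = y - Xc @ coef
    n = len(y)
    sigma = (resid.T @ resid) / n
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise BaselineError("residual covariance not positive definite")
    free_params = order * n_ch * n_ch + n_ch  # lag coefficients + intercepts
    bic = logdet + free_params * math.log(n) / n
    rv = float(np.mean(np.diag(sigma)))
    return ARModelFit(order=order, coefficients=coef, residual_variance=rv, n_obs=n, bic=bic)


def select_order_bic(ts: TimeSeriesSet, channels=None, p_max: int = 10) -> int:
    """Smallest-BIC VAR order over p = 1..p_max.

    All candidate orders are fit on the same samples (the first p_max
    rows are dropped once) so their BICs are comparable.
    """
    channels = tuple(channels) if channels is not None else ts.channels
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if p_max >= ts.n_samples / 10:
        raise ValueError("p_max too large for record length (need p_max < T/10)")
    values = np.column_stack([ts.channel(c) for c in channels])
    bics = []
    fits = {}
    for p in range(1, p_max + 1):
        fit = _var_fit(values, p, t_start=p_max)
        fits[p] = fit
        bics.append((fit.bic, p))
    return min(bics)[1]
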