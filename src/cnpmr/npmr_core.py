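"""Nonparametric multiplicative regression (NPMR) with leave-one-out
local-mean prediction.

The response at time t is estimated as a weighted mean of every *other*
response sample, where sample i's weight is the product over predictor
columns j of a Gaussian kernel evaluated at the distance between x_{i,j}
and the query coordinate x_{t,j}:

    w_{i,j} = exp(-0.5 ((x_{i,j} - x_{t,j}) / sigma_j)^2)
    yhat_t  = sum_{i != t} y_i prod_j w_{i,j} / sum_{i != t} prod_j w_{i,j}

Multiplying (rather than adding) the per-predictor weights means a point
that is far from the query on *any* predictor contributes nothing —
this is what lets the same estimator serve pairwise and conditional
causality without modification.  Leaving t itself out of its own
weighted mean is the cross-validation that prevents overfitting.

The kernel tolerance sigma_j is the bandwidth per predictor.  The
benchmark experiments fix sigma_j = 1 for all predictors; as a
data-driven alternative, :func:`tolerance_from_range` takes the value
such that the observed predictor range spans six tolerances.

If the raw signals live on wildly different scales a fixed tolerance can
drive every product weight to zero for some query points; such points
are flagged invalid and excluded.  Z-scoring the channels first (see
:func:`cnpmr.timeseries.zscore`) avoids this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddedDesign

__all__ = [
    "KernelConfig",
    "NPMRFit",
    "NPMRError",
    "kernel_weights",
    "npmr_predict",
    "cross_r2",
    "tolerance_from_range",
]


class NPMRError(ValueError):
    """Degenerate input to an NPMR fit."""


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian-kernel tolerances, one per predictor column.

    ``tolerances`` may be a scalar (broadcast to every column) or a
    sequence matching the design width m.  All tolerances must be
    positive.
    """

    tolerances: object = 1.0
    kernel: str = "gaussian"

    def __post_init__(self):
        if self.kernel != "gaussian":
            raise NPMRError(f"unsupported kernel {self.kernel!r}")
        tol = np.atleast_1d(np.asarray(self.tolerances, dtype=float))
        if not np.all(tol > 0):
            raise NPMRError("all kernel tolerances must be > 0")
        object.__setattr__(self, "tolerances", tol)

    def resolve(self, m: int) -> np.ndarray:
        """Per-column tolerance vector of length m."""
        tol = self.tolerances
        if tol.size == 1:
            return np.full(m, tol[0])
        if tol.size != m:
            raise NPMRError(f"{tol.size} tolerances for {m} predictor columns")
        return tol.copy()


@dataclass(frozen=True)
class NPMRFit:
    """Leave-one-out fit: predictions, residual variance, cross R^2.

    ``valid_mask`` flags query points whose weight denominator did not
    underflow to zero; predictions at invalid points are NaN and are
    excluded from ``error_variance`` and ``xr2``.
    """

    predictions: np.ndarray
    residuals: np.ndarray
    error_variance: float
    xr2: float
    valid_mask: np.ndarray = field(repr=False)
    n_valid: int


def kernel_weights(column, target_value: float, sigma: float) -> np.ndarray:
    """Gaussian weights of one predictor column against a query value."""
    column = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(column)) or not np.isfinite(target_value):
        raise NPMRError("non-finite values in kernel input")
    if sigma <= 0:
        raise NPMRError("sigma must be > 0")
    z = (column - target_value) / sigma
    return np.exp(-0.5 * z * z)


def log_weight_contribution(lag_matrix: np.ndarray, sigmas) -> np.ndarray:
    """Symmetric T x T log-weight term summed over the given columns.

    Entry (i, t) is sum_j -0.5 ((x_{i,j} - x_{t,j}) / sigma_j)^2.  The
    full multiplicative weight matrix is exp of the sum of these
    contributions over all predictor blocks, which lets callers cache
    the block for columns that do not change (e.g. the response
    channel's own lags across surrogate re-fits).
    """
    lag_matrix = np.atleast_2d(np.asarray(lag_matrix, dtype=float))
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (lag_matrix.shape[1],))
    T = lag_matrix.shape[0]
    acc = np.zeros((T, T))
    diff = np.empty((T, T))
    for j in range(lag_matrix.shape[1]):
        col = lag_matrix[:, j]
        np.subtract(col[:, None], col[None, :], out=diff)
        np.square(diff, out=diff)
        diff *= -0.5 / (sigmas[j] * sigmas[j])
        acc += diff
    return acc


def fit_from_log_weights(y: np.ndarray, log_w: np.ndarray) -> NPMRFit:
    """Finish a leave-one-out fit given the summed log-weight matrix."""
    y = np.asarray(y, dtype=float)
    T = len(y)
    if T < 3:
        raise NPMRError("need at least 3 samples for a leave-one-out fit")
    W = np.exp(log_w)
    np.fill_diagonal(W, 0.0)
    denom = W.sum(axis=0)
    valid = denom > 0.0
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise NPMRError(
            "fewer than 2 query points received any kernel weight; "
            "z-score the channels or enlarge the kernel tolerance"
        )
    num = y @ W
    predictions = np.full(T, np.nan)
    predictions[valid] = num[valid] / denom[valid]
    residuals = y - predictions
    error_variance = float(np.var(residuals[valid], ddof=1))
    yv = y[valid]
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0.0:
        raise NPMRError("response is constant over valid points; xR^2 undefined")
    rss = float(np.sum(residuals[valid] ** 2))
    xr2 = 1.0 - rss / tss
    return NPMRFit(
        predictions=predictions,
        residuals=residuals,
        error_variance=error_variance,
        xr2=xr2,
        valid_mask=valid,
        n_valid=n_valid,
    )


def npmr_predict(design: EmbeddedDesign, config: KernelConfig | None = None) -> NPMRFit:
    """Leave-one-out NPMR fit of a design under a kernel configuration."""
    config = config or KernelConfig()
    if design.m < 1:
        raise NPMRError("design has no predictor columns")
    sigmas = config.resolve(design.m)
    if not np.all(np.isfinite(design.predictors)) or not np.all(np.isfinite(design.response)):
        raise NPMRError("non-finite values in design")
    log_w = log_weight_contribution(design.predictors, sigmas)
    return fit_from_log_weights(design.response, log_w)


def cross_r2(y, yhat) -> float:
    """Goodness of fit 1 - RSS/TSS from cross-validated predictions.

    1 is a perfect fit, 0 no better than the response mean; weak models
    can go negative because the predictions are leave-one-out, not
    in-sample.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise NPMRError("y and yhat must be equal-length vectors of length >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise NPMRError("constant response; xR^2 undefined")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


def tolerance_from_range(column) -> float:
    """Data-driven tolerance: the column range spans six tolerances."""
    column = np.asarray(column, dtype=float)
    rng = float(np.max(column) - np.min(column))
    if rng == 0.0:
        raise NPMRError("constant predictor column; range-based tolerance undefined")
    return rng / 6.0
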