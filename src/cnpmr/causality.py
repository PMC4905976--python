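"""Pairwise and conditional causality from paired NPMR fits.

Following the Granger framework, the causal influence of a source X on a
target Y is the log ratio of the leave-one-out prediction-error
variances of two nested NPMR models of Y:

    C(X -> Y)       = log( var[Y | own lags] / var[Y | own + X lags] )
    C(X -> Y | Z)   = log( var[Y | own + Z lags] / var[Y | own + Z + X lags] )

A positive value means the source's past improves the prediction of the
target beyond what the target's own past (and, conditionally, the other
channels' pasts) already provides.  Negative raw values mean the extra
predictors hurt the cross-validated fit and are clipped to zero for
reporting, while the raw value is preserved for statistics.

Both fits in a ratio are compared over the intersection of their valid
query points, so the two variances always describe identical samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .embedding import build_design
from .npmr_core import (
    KernelConfig,
    NPMRError,
    NPMRFit,
    fit_from_log_weights,
    log_weight_contribution,
)
from .timeseries import TimeSeriesSet

__all__ = [
    "CausalityResult",
    "cnpmr_pairwise",
    "cnpmr_conditional",
    "cnpmr_all_pairs",
    "windowed_cnpmr",
    "adjacency",
    "DISPLAY_THRESHOLD",
]

#: Graph edges with clipped causality below this are conventionally not
#: drawn; a reporting convention only, never part of estimation.
DISPLAY_THRESHOLD = 0.005


@dataclass(frozen=True)
class CausalityResult:
    """One directed causality estimate.

    ``value_raw`` is the unbounded log variance ratio; ``value`` is the
    reported, non-negative version (negative ratios indicate a worse
    multivariate fit, i.e. no causal relationship).  ``significant`` and
    ``threshold`` stay unset (None/NaN) until surrogate testing.
    """

    source: str
    target: str
    conditioning: tuple
    value_raw: float
    uni_variance: float
    multi_variance: float
    significant: bool | None = None
    threshold: float = math.nan
    params: dict = field(default_factory=dict, compare=False)

    @property
    def value(self) -> float:
        return max(self.value_raw, 0.0)

    def to_record(self) -> dict:
        """JSON-ready record with deterministic key order."""
        return {
            "source": self.source,
            "target": self.target,
            "conditioning": list(self.conditioning),
            "value": self.value,
            "value_raw": self.value_raw,
            "significant": self.significant,
            "threshold": None if math.isnan(self.threshold) else self.threshold,
            "uni_variance": self.uni_variance,
            "multi_variance": self.multi_variance,
            "params": {k: self.params[k] for k in sorted(self.params)},
        }


def variance_ratio(fit_restricted: NPMRFit, fit_full: NPMRFit) -> tuple:
    """(restricted var, full var, log ratio) over the common valid points."""
    mask = fit_restricted.valid_mask & fit_full.valid_mask
    if int(mask.sum()) < 2:
        raise NPMRError("fewer than 2 points valid in both fits")
    var_r = float(np.var(fit_restricted.residuals[mask], ddof=1))
    var_f = float(np.var(fit_full.residuals[mask], ddof=1))
    if var_r <= 0.0 or var_f <= 0.0:
        raise NPMRError("zero residual variance; causality ratio undefined")
    return var_r, var_f, math.log(var_r / var_f)


def _params(tau, d, config, extra=None):
    p = {"tau": tau, "d": d, "sigma": np.asarray(config.tolerances).tolist()}
    if extra:
        p.update(extra)
    return p


def cnpmr_conditional(
    ts: TimeSeriesSet,
    source: str,
    target: str,
    conditioning=(),
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
) -> CausalityResult:
    """Conditional causality C(source -> target | conditioning).

    With an empty conditioning set this *is* the pairwise estimate —
    the restricted model then contains only the target's own lags.
    """
    config = config or KernelConfig()
    conditioning = tuple(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    restricted = build_design(ts, target, conditioning, tau=tau, d=d)
    full = build_design(ts, target, (*conditioning, source), tau=tau, d=d)
    # per-column tolerances are indexed by the full design; the
    # restricted model uses its leading (shared) columns
    sigmas = config.resolve(full.m)
    fit_r = _fit(restricted, sigmas[: restricted.m])
    fit_f = _fit(full, sigmas)
    var_r, var_f, raw = variance_ratio(fit_r, fit_f)
    return CausalityResult(
        source=source,
        target=target,
        conditioning=conditioning,
        value_raw=raw,
        uni_variance=var_r,
        multi_variance=var_f,
        params=_params(tau, d, config),
    )


def _fit(design, sigmas):
    log_w = log_weight_contribution(design.predictors, sigmas)
    return fit_from_log_weights(design.response, log_w)


def cnpmr_pairwise(
    ts: TimeSeriesSet,
    source: str,
    target: str,
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
) -> CausalityResult:
    """Pairwise causality C(source -> target): restricted model is the
    target's own past only."""
    return cnpmr_conditional(ts, source, target, (), tau=tau, d=d, config=config)


def cnpmr_all_pairs(
    ts: TimeSeriesSet,
    mode: str = "pairwise",
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
) -> dict:
    """All ordered channel pairs; dict keyed by (source, target).

    In ``conditional`` mode the conditioning set of each pair is every
    remaining channel, which suppresses indirect links.
    """
    if mode not in ("pairwise", "conditional"):
        raise ValueError("mode must be 'pairwise' or 'conditional'")
    if ts.n_channels < 2:
        raise ValueError("need at least 2 channels")
    out = {}
    for target in ts.channels:
        for source in ts.channels:
            if source == target:
                continue
            cond = (
                tuple(c for c in ts.channels if c not in (source, target))
                if mode == "conditional"
                else ()
            )
            out[(source, target)] = cnpmr_conditional(
                ts, source, target, cond, tau=tau, d=d, config=config
            )
    return out


def adjacency(results: dict, channels, attr: str = "value") -> pd.DataFrame:
    """Square matrix view of all-pairs results (rows: source, cols: target).

    ``attr`` may be any CausalityResult field name or "value"; the
    diagonal is NaN.  Edges below :data:`DISPLAY_THRESHOLD` are the
    caller's concern — values are reported as-is.
    """
    channels = list(channels)
    mat = pd.DataFrame(np.nan, index=channels, columns=channels)
    for (src, tgt), res in results.items():
        mat.loc[src, tgt] = getattr(res, attr)
    return mat


def windowed_cnpmr(
    ts: TimeSeriesSet,
    window_len: int,
    mode: str = "pairwise",
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
    estimator=None,
) -> list:
    """Split a long record into non-overlapping windows and estimate
    each one; the trailing remainder is discarded.

    ``estimator`` defaults to :func:`cnpmr_all_pairs`; any callable with
    the signature ``f(ts, mode, tau, d, config)`` (e.g. a
    significance-testing wrapper) can be substituted.
    """
    if window_len > ts.n_samples:
        raise ValueError("window_len exceeds record length")
    if window_len < d * tau + 3:
        raise ValueError(f"window_len must be at least d*tau + 3 = {d * tau + 3}")
    estimator = estimator or cnpmr_all_pairs
    n_windows = ts.n_samples // window_len
    out = []
    for w in range(n_windows):
        win = ts.window(w * window_len, (w + 1) * window_len)
        out.append(estimator(win, mode=mode, tau=tau, d=d, config=config))
    return out
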