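"""Time-shifted surrogate significance testing and sensitivity analysis.

Significance: the null hypothesis "the source's past carries no
information about the target" is emulated by circularly rotating the
source channel by a large random offset.  The rotation preserves the
source's marginal distribution and autocorrelation but destroys its
alignment with the target.  The estimate is declared significant when
the real causality exceeds the *maximum* over S surrogate estimates;
with S = 1/alpha - 1 surrogates that max-threshold test has size alpha.

Sensitivity: within a fitted NPMR model, the importance of predictor
column j is probed by nudging the query coordinate x_{t,j} up and down
by a small fraction Delta of the column's range and measuring the mean
absolute response change, normalised by the response range:

    Q(Y/X_j) = sum_t (|yhat+_t - yhat_t| + |yhat-_t - yhat_t|)
               / (2 T |y_max - y_min| Delta)

Q = 0 means the predictor has no detectable effect; Q = 1 means a nudge
moves the response by an equal relative amount.  Only the query
coordinate moves — the stored sample coordinates stay fixed, otherwise
the perturbation would cancel in every kernel distance.  Sensitivities
are only meaningful for links whose causality passed the surrogate
test, so profiles are gated on significance and need no separate test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .causality import CausalityResult, variance_ratio
from .embedding import EmbeddedDesign, build_design, embed_channel
from .npmr_core import (
    KernelConfig,
    NPMRError,
    fit_from_log_weights,
    log_weight_contribution,
)
from .timeseries import TimeSeriesSet

__all__ = [
    "SurrogateConfig",
    "SensitivityProfile",
    "surrogate_count",
    "time_shift_surrogate",
    "significance_test",
    "significance_all_pairs",
    "sensitivity_q",
    "sensitivity_all",
    "sensitivity_profile",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Surrogate-test parameters.

    ``n_surrogates`` defaults to ceil(1/alpha - 1), the smallest count
    for which the max-of-surrogates threshold attains level alpha.
    ``min_shift_fraction`` bounds the random rotation away from small
    offsets that would leave the alignment partly intact.
    """

    alpha: float = 0.05
    n_surrogates: int | None = None
    min_shift_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.min_shift_fraction < 1.0:
            raise ValueError("min_shift_fraction must lie in (0, 1)")
        if self.n_surrogates is not None and self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")

    @property
    def effective_n_surrogates(self) -> int:
        if self.n_surrogates is not None:
            return self.n_surrogates
        return surrogate_count(self.alpha)


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-(channel, lag) sensitivities of one response model.

    ``entries`` holds (predictor channel, lag, Q) triples; insignificant
    links are omitted, or zeroed when ``gated`` is False at call time.
    """

    response: str
    entries: tuple
    delta: float
    gated: bool

    def as_dict(self) -> dict:
        return {(ch, lag): q for ch, lag, q in self.entries}


def surrogate_count(alpha: float) -> int:
    """Number of surrogates for the max-threshold test: ceil(1/alpha - 1)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    # guard against float artefacts like 1/0.05 - 1 = 19.000000000000004
    return math.ceil(1.0 / alpha - 1.0 - 1e-9)


def time_shift_surrogate(series, cfg: SurrogateConfig, rng: np.random.Generator) -> np.ndarray:
    """Circularly rotate a channel by a random offset of at least
    ``ceil(L * min_shift_fraction)`` samples."""
    series = np.asarray(series, dtype=float)
    L = len(series)
    if L < 6:
        raise ValueError("series too short for a time-shift surrogate")
    lo = math.ceil(L * cfg.min_shift_fraction)
    hi = L - 1
    if lo > hi:
        raise ValueError("min_shift_fraction leaves no admissible shift")
    shift = int(rng.integers(lo, hi + 1))
    return np.roll(series, shift)


def _surrogate_rng(cfg: SurrogateConfig, key: tuple) -> np.random.Generator:
    entropy = [int(cfg.seed) & 0x7FFFFFFF, *[int(k) for k in key]]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def significance_test(
    ts: TimeSeriesSet,
    source: str,
    target: str,
    conditioning=(),
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
    surrogate_cfg: SurrogateConfig | None = None,
) -> CausalityResult:
    """Estimate C(source -> target | conditioning) and test it against
    time-shifted surrogates of the source.

    Only the candidate source is surrogated; the restricted model (and
    its fit) is shared by the real and all surrogate estimates, so the
    threshold compares like with like.  Each surrogate draws its shift
    from an independent stream keyed by (seed, source, target,
    surrogate index) for reproducible thresholds.
    """
    config = config or KernelConfig()
    cfg = surrogate_cfg or SurrogateConfig()
    conditioning = tuple(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")

    restricted = build_design(ts, target, conditioning, tau=tau, d=d)
    sigmas_all = config.resolve(restricted.m + d)
    log_w_base = log_weight_contribution(restricted.predictors, sigmas_all[: restricted.m])
    fit_r = fit_from_log_weights(restricted.response, log_w_base)
    src_sigmas = sigmas_all[restricted.m :]
    src_series = ts.channel(source)

    def fit_with_source(series):
        lags = embed_channel(series, tau, d)
        log_w = log_w_base + log_weight_contribution(lags, src_sigmas)
        return fit_from_log_weights(restricted.response, log_w)

    fit_f = fit_with_source(src_series)
    var_r, var_f, raw = variance_ratio(fit_r, fit_f)

    S = cfg.effective_n_surrogates
    src_i = ts.channels.index(source)
    tgt_i = ts.channels.index(target)
    surrogate_values = np.empty(S)
    for s in range(S):
        rng = _surrogate_rng(cfg, (src_i, tgt_i, s))
        shifted = time_shift_surrogate(src_series, cfg, rng)
        fit_s = fit_with_source(shifted)
        _, _, surrogate_values[s] = variance_ratio(fit_r, fit_s)

    threshold = float(surrogate_values.max())
    return CausalityResult(
        source=source,
        target=target,
        conditioning=conditioning,
        value_raw=raw,
        uni_variance=var_r,
        multi_variance=var_f,
        significant=bool(raw > threshold),
        threshold=threshold,
        params={
            "tau": tau,
            "d": d,
            "sigma": np.asarray(config.tolerances).tolist(),
            "alpha": cfg.alpha,
            "n_surrogates": S,
        },
    )


def significance_all_pairs(
    ts: TimeSeriesSet,
    mode: str = "pairwise",
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
    surrogate_cfg: SurrogateConfig | None = None,
) -> dict:
    """Surrogate-tested causalities for all ordered pairs.

    Mirrors :func:`cnpmr.causality.cnpmr_all_pairs`; in ``conditional``
    mode each pair conditions on every remaining channel.
    """
    if mode not in ("pairwise", "conditional"):
        raise ValueError("mode must be 'pairwise' or 'conditional'")
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
            out[(source, target)] = significance_test(
                ts, source, target, cond, tau=tau, d=d,
                config=config, surrogate_cfg=surrogate_cfg,
            )
    return out


def sensitivity_all(
    design: EmbeddedDesign,
    config: KernelConfig | None = None,
    delta: float = 0.05,
    indices=None,
) -> dict:
    """Sensitivity Q for several predictor columns of one fitted design.

    The leave-one-out weight matrix is built once; each column's nudged
    predictions reuse it with a rank-style multiplicative update (only
    the query coordinate of column j moves, so only that column's
    kernel factor changes).  Returns {column index: Q}.
    """
    config = config or KernelConfig()
    if delta <= 0:
        raise ValueError("delta must be > 0")
    indices = list(range(design.m)) if indices is None else list(indices)
    y = design.response
    y_range = float(np.max(y) - np.min(y))
    if y_range == 0.0:
        raise NPMRError("constant response; sensitivity undefined")
    sigmas = config.resolve(design.m)
    log_w = log_weight_contribution(design.predictors, sigmas)
    W = np.exp(log_w)
    np.fill_diagonal(W, 0.0)
    denom = W.sum(axis=0)
    valid = denom > 0.0
    yhat = np.full(design.t_eff, np.nan)
    yhat[valid] = (y @ W)[valid] / denom[valid]

    out = {}
    for j in indices:
        col = design.predictors[:, j]
        col_range = float(np.max(col) - np.min(col))
        if col_range == 0.0:
            raise NPMRError(f"constant predictor column {j}; sensitivity undefined")
        delta_abs = delta * col_range
        diff = col[:, None] - col[None, :]  # x_{i,j} - x_{t,j}
        s2 = sigmas[j] * sigmas[j]
        q_sum = np.zeros(design.t_eff)
        mask = valid.copy()
        for sign in (+1.0, -1.0):
            Wn = W * np.exp(sign * delta_abs * diff / s2 - 0.5 * delta_abs**2 / s2)
            dn = Wn.sum(axis=0)
            ok = dn > 0.0
            yn = np.full(design.t_eff, np.nan)
            yn[ok] = (y @ Wn)[ok] / dn[ok]
            mask &= ok
            q_sum += np.abs(yn - yhat)
        n_used = int(mask.sum())
        if n_used == 0:
            raise NPMRError("no query point valid in base and nudged fits")
        out[j] = float(q_sum[mask].sum() / (2.0 * n_used * y_range * delta))
    return out


def sensitivity_q(
    design: EmbeddedDesign,
    config: KernelConfig | None = None,
    predictor_index: int = 0,
    delta: float = 0.05,
) -> float:
    """Sensitivity of the response to one predictor column."""
    return sensitivity_all(design, config, delta, [predictor_index])[predictor_index]


def sensitivity_profile(
    ts: TimeSeriesSet,
    target: str,
    results: dict,
    tau: int = 1,
    d: int = 3,
    config: KernelConfig | None = None,
    delta: float = 0.05,
    gate: str = "omit",
) -> SensitivityProfile:
    """Gated sensitivities of one target's full multivariate model.

    Q is computed on the design containing the target's own lags plus
    every other channel's lags.  Entries for channels whose link
    ``(source, target)`` is not significant in ``results`` are omitted
    (``gate='omit'``) or reported as 0 (``gate='zero'``).
    """
    if gate not in ("omit", "zero"):
        raise ValueError("gate must be 'omit' or 'zero'")
    predictors = tuple(c for c in ts.channels if c != target)
    design = build_design(ts, target, predictors, tau=tau, d=d)
    significant = {
        src for src in predictors
        if (src, target) in results and results[(src, target)].significant
    }
    sig_cols = [j for j, (ch, _) in enumerate(design.labels) if ch in significant]
    qs = sensitivity_all(design, config, delta, sig_cols) if sig_cols else {}
    entries = []
    for j, (ch, lag) in enumerate(design.labels):
        if ch == target:
            continue
        if ch in significant:
            entries.append((ch, lag, qs[j]))
        elif gate == "zero":
            entries.append((ch, lag, 0.0))
    return SensitivityProfile(
        response=target, entries=tuple(entries), delta=delta, gated=(gate == "omit")
    )
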