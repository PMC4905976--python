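"""Takens time-delay embedding and design-matrix assembly.

A causal model of channel Y predicts y(t) from strictly past samples:
its own lags y(t-tau), ..., y(t-d*tau) and, optionally, the same lags of
candidate source channels.  ``embed_channel`` builds the lag matrix for
one channel; ``build_design`` stacks the response channel's lags first,
then each predictor channel's, all aligned to the same response index.
Lag 0 is never included — with it, prediction would be trivial and the
causal question empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeriesSet

__all__ = ["EmbeddedDesign", "embed_channel", "build_design"]


@dataclass(frozen=True)
class EmbeddedDesign:
    """Aligned response vector and lagged predictor matrix.

    ``labels[j]`` is ``(channel_name, lag_in_samples)`` for predictor
    column j; lags run 1..d (times tau) and are strictly past.
    ``t_offset`` is the index in the original series of the first
    response sample (= d * tau).
    """

    response: np.ndarray
    predictors: np.ndarray
    labels: tuple
    tau: int
    dim_d: int
    t_offset: int

    def __post_init__(self):
        if self.predictors.shape != (len(self.response), len(self.labels)):
            raise ValueError("predictor matrix shape does not match response/labels")

    @property
    def t_eff(self) -> int:
        return len(self.response)

    @property
    def m(self) -> int:
        return self.predictors.shape[1]

    def columns_for(self, channel: str) -> list:
        """Indices of the predictor columns belonging to one channel."""
        return [j for j, (ch, _) in enumerate(self.labels) if ch == channel]


def embed_channel(series, tau: int, d: int) -> np.ndarray:
    """Lag matrix of one channel: column k holds series[t - k*tau].

    Rows are aligned so that row r corresponds to response index
    t = r + d*tau.  Requires ``len(series) > d*tau``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if tau < 1 or d < 1:
        raise ValueError("tau and d must be >= 1")
    T = len(series)
    if T <= d * tau:
        raise ValueError(
            f"series of length {T} too short for tau={tau}, d={d}; need at least {d * tau + 1} samples"
        )
    t0 = d * tau
    cols = [series[t0 - k * tau : T - k * tau] for k in range(1, d + 1)]
    return np.column_stack(cols)


def build_design(
    ts: TimeSeriesSet,
    response_channel: str,
    predictor_channels=(),
    tau: int = 1,
    d: int = 3,
) -> EmbeddedDesign:
    """Assemble a causal prediction design for one response channel.

    The predictor matrix concatenates the embedded response channel
    first, then each entry of ``predictor_channels`` in order, so a
    univariate design (empty predictor list) has m = d columns and each
    extra channel adds d more.  All columns share the response
    alignment, so nested designs share their leading columns exactly.
    """
    names = [response_channel, *predictor_channels]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate channels in design: {names}")
    blocks = []
    labels = []
    for name in names:
        series = ts.channel(name)  # raises KeyError on unknown name
        blocks.append(embed_channel(series, tau, d))
        labels.extend((name, k * tau) for k in range(1, d + 1))
    response = ts.channel(response_channel)[d * tau :]
    return EmbeddedDesign(
        response=response,
        predictors=np.hstack(blocks),
        labels=tuple(labels),
        tau=tau,
        dim_d=d,
        t_offset=d * tau,
    )
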