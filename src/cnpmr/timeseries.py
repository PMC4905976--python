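"""Multichannel time-series container and delimited-text I/O.

A :class:`TimeSeriesSet` is a plain T x n matrix of synchronously sampled
channels with channel names attached.  It is deliberately thin: all
estimation code receives numpy views through it, and pandas handles the
round trip to CSV/TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesSet", "read_timeseries", "write_timeseries", "zscore"]


class TimeSeriesError(ValueError):
    """Malformed or degenerate time-series input."""


@dataclass(frozen=True)
class TimeSeriesSet:
    """T x n matrix of observed channels with names.

    Parameters
    ----------
    values : ndarray, shape (T, n)
        One column per channel, one row per sample.
    channels : tuple of str
        Channel names, one per column.
    fs : float, optional
        Sampling rate in Hz; purely metadata, never used in estimation.
    """

    values: np.ndarray
    channels: tuple
    fs: float | None = field(default=None, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TimeSeriesError("values must be a 2-D (T x n) array")
        channels = tuple(str(c) for c in self.channels)
        if len(channels) != values.shape[1]:
            raise TimeSeriesError(
                f"{len(channels)} channel names for {values.shape[1]} columns"
            )
        if len(set(channels)) != len(channels):
            raise TimeSeriesError("channel names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channels", channels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channels)}"
            ) from None
        return self.values[:, idx]

    def window(self, start: int, stop: int) -> "TimeSeriesSet":
        """Contiguous sample slice [start, stop) as a new set."""
        return TimeSeriesSet(self.values[start:stop], self.channels, fs=self.fs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.channels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float | None = None) -> "TimeSeriesSet":
        return cls(df.to_numpy(dtype=float), tuple(df.columns.astype(str)), fs=fs)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_timeseries(path, sep: str | None = None) -> TimeSeriesSet:
    """Read a delimited text file with a header row of channel names.

    The delimiter is inferred from the extension (``.tsv`` -> tab, else
    comma) unless given.  A header row is mandatory; missing values and
    non-numeric cells are hard errors that name the offending cell.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if all(_looks_numeric(c) for c in df.columns):
        raise TimeSeriesError(f"{path}: first row is numeric; a header row of channel names is required")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna()]
        if len(bad):
            raise TimeSeriesError(
                f"{path}: non-numeric or missing value in column {col!r}, row {int(bad[0]) + 2}"
            )
        df[col] = series
    ts = TimeSeriesSet.from_dataframe(df)
    const = [c for c in ts.channels if np.ptp(ts.channel(c)) == 0.0]
    if const:
        warnings.warn(f"constant channel(s) {const}; estimation on them will fail", stacklevel=2)
    return ts


def write_timeseries(ts: TimeSeriesSet, path, sep: str = ",") -> None:
    """Write a set as delimited text with a header row, full precision."""
    ts.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.17g")


def zscore(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Normalise every channel to zero mean and unit sample variance.

    Recommended before estimation when channels live on very different
    scales, so that a single kernel tolerance is meaningful for all
    predictors.
    """
    sd = ts.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(ts.channels, sd) if s == 0]
        raise TimeSeriesError(f"cannot z-score constant channel(s) {bad}")
    vals = (ts.values - ts.values.mean(axis=0)) / sd
    return TimeSeriesSet(vals, ts.channels, fs=ts.fs)
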