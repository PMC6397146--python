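"""Irregularly sampled observation series and calendar helpers.

Observation times are carried as decimal years on the proleptic Gregorian
calendar (day-of-year / 365.2425), which keeps gap arithmetic trivial for
the state-space machinery while CSV interfaces speak ISO-8601 dates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OrderingError

#: Mean Gregorian year length in days, used for date <-> decimal-year maps.
DAYS_PER_YEAR = 365.2425


def to_decimal_year(dates) -> np.ndarray:
    """Convert datetimes (anything ``pd.to_datetime`` accepts) to decimal years."""
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    frac_day = (idx.hour * 3600 + idx.minute * 60 + idx.second) / 86400.0
    return np.asarray(idx.year + (idx.dayofyear - 1 + frac_day) / DAYS_PER_YEAR, dtype=float)


def from_decimal_year(times) -> pd.DatetimeIndex:
    """Convert decimal years back to timestamps (second resolution)."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    years = np.floor(t).astype(int)
    rem_days = (t - years) * DAYS_PER_YEAR
    stamps = [
        (pd.Timestamp(int(y), 1, 1) + pd.Timedelta(seconds=round(d * 86400.0)))
        for y, d in zip(years, rem_days)
    ]
    return pd.DatetimeIndex(stamps)


@dataclass
class IrregularSeries:
    """Time-stamped observations at strictly increasing, non-uniform times.

    Parameters
    ----------
    times
        Decimal years, strictly increasing.
    values
        Observations ``y_t``; must be finite (gaps are absent instants,
        never placeholders).
    label
        Free-text description of the series.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise OrderingError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise OrderingError(
                f"times ({self.times.size}) and values ({self.values.size}) differ in length"
            )
        if self.times.size and not np.all(np.diff(self.times) > 0):
            k = int(np.argmin(np.diff(self.times)))
            raise OrderingError(
                f"times must be strictly increasing (violation near index {k + 1})"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise OrderingError("times and values must be finite; represent gaps by absence")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dates(self) -> pd.DatetimeIndex:
        return from_decimal_year(self.times)

    @classmethod
    def from_dates(cls, dates, values, label: str = "") -> "IrregularSeries":
        return cls(to_decimal_year(dates), np.asarray(values, dtype=float), label=label)

    @classmethod
    def from_csv(cls, path, date_column: str = None, value_column: str = None,
                 label: str = "") -> "IrregularSeries":
        """Read a two-column CSV (ISO-8601 date, value) with a header row."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise OrderingError(f"{path}: expected at least two columns (date, value)")
        date_column = date_column or df.columns[0]
        value_column = value_column or df.columns[1]
        df = df.dropna(subset=[value_column])
        return cls.from_dates(df[date_column], df[value_column], label=label or str(value_column))

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({
            "date": self.dates.strftime("%Y-%m-%d %H:%M:%S"),
            value_name: self.values,
        })

    def to_csv(self, path, value_name: str = "value") -> None:
        self.to_frame(value_name).to_csv(path, index=False)
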