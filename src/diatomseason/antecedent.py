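"""Antecedent environmental windows.

Benthic diatom assemblages integrate the conditions experienced while the
biofilm colonises (one to three weeks), so each biological sample is
paired with the mean of every sensor variable over a backward window —
21 days by default — ending at, and excluding, the sampling instant.
Sensor gaps are tolerated: the mean is taken over the readings that exist,
a coverage fraction (observed / expected readings at the nominal 15-minute
cadence) is reported, and variables under a minimum coverage are withheld
rather than imputed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, NoDataError, OrderingError

logger = logging.getLogger("diatomseason.antecedent")

#: Nominal sensor cadence: readings per day at 15-minute resolution.
READINGS_PER_DAY = 96

DEFAULT_WINDOW_DAYS = 21.0
DEFAULT_MIN_COVERAGE = 0.5

#: Variables log-transformed before ordination, following common practice
#: for heavy-tailed hydrological drivers.
DEFAULT_LOG_VARS = ("turbidity", "rainfall", "discharge")

#: Units of the canonical sensor variables (metadata only).
CANONICAL_UNITS = {
    "rainfall": "mm",
    "discharge": "m3 s-1",
    "trp": "mg P L-1",
    "nitrate_n": "mg N L-1",
    "water_temperature": "degC",
    "net_radiation": "W m-2",
    "dissolved_oxygen": "%",
    "ph": "pH units",
    "turbidity": "NTU",
    "conductivity": "uS cm-1",
}


@dataclass
class SensorSeries:
    """High-frequency sensor data: DatetimeIndex rows, one column per variable."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df.index)))
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise OrderingError("sensor timestamps must be strictly increasing")
        self.data = df
        if not self.units:
            self.units = {c: CANONICAL_UNITS.get(c, "") for c in df.columns}

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path, units: dict = None) -> "SensorSeries":
        df = pd.read_csv(path)
        df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df[df.columns[0]])))
        return cls(df.drop(columns=df.columns[0]), units=units or {})

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%d %H:%M:%S"))
        out.to_csv(path, index=False)


def antecedent_mean(sensor: SensorSeries, sample_date,
                    window_days: float = DEFAULT_WINDOW_DAYS,
                    min_coverage: float = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Backward-window means for one sample date.

    The window is half-open, ``[sample_date - window_days, sample_date)``,
    so the sampling instant itself is excluded.  Returns a one-row frame
    per variable pair of columns ``(mean, coverage)``; means failing
    ``min_coverage`` are NaN with a logged warning.
    """
    if not (window_days > 0):
        raise DomainError(f"window_days must be positive, got {window_days}")
    ts = pd.Timestamp(sample_date)
    if ts <= sensor.data.index[0]:
        raise NoDataError(f"sample date {ts} precedes the first sensor record")
    lo = ts - pd.Timedelta(days=window_days)
    window = sensor.data.loc[(sensor.data.index >= lo) & (sensor.data.index < ts)]
    expected = window_days * READINGS_PER_DAY
    out = {}
    for var in sensor.variables:
        col = window[var].dropna()
        coverage = min(len(col) / expected, 1.0)
        mean = float(col.mean()) if len(col) else np.nan
        if coverage < min_coverage:
            logger.warning("LOW_COVERAGE %s %s: coverage %.2f < %.2f; mean withheld",
                           ts.date(), var, coverage, min_coverage)
            mean = np.nan
        out[(var, "mean")] = mean
        out[(var, "coverage")] = coverage
    return pd.DataFrame(out, index=[ts])


def log_transform(values, a: float = 1.0, b: float = 1.0):
    """Natural log of ``a*x + b`` (elementwise)."""
    x = np.asarray(values, dtype=float)
    arg = a * x + b
    if np.any(arg <= 0):
        bad = np.asarray(x[arg <= 0]).ravel()[:5]
        raise DomainError(f"log argument non-positive for values {bad.tolist()}")
    out = np.log(arg)
    return float(out) if np.isscalar(values) else out


def build_env_matrix(sensor: SensorSeries, sample_dates,
                     window_days: float = DEFAULT_WINDOW_DAYS,
                     min_coverage: float = DEFAULT_MIN_COVERAGE,
                     log_vars=DEFAULT_LOG_VARS,
                     log_a: float = 1.0, log_b: float = 1.0) -> pd.DataFrame:
    """Samples x variables antecedent-mean matrix aligned to biology dates.

    Log transform (natural log of ``a*x + b``) is applied to the configured
    variables after averaging.  Rows whose every variable fails coverage
    are dropped; if all rows fail, :class:`CoverageError` is raised.
    """
    rows = []
    for date in pd.DatetimeIndex(pd.to_datetime(sample_dates)):
        try:
            row = antecedent_mean(sensor, date, window_days, min_coverage)
        except NoDataError:
            logger.warning("NO_DATA %s: before sensor record; row skipped", date.date())
            continue
        rows.append(row)
    if not rows:
        raise CoverageError("no sample date has any sensor data")
    table = pd.concat(rows)
    means = table.xs("mean", axis=1, level=1)
    means = means.dropna(how="all")
    if means.empty:
        raise CoverageError("every sample failed the coverage threshold")
    means = means.copy()
    for var in log_vars:
        if var in means.columns:
            ok = means[var].notna()
            means.loc[ok, var] = log_transform(means.loc[ok, var].to_numpy(),
                                               log_a, log_b)
    return means
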