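"""Synthetic datasets with the statistical structure the analysis assumes.

Three generators emulate the study design at desk scale, each emitting a
ground-truth sidecar so recovery can be tested:

* :func:`gen_eqr_series` — ~5.5 years of mid-monthly, date-jittered EQR
  observations: slow trend + annual sinusoid whose cos/sin coefficients
  drift as random walks, plus Gaussian observation noise.
* :func:`gen_counts` — 300-valve multinomial assemblages whose composition
  blends a "summer" and a "winter" species pool with a seasonal mixing
  weight, so dominance switches with season.
* :func:`gen_sensor` — 15-minute sensor series: winter-weighted marked
  Poisson rainfall, linear-reservoir discharge, event-driven TRP and
  turbidity, annual+diel temperature and radiation, and seasonal DO, pH
  and conductivity.

Every stochastic draw comes from a named substream of one seeded
generator per dataset, so adding a variable never perturbs existing
draws, and regenerating with the same seed is bit-for-bit reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .antecedent import SensorSeries
from .diatom_metrics import STANDARD_VALVE_TOTAL, CountMatrix, TraitTable
from .errors import SpecificationError
from .series import IrregularSeries, from_decimal_year, to_decimal_year

logger = logging.getLogger("diatomseason.synthetic")

#: Stable substream indices; append only, never reorder.
_SUBSTREAMS = {
    "sample_jitter": 0,
    "amp_walk": 1,
    "obs_noise": 2,
    "counts": 3,
    "rain_occurrence": 4,
    "rain_depth": 5,
    "temperature": 6,
    "radiation": 7,
    "dissolved_oxygen": 8,
    "ph": 9,
    "conductivity": 10,
    "trp": 11,
    "turbidity": 12,
    "nitrate": 13,
}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[name],)))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class _Truth:
    def to_dict(self) -> dict:
        return _jsonable(asdict(self))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# --------------------------------------------------------------------------
# EQR-like irregular series
# --------------------------------------------------------------------------

@dataclass
class EqrTruth(_Truth):
    """Ground truth for a generated EQR series."""

    seed: int
    times: np.ndarray
    trend: np.ndarray
    a: np.ndarray                 # cos coefficient path (annual harmonic)
    b: np.ndarray                 # sin coefficient path
    seasonal: np.ndarray
    noise: np.ndarray
    noise_sd: float
    clipped: np.ndarray           # boolean mask of clipped observations


def sample_schedule(n_years: float, seed: int, start_year: int = 2011,
                    start_month: int = 3, jitter_days: float = 5.0) -> np.ndarray:
    """Mid-monthly sampling instants (decimal years) with uniform date jitter."""
    n_months = int(round(n_years * 12))
    rng = _rng(seed, "sample_jitter")
    stamps = []
    year, month = start_year, start_month
    for _ in range(n_months):
        stamps.append(pd.Timestamp(year, month, 15, 12))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    jitter = rng.uniform(-jitter_days, jitter_days, size=n_months)
    times = to_decimal_year(stamps) + jitter / 365.2425
    return times


def gen_eqr_series(n_years: float = 5.5, seed: int = 1,
                   amp_drift_sd: float = 0.05, noise_frac: float = 0.15,
                   trend_slope: float = 0.0, level: float = 0.7,
                   mean_amplitude: float = 0.2, peak_time: float = 0.5,
                   start_year: int = 2011, start_month: int = 3):
    """Irregular seasonal EQR-like series with drifting amplitude.

    ``y = trend + a_t cos(2 pi t) + b_t sin(2 pi t) + noise`` where the
    coefficient paths are random walks with step standard deviation
    ``amp_drift_sd`` per sqrt-year around an initial amplitude of
    ``mean_amplitude`` peaking at ``peak_time`` (fraction of the year;
    0.5 = early July).  The observation-noise variance is ``noise_frac``
    times the signal variance.  Values are clipped to [0, 1.25] with clip
    events logged.  Returns ``(series, truth)``.
    """
    if n_years < 1:
        raise SpecificationError(f"n_years must be >= 1, got {n_years}")
    if not (0.0 < noise_frac < 1.0):
        raise SpecificationError(f"noise_frac must lie in (0, 1), got {noise_frac}")
    times = sample_schedule(n_years, seed, start_year, start_month)
    n = times.size
    w = 2.0 * np.pi
    rng_amp = _rng(seed, "amp_walk")
    a = np.empty(n); b = np.empty(n)
    a[0] = mean_amplitude * np.cos(w * peak_time)
    b[0] = mean_amplitude * np.sin(w * peak_time)
    dts = np.diff(times)
    steps = rng_amp.normal(size=(n - 1, 2)) * (amp_drift_sd * np.sqrt(dts))[:, None]
    a[1:] = a[0] + np.cumsum(steps[:, 0])
    b[1:] = b[0] + np.cumsum(steps[:, 1])
    trend = level + trend_slope * (times - times[0])
    seasonal = a * np.cos(w * times) + b * np.sin(w * times)
    sig = trend + seasonal
    noise_sd = float(np.sqrt(noise_frac * np.var(sig)))
    noise = _rng(seed, "obs_noise").normal(scale=noise_sd, size=n) if noise_sd > 0 \
        else np.zeros(n)
    y = sig + noise
    clipped = (y < 0.0) | (y > 1.25)
    if clipped.any():
        logger.warning("CLIP %d generated values clipped to [0, 1.25]",
                       int(clipped.sum()))
    y = np.clip(y, 0.0, 1.25)
    series = IrregularSeries(times, y, label=f"synthetic EQR seed={seed}")
    truth = EqrTruth(seed=seed, times=times, trend=trend, a=a, b=b,
                     seasonal=seasonal, noise=noise, noise_sd=noise_sd,
                     clipped=clipped)
    return series, truth


# --------------------------------------------------------------------------
# seasonal count matrices
# --------------------------------------------------------------------------

#: Default summer-state composition: low-nutrient pioneer community
#: dominated by Achnanthidium minutissimum.
SUMMER_POOL = {
    "AMIN": 0.45, "GOLI": 0.10, "MCIR": 0.07, "RABB": 0.08, "EMIN": 0.07,
    "SCRU": 0.05, "GPAR": 0.05, "APED": 0.05, "NLAN": 0.03, "CEUG": 0.02,
    "NCRY": 0.02, "CBAC": 0.01,
}

#: Default winter-state composition: nutrient/flow-tolerant community led
#: by Amphora pediculus and motile taxa.
WINTER_POOL = {
    "APED": 0.35, "NLAN": 0.15, "CEUG": 0.10, "NCRY": 0.08, "CBAC": 0.07,
    "GPAR": 0.08, "AMIN": 0.08, "GOLI": 0.02, "MCIR": 0.02, "RABB": 0.02,
    "EMIN": 0.02, "SCRU": 0.01,
}


@dataclass
class CountTruth(_Truth):
    """Ground truth for a generated count matrix."""

    seed: int
    times: np.ndarray             # decimal years
    summer_weight: np.ndarray     # per-date mixing proportion of the summer pool
    summer_pool: dict
    winter_pool: dict
    peak_time: float
    total_valves: int


def _validate_pool(pool: dict, name: str, traits: TraitTable) -> None:
    p = np.asarray(list(pool.values()), dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise SpecificationError(f"{name} pool must be proportions summing to 1")
    unknown = set(pool) - set(traits.table.index)
    if unknown:
        raise SpecificationError(
            f"{name} pool taxa {sorted(unknown)} absent from the trait table")


def gen_counts(dates, seed: int = 1, total_valves: int = STANDARD_VALVE_TOTAL,
               summer_pool: Optional[dict] = None,
               winter_pool: Optional[dict] = None, peak_time: float = 0.5,
               traits: Optional[TraitTable] = None):
    """Multinomial valve counts blending summer and winter species pools.

    Per date the mixing weight is ``w(t) = (1 + cos(2 pi (t - peak_time))) / 2``
    (1 at the summer peak, 0 mid-winter); expected composition is
    ``w * summer_pool + (1 - w) * winter_pool`` and counts are one
    multinomial draw of ``total_valves``.  ``dates`` may be timestamps or
    decimal years.  Returns ``(CountMatrix, CountTruth)``.
    """
    traits = traits or TraitTable.bundled()
    summer_pool = dict(summer_pool or SUMMER_POOL)
    winter_pool = dict(winter_pool or WINTER_POOL)
    _validate_pool(summer_pool, "summer", traits)
    _validate_pool(winter_pool, "winter", traits)
    if set(summer_pool) != set(winter_pool):
        raise SpecificationError("summer and winter pools must cover the same taxa")
    taxa = sorted(summer_pool)
    ps = np.array([summer_pool[t] for t in taxa])
    pw = np.array([winter_pool[t] for t in taxa])

    arr = np.asarray(dates)
    if np.issubdtype(arr.dtype, np.number):
        times = arr.astype(float)
        stamps = from_decimal_year(times)
    else:
        stamps = pd.DatetimeIndex(pd.to_datetime(dates))
        times = to_decimal_year(stamps)
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * (times - peak_time)))
    rng = _rng(seed, "counts")
    rows = np.empty((times.size, len(taxa)), dtype=int)
    for k in range(times.size):
        p = w[k] * ps + (1.0 - w[k]) * pw
        rows[k] = rng.multinomial(int(total_valves), p)
    counts = CountMatrix(pd.DataFrame(rows, index=stamps, columns=taxa))
    truth = CountTruth(seed=seed, times=times, summer_weight=w,
                       summer_pool=summer_pool, winter_pool=winter_pool,
                       peak_time=peak_time, total_valves=int(total_valves))
    return counts, truth


# --------------------------------------------------------------------------
# 15-minute sensor series
# --------------------------------------------------------------------------

@dataclass
class SensorTruth(_Truth):
    """Ground truth for a generated sensor dataset."""

    seed: int
    n_events: int
    event_times: list             # ISO timestamps of rainfall events
    params: dict


def gen_sensor(start, end, seed: int = 1, rain_rate_per_day: float = 1.2,
               rain_winter_weight: float = 0.6, rain_depth_mm: float = 1.5,
               baseflow: float = 0.15, baseflow_seasonal: float = 0.10,
               reservoir_tau_days: float = 0.6, runoff_coeff: float = 4.0):
    """Event-driven 15-minute sensor series for ``[start, end)``.

    Rainfall is a marked Poisson process whose intensity peaks in winter;
    discharge is seasonal baseflow plus a linear-reservoir convolution of
    rainfall; TRP and turbidity respond to positive discharge increments
    (event-driven transfer); temperature and net radiation carry annual
    and diel cycles (radiation truncated at zero); DO, pH and conductivity
    are seasonal sinusoids with noise.  Returns ``(SensorSeries, truth)``.
    """
    idx = pd.date_range(start=start, end=end, freq="15min", inclusive="left")
    if len(idx) == 0:
        raise SpecificationError("end must be after start")
    t = to_decimal_year(idx)                    # decimal years
    hod = idx.hour + idx.minute / 60.0          # hour of day
    dt_days = 15.0 / (60.0 * 24.0)
    ann = lambda phase: np.cos(2.0 * np.pi * (t - phase))

    # rainfall: winter-weighted marked Poisson events
    lam = rain_rate_per_day * np.clip(1.0 + rain_winter_weight * ann(0.04), 0.0, None)
    occ = _rng(seed, "rain_occurrence").random(len(idx)) < lam * dt_days
    depth = _rng(seed, "rain_depth").exponential(rain_depth_mm, size=len(idx))
    rainfall = np.where(occ, depth, 0.0)

    # discharge: seasonal baseflow + storm runoff from a two-reservoir
    # cascade (humped unit hydrograph with a rising limb; kernel mass 1,
    # so runoff_coeff is storm volume per mm of rain in m3 s-1 steps)
    alpha = float(np.exp(-dt_days / reservoir_tau_days))
    lagged = np.concatenate([[0.0], rainfall[:-1]])
    one = _signal.lfilter([1.0 - alpha], [1.0, -alpha], lagged)
    storm = runoff_coeff * _signal.lfilter([1.0 - alpha], [1.0, -alpha], one)
    base = baseflow + baseflow_seasonal * ann(0.04)
    discharge = base + storm

    # event-driven nutrient / sediment transfer
    dq = np.clip(np.diff(discharge, prepend=discharge[0]), 0.0, None)
    trp = 0.015 + 15.0 * dq + np.abs(_rng(seed, "trp").normal(0.0, 0.002, len(idx)))
    turbidity = np.clip(
        1.5 + 8000.0 * dq + _rng(seed, "turbidity").normal(0.0, 0.4, len(idx)), 0.0, None)

    diel = np.sin(2.0 * np.pi * (hod - 9.0) / 24.0)
    temperature = (9.0 + 5.0 * ann(0.55) + 1.2 * diel
                   + _rng(seed, "temperature").normal(0.0, 0.3, len(idx)))
    daylight = np.clip(np.sin(np.pi * (hod - 6.0) / 12.0), 0.0, None)
    ann_rad = 90.0 + 110.0 * ann(0.54)
    radiation = np.clip(ann_rad * daylight
                        + _rng(seed, "radiation").normal(0.0, 10.0, len(idx)), 0.0, None)
    do = 100.0 + 8.0 * ann(0.04) + _rng(seed, "dissolved_oxygen").normal(0.0, 2.0, len(idx))
    ph = 7.8 + 0.15 * ann(0.5) + _rng(seed, "ph").normal(0.0, 0.05, len(idx))
    conductivity = (250.0 + 50.0 * ann(0.62)
                    + _rng(seed, "conductivity").normal(0.0, 5.0, len(idx)))

    data = pd.DataFrame({
        "rainfall": rainfall,
        "discharge": discharge,
        "trp": trp,
        "nitrate_n": 1.8 + 0.6 * ann(0.04)
                     + _rng(seed, "nitrate").normal(0.0, 0.05, len(idx)),
        "water_temperature": temperature,
        "net_radiation": radiation,
        "dissolved_oxygen": do,
        "ph": ph,
        "turbidity": turbidity,
        "conductivity": conductivity,
    }, index=idx)
    sensor = SensorSeries(data)
    truth = SensorTruth(
        seed=seed, n_events=int(occ.sum()),
        event_times=[ts.isoformat() for ts in idx[occ][:2000]],
        params={
            "rain_rate_per_day": rain_rate_per_day,
            "rain_winter_weight": rain_winter_weight,
            "rain_depth_mm": rain_depth_mm,
            "baseflow": baseflow,
            "baseflow_seasonal": baseflow_seasonal,
            "reservoir_tau_days": reservoir_tau_days,
            "runoff_coeff": runoff_coeff,
        })
    return sensor, truth
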