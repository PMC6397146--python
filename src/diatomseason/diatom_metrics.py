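"""Diatom count matrices, weighted-average quality index, EQR and status.

The index engine is the generic trophic-index form: the weighted mean
sensitivity of a sample is

    WMS = sum_j a_j s_j v_j / sum_j a_j v_j

over trait-covered taxa, where ``a_j`` is relative abundance, ``s_j`` a
nutrient-sensitivity score in [1, 5] (higher = more nutrient tolerant) and
``v_j`` an indicator-reliability weight in [1, 3].  WMS maps to a 0-100
index, the index to an Ecological Quality Ratio against a reference
expectation, and the EQR to the Water Framework Directive status bands
(high/good/moderate/poor/bad at 0.8/0.6/0.4/0.2, ties upward).

The bundled trait table (``data/synthetic_traits.csv``) is a synthetic,
invented score set covering the common riffle taxa used throughout the
package; it is NOT the official DARLEQ coefficient set, which is not
redistributed here.  Any user table with the same columns can be loaded
from CSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    DomainError,
    EmptySampleError,
    NoIndexError,
    SpecificationError,
    TaxonLookupError,
)
from .series import IrregularSeries, to_decimal_year

logger = logging.getLogger("diatomseason.diatom_metrics")

#: Convention for a full count: valves identified per sample.
STANDARD_VALVE_TOTAL = 300

#: Status boundaries, upper class owns the boundary value.
STATUS_BOUNDARIES = (("high", 0.8), ("good", 0.6), ("moderate", 0.4), ("poor", 0.2))

#: EQR values above this are capped (and flagged); > 1 means better than reference.
EQR_CAP = 1.25

GUILDS = {"low_profile", "high_profile", "motile", "planktic", "unknown"}


@dataclass
class CountMatrix:
    """Valve counts, samples x taxa.  ``counts.index`` are sample timestamps."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if not isinstance(df.index, pd.DatetimeIndex):
            df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df.index)))
        vals = df.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise SpecificationError("counts must be non-negative integers")
        totals = vals.sum(axis=1)
        if np.any(totals <= 0):
            bad = df.index[totals <= 0][0]
            raise EmptySampleError(f"sample {bad.date()} has zero total valves")
        off = df.index[totals != STANDARD_VALVE_TOTAL]
        if len(off):
            logger.info("VALVE_TOTAL %d samples deviate from the %d-valve convention",
                        len(off), STANDARD_VALVE_TOTAL)
        self.counts = df.astype(int)

    @property
    def sample_dates(self) -> pd.DatetimeIndex:
        return self.counts.index

    @property
    def taxon_codes(self) -> list:
        return list(self.counts.columns)

    @classmethod
    def from_csv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path)
        df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df[df.columns[0]])))
        return cls(df.drop(columns=df.columns[0]))

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


@dataclass
class TraitTable:
    """Per-taxon sensitivity (1-5), indicator weight (1-3) and growth guild."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        required = {"sensitivity", "indicator_weight"}
        if not required.issubset(df.columns):
            raise SpecificationError(f"trait table needs columns {sorted(required)}")
        if df.index.has_duplicates:
            raise SpecificationError("taxon codes must be unique")
        if "guild" not in df.columns:
            df = df.assign(guild="unknown")
        bad_guild = set(df["guild"]) - GUILDS
        if bad_guild:
            raise SpecificationError(f"unknown guilds {sorted(bad_guild)}")
        s, v = df["sensitivity"], df["indicator_weight"]
        if not ((s >= 1) & (s <= 5)).all():
            raise SpecificationError("sensitivity scores must lie in [1, 5]")
        if not ((v >= 1) & (v <= 3)).all():
            raise SpecificationError("indicator weights must lie in [1, 3]")
        self.table = df

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        df = pd.read_csv(path).set_index("taxon")
        return cls(df)

    @classmethod
    def bundled(cls) -> "TraitTable":
        """The synthetic illustrative trait table shipped with the package."""
        with resources.files("diatomseason.data").joinpath(
                "synthetic_traits.csv").open() as fh:
            return cls(pd.read_csv(fh).set_index("taxon"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="taxon")


def relative_abundance(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample proportions; every row sums to one."""
    df = counts.counts
    totals = df.sum(axis=1)
    return df.div(totals, axis=0)


def dominance_ratio(counts: CountMatrix, taxon_a: str, taxon_b: str) -> pd.Series:
    """Per-sample count ratio a/b; NaN (flagged) where taxon_b is absent."""
    for tx in (taxon_a, taxon_b):
        if tx not in counts.counts.columns:
            raise TaxonLookupError(f"taxon {tx!r} not in count matrix")
    a = counts.counts[taxon_a].astype(float)
    b = counts.counts[taxon_b].astype(float)
    ratio = a / b.replace(0, np.nan)
    undef = ratio.index[b == 0]
    for d in undef:
        logger.warning("RATIO_UNDEFINED %s %s/%s: denominator count is zero",
                       d.date(), taxon_a, taxon_b)
    ratio.name = f"{taxon_a}/{taxon_b}"
    return ratio


def weighted_mean_sensitivity(proportions: pd.Series, traits: TraitTable):
    """WMS of one sample; returns ``(wms, coverage_fraction)``.

    Coverage is the proportion of counted material belonging to taxa with
    trait entries; taxa without traits are excluded from the average.
    """
    present = proportions[proportions > 0]
    covered = present.index.intersection(traits.table.index)
    coverage = float(present[covered].sum() / present.sum()) if present.sum() else 0.0
    if len(covered) == 0:
        raise NoIndexError("no counted taxon has trait coverage")
    a = present[covered].to_numpy(dtype=float)
    s = traits.table.loc[covered, "sensitivity"].to_numpy(dtype=float)
    v = traits.table.loc[covered, "indicator_weight"].to_numpy(dtype=float)
    wms = float(np.sum(a * s * v) / np.sum(a * v))
    return wms, coverage


def index_from_wms(wms: float) -> float:
    """Map WMS in [1, 5] onto the 0-100 index scale: (WMS - 1) * 25."""
    return (wms - 1.0) * 25.0


def eqr(observed_index: float, expected_index: float):
    """EQR = (100 - observed) / (100 - expected); higher = cleaner.

    Values above :data:`EQR_CAP` are capped with a logged flag; returns
    ``(eqr_value, capped_flag)``.
    """
    if not (0.0 <= observed_index <= 100.0) or not (0.0 <= expected_index <= 100.0):
        raise DomainError("indices must lie in [0, 100]")
    if expected_index >= 100.0:
        raise DegenerateReferenceError("expected index of 100 leaves EQR undefined")
    value = (100.0 - observed_index) / (100.0 - expected_index)
    capped = value > EQR_CAP
    if capped:
        logger.warning("EQR_CAP value %.3f capped at %.2f", value, EQR_CAP)
        value = EQR_CAP
    return value, bool(capped)


def classify_status(eqr_value: float) -> str:
    """WFD status band; the boundary value belongs to the upper class."""
    if eqr_value < 0:
        raise DomainError(f"EQR must be non-negative, got {eqr_value}")
    for name, bound in STATUS_BOUNDARIES:
        if eqr_value >= bound:
            return name
    return "bad"


def eqr_series(counts: CountMatrix, traits: TraitTable, expected_index: float,
               min_coverage: float = 0.0):
    """Chain counts -> WMS -> index -> EQR -> status for every sample.

    Returns ``(results, series)`` where ``results`` is a per-sample
    DataFrame (wms, index, eqr, capped, status, trait_coverage) and
    ``series`` an :class:`IrregularSeries` of EQR values ready for the
    seasonal decomposition.  Samples that fail (zero trait coverage, or
    coverage below ``min_coverage``) are logged and excluded, never
    imputed.
    """
    props = relative_abundance(counts)
    rows = {}
    for date, prop in props.iterrows():
        try:
            wms, cov = weighted_mean_sensitivity(prop, traits)
        except NoIndexError:
            logger.warning("NO_INDEX %s: no trait coverage; sample excluded",
                           date.date())
            continue
        if cov < min_coverage:
            logger.warning("LOW_TRAIT_COVERAGE %s: coverage %.2f < %.2f; excluded",
                           date.date(), cov, min_coverage)
            continue
        idx = index_from_wms(wms)
        value, capped = eqr(idx, expected_index)
        rows[date] = {
            "wms": wms, "index": idx, "eqr": value, "capped": capped,
            "status": classify_status(value), "trait_coverage": cov,
            "expected_index": expected_index,
        }
    results = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if results.empty:
        raise NoIndexError("every sample failed index computation")
    series = IrregularSeries(to_decimal_year(results.index),
                             results["eqr"].to_numpy(), label="EQR")
    return results, series
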