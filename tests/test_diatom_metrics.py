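"""Count-matrix handling, weighted index, EQR and WFD status banding."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from diatomseason import (
    CountMatrix,
    TraitTable,
    classify_status,
    dominance_ratio,
    eqr,
    eqr_series,
    gen_counts,
    index_from_wms,
    relative_abundance,
    sample_schedule,
    weighted_mean_sensitivity,
)
from diatomseason.errors import (
    DegenerateReferenceError,
    DomainError,
    EmptySampleError,
    NoIndexError,
    TaxonLookupError,
)


def _cm(rows, taxa, dates=None):
    dates = dates or pd.date_range("2012-01-15", periods=len(rows), freq="MS")
    return CountMatrix(pd.DataFrame(rows, index=pd.DatetimeIndex(dates),
                                    columns=taxa))


def test_relative_abundance_rows_sum_to_one(rng):
    counts = _cm(rng.integers(0, 40, size=(6, 5)) + 1, list("ABCDE"))
    props = relative_abundance(counts)
    np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)
    single = _cm([[300]], ["A"])
    assert relative_abundance(single).iloc[0, 0] == 1.0
    np.testing.assert_allclose(
        relative_abundance(_cm([[150, 150]], ["A", "B"])).iloc[0], [0.5, 0.5])


def test_zero_total_sample_rejected():
    with pytest.raises(EmptySampleError, match="2012"):
        _cm([[0, 0]], ["A", "B"])


def test_dominance_ratio_values_and_flags(caplog):
    counts = _cm([[100, 100], [210, 30], [50, 0]], ["AMIN", "APED"])
    with caplog.at_level("WARNING"):
        ratio = dominance_ratio(counts, "AMIN", "APED")
    np.testing.assert_allclose(ratio.iloc[:2], [1.0, 7.0])
    assert np.isnan(ratio.iloc[2])
    assert any("RATIO_UNDEFINED" in r.message for r in caplog.records)
    with pytest.raises(TaxonLookupError):
        dominance_ratio(counts, "AMIN", "XXXX")


def test_dominance_ratio_tracks_summer_state(traits):
    times = sample_schedule(3.0, seed=7)
    counts, truth = gen_counts(times, seed=7)
    ratio = dominance_ratio(counts, "AMIN", "APED").to_numpy()
    ok = np.isfinite(ratio)
    rho = pd.Series(ratio[ok]).corr(pd.Series(truth.summer_weight[ok]),
                                    method="spearman")
    assert rho > 0


def test_wms_examples(traits):
    one = pd.Series({"X": 1.0})
    tt = TraitTable(pd.DataFrame({"sensitivity": [3.0], "indicator_weight": [2.0]},
                                 index=pd.Index(["X"], name="taxon")))
    assert weighted_mean_sensitivity(one, tt)[0] == pytest.approx(3.0)
    two = pd.Series({"X": 0.5, "Y": 0.5})
    tt2 = TraitTable(pd.DataFrame({"sensitivity": [1.0, 5.0],
                                   "indicator_weight": [2.0, 2.0]},
                                  index=pd.Index(["X", "Y"], name="taxon")))
    assert weighted_mean_sensitivity(two, tt2)[0] == pytest.approx(3.0)


def test_wms_matches_hand_summation(traits):
    """Five-taxon sample against an explicit sum over the bundled table."""
    prop = pd.Series({"AMIN": 0.4, "APED": 0.2, "GPAR": 0.1, "NLAN": 0.2,
                      "CEUG": 0.1})
    tbl = traits.table
    num = sum(prop[c] * tbl.loc[c, "sensitivity"] * tbl.loc[c, "indicator_weight"]
              for c in prop.index)
    den = sum(prop[c] * tbl.loc[c, "indicator_weight"] for c in prop.index)
    wms, cov = weighted_mean_sensitivity(prop, traits)
    assert wms == pytest.approx(num / den, rel=1e-12)
    assert cov == pytest.approx(1.0)


def test_wms_needs_trait_coverage(traits):
    with pytest.raises(NoIndexError):
        weighted_mean_sensitivity(pd.Series({"ZZZZ": 1.0}), traits)


@given(st.lists(st.tuples(st.floats(0.01, 1.0), st.floats(1.0, 5.0),
                          st.floats(1.0, 3.0)), min_size=1, max_size=8))
def test_wms_bounded_by_present_scores(entries):
    """A weighted mean can never leave the range of its inputs."""
    props = pd.Series({f"T{i}": a for i, (a, _, _) in enumerate(entries)})
    tt = TraitTable(pd.DataFrame(
        {"sensitivity": [s for _, s, _ in entries],
         "indicator_weight": [v for _, _, v in entries]},
        index=pd.Index([f"T{i}" for i in range(len(entries))], name="taxon")))
    wms, _ = weighted_mean_sensitivity(props / props.sum(), tt)
    scores = [s for _, s, _ in entries]
    assert min(scores) - 1e-9 <= wms <= max(scores) + 1e-9


@pytest.mark.parametrize("wms,expected", [(1.0, 0.0), (3.0, 50.0), (5.0, 100.0)])
def test_index_scale(wms, expected):
    assert index_from_wms(wms) == pytest.approx(expected)


def test_eqr_arithmetic_and_cap(caplog):
    assert eqr(20.0, 20.0)[0] == pytest.approx(1.0)
    assert eqr(100.0, 20.0)[0] == pytest.approx(0.0)
    assert eqr(60.0, 20.0)[0] == pytest.approx(0.5)
    with caplog.at_level("WARNING"):
        value, capped = eqr(0.0, 30.0)          # raw ratio 100/70 = 1.43
    assert capped and value == pytest.approx(1.25)
    assert any("EQR_CAP" in r.message for r in caplog.records)
    with pytest.raises(DegenerateReferenceError):
        eqr(50.0, 100.0)


@pytest.mark.parametrize("value,band", [
    (0.85, "high"), (0.8, "high"), (0.6, "good"), (0.79, "good"),
    (0.4, "moderate"), (0.2, "poor"), (0.05, "bad"), (0.0, "bad"),
    (1.25, "high"),
])
def test_status_boundaries_with_upward_ties(value, band):
    assert classify_status(value) == band


def test_negative_eqr_rejected():
    with pytest.raises(DomainError):
        classify_status(-0.01)


def test_eqr_series_extremes():
    clean = TraitTable(pd.DataFrame({"sensitivity": [1.0, 1.0],
                                     "indicator_weight": [2.0, 1.0]},
                                    index=pd.Index(["A", "B"], name="taxon")))
    counts = _cm([[200, 100], [150, 150]], ["A", "B"])
    results, series = eqr_series(counts, clean, expected_index=25.0)
    assert (results["status"] == "high").all()
    assert (results["eqr"] == 1.25).all() and results["capped"].all()
    dirty = TraitTable(pd.DataFrame({"sensitivity": [5.0, 5.0],
                                     "indicator_weight": [2.0, 1.0]},
                                    index=pd.Index(["A", "B"], name="taxon")))
    results, _ = eqr_series(counts, dirty, expected_index=25.0)
    assert (results["eqr"] == 0.0).all()
    assert (results["status"] == "bad").all()


def test_summer_months_cleaner_than_winter(traits):
    """Seasonal pool switching shows up as a summer-winter EQR contrast."""
    diffs = []
    for seed in range(1, 21):
        times = sample_schedule(2.0, seed=seed)
        counts, truth = gen_counts(times, seed=seed)
        results, series = eqr_series(counts, traits, expected_index=25.0)
        month = results.index.month
        summer = results.loc[np.isin(month, [6, 7, 8]), "eqr"].mean()
        winter = results.loc[np.isin(month, [12, 1, 2]), "eqr"].mean()
        diffs.append(summer - winter)
    assert np.mean(diffs) > 0
    assert np.all(np.asarray(diffs) > 0)


def test_column_permutation_and_count_doubling_invariance(traits):
    times = sample_schedule(1.0, seed=2)
    counts, _ = gen_counts(times, seed=2)
    base, _ = eqr_series(counts, traits, 25.0)
    shuffled = CountMatrix(counts.counts[list(reversed(counts.taxon_codes))])
    perm, _ = eqr_series(shuffled, traits, 25.0)
    np.testing.assert_allclose(perm["eqr"], base["eqr"], rtol=1e-12)
    doubled = CountMatrix(counts.counts * 2)
    dbl, _ = eqr_series(doubled, traits, 25.0)
    np.testing.assert_allclose(dbl["eqr"], base["eqr"], rtol=1e-12)
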