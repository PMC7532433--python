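"""CA-HR correlation, validity verdicts, binning, regression, group comparison."""

import numpy as np
import pandas as pd
import pytest

from phenochill import cahr_validity as cv
from phenochill.accumulation import ca_column, hr_column

VALID_SET = {"C1", "C2", "C4", "C5", "C12"}


def _toy_table(ca, hr, station="S0", species="sp", start_year=2000, lat=50.0):
    n = len(ca)
    return pd.DataFrame(
        {
            "station_id": station,
            "species": species,
            "bbch": 11,
            "year": np.arange(start_year, start_year + n),
            "onset_doy": 100,
            "lat": lat,
            "lon": 10.0,
            "alt": 100.0,
            ca_column("C1"): np.asarray(ca, dtype=float),
            hr_column("F1"): np.asarray(hr, dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# pearson test
# ---------------------------------------------------------------------------

def test_pearson_perfect_correlations():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r, p = cv.pearson_test(x, 2 * x)
    assert r == pytest.approx(1.0)
    r, _ = cv.pearson_test(x, -x + 10.0)
    assert r == pytest.approx(-1.0)


def test_pearson_hand_computed_value():
    r, p = cv.pearson_test([1, 2, 3, 4], [2, 1, 4, 3])
    assert r == pytest.approx(0.6)
    assert 0 < p < 1


def test_pearson_degenerate_inputs_raise():
    with pytest.raises(cv.UndefinedCorrelationError):
        cv.pearson_test([1, 2], [3, 4])
    with pytest.raises(cv.UndefinedCorrelationError):
        cv.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# validity classification
# ---------------------------------------------------------------------------

def test_negative_mechanism_is_classified_valid():
    rng = np.random.default_rng(0)
    ca = rng.uniform(50, 150, 200)
    hr = 600 - 0.5 * ca + rng.normal(0, 5, 200)
    verdict = cv.classify_model_validity(_toy_table(ca, hr), "C1")
    assert verdict.verdict == "valid"
    assert verdict.r < 0 and verdict.p < 0.05


def test_unrelated_hr_is_classified_invalid():
    rng = np.random.default_rng(1)
    ca = rng.uniform(50, 150, 1000)
    hr = rng.normal(400, 30, 1000)
    verdict = cv.classify_model_validity(_toy_table(ca, hr), "C1")
    assert verdict.verdict == "invalid"


def test_valid_mechanism_scenario_separates_c1_from_c3(valid_mechanism_table):
    v1 = cv.classify_model_validity(valid_mechanism_table, "C1")
    v3 = cv.classify_model_validity(valid_mechanism_table, "C3")
    assert v1.verdict == "valid"
    assert v3.verdict == "invalid"


def test_verdicts_invariant_to_order_and_hr_unit_rescaling(small_mechanism_table):
    base = cv.validity_table(small_mechanism_table)
    shuffled = small_mechanism_table.sample(frac=1.0, random_state=4)
    rescaled = shuffled.copy()
    rescaled[hr_column("F1")] = 1.8 * rescaled[hr_column("F1")] + 32.0
    again = cv.validity_table(rescaled)
    assert list(base["verdict"]) == list(again["verdict"])
    np.testing.assert_allclose(base["r"], again["r"], atol=1e-12)


def test_valid_model_set_is_robust_to_forcing_model_choice(valid_mechanism_table):
    """The chilling-model partition does not depend on which forcing model
    defines the heat requirement, among forcing models that register winter
    heat at the generator's ~0 degC winter plateau (thresholds at 0 degC on
    their input). High-threshold measures (F2, F7, F8) record no winter heat
    in this synthetic climate and are uninformative for the partition — a
    documented divergence from real maritime winters (see docs/methods.md)."""
    for forcing in ("F1", "F3", "F4", "F5", "F6"):
        table = cv.validity_table(valid_mechanism_table, forcing_model=forcing)
        valid = set(table.loc[table["verdict"] == "valid", "chilling_model"])
        assert valid == VALID_SET, forcing
        fracs = {
            cm: cv.station_level_fraction(valid_mechanism_table, cm, forcing).fraction
            for cm in table["chilling_model"]
        }
        # station-level separation: every valid model beats every invalid one
        assert min(fracs[c] for c in VALID_SET) > max(
            fracs[c] for c in fracs if c not in VALID_SET
        ), forcing


# ---------------------------------------------------------------------------
# station-level analysis
# ---------------------------------------------------------------------------

def test_station_fraction_empty_when_no_long_records():
    table = _toy_table(np.arange(10.0), np.arange(10.0))
    res = cv.station_level_fraction(table, "C1", min_years=15)
    assert res.empty
    assert np.isnan(res.fraction)
    assert res.stations == ()


def test_station_fraction_one_when_all_stations_share_exact_negative_line():
    rng = np.random.default_rng(2)
    frames = []
    for s in range(4):
        ca = rng.uniform(50, 150, 20)
        frames.append(_toy_table(ca, 500 - 2 * ca, station=f"S{s}"))
    res = cv.station_level_fraction(pd.concat(frames, ignore_index=True), "C1")
    assert res.fraction == 1.0
    assert len(res.stations) == 4


def test_station_fractions_rank_c1_above_c8(valid_mechanism_table):
    f1 = cv.station_level_fraction(valid_mechanism_table, "C1")
    f8 = cv.station_level_fraction(valid_mechanism_table, "C8")
    assert not f1.empty
    assert f1.fraction > f8.fraction


# ---------------------------------------------------------------------------
# equal-count binning
# ---------------------------------------------------------------------------

def test_even_binning_gives_equal_group_sizes():
    rng = np.random.default_rng(3)
    table = _toy_table(rng.uniform(0, 100, 40), rng.uniform(0, 100, 40))
    groups = cv.bin_equal_count(table, "C1")
    assert len(groups) == 20
    assert (groups["n"] == 2).all()


def test_remainder_groups_sit_at_the_low_ca_end():
    rng = np.random.default_rng(4)
    table = _toy_table(rng.uniform(0, 100, 45), rng.uniform(0, 100, 45))
    groups = cv.bin_equal_count(table, "C1")
    assert list(groups["n"]) == [3] * 5 + [2] * 15
    assert groups["ca_mean"].is_monotonic_increasing
    assert groups["n"].sum() == 45


def test_binning_deterministic_under_ca_ties():
    table = _toy_table(np.full(40, 10.0), np.arange(40.0))
    g1 = cv.bin_equal_count(table, "C1")
    g2 = cv.bin_equal_count(table.sample(frac=1.0, random_state=9), "C1")
    pd.testing.assert_frame_equal(g1, g2)
    assert (g1["n"] == 2).all()


def test_binning_requires_enough_records():
    table = _toy_table(np.arange(10.0), np.arange(10.0))
    with pytest.raises(ValueError):
        cv.bin_equal_count(table, "C1", k=20)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def test_exact_line_fit_has_zero_width_intervals():
    ca = np.linspace(50, 150, 30)
    fit = cv.fit_ca_hr_regression(ca, 500 - 2 * ca)
    assert fit.a == pytest.approx(500.0)
    assert fit.b == pytest.approx(-2.0)
    assert fit.ci95_a[1] - fit.ci95_a[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.ci95_b[1] - fit.ci95_b[0] == pytest.approx(0.0, abs=1e-10)


def test_constant_ca_is_a_degenerate_design():
    with pytest.raises(cv.DegenerateDesignError):
        cv.fit_ca_hr_regression(np.full(10, 7.0), np.arange(10.0))


def test_confidence_intervals_cover_the_generating_parameters():
    rng = np.random.default_rng(0)
    hits_a = hits_b = 0
    for _ in range(100):
        ca = rng.uniform(80, 170, 500)
        hr = 500 - 2 * ca + rng.normal(0, 20, 500)
        fit = cv.fit_ca_hr_regression(ca, hr)
        hits_a += fit.ci95_a[0] <= 500 <= fit.ci95_a[1]
        hits_b += fit.ci95_b[0] <= -2 <= fit.ci95_b[1]
    assert hits_a >= 93
    assert hits_b >= 93


# ---------------------------------------------------------------------------
# group comparison (latitude split)
# ---------------------------------------------------------------------------

def test_identical_mechanisms_rarely_differ_significantly():
    rng = np.random.default_rng(6)
    significant = 0
    for _ in range(100):
        ca = rng.uniform(50, 150, 300)
        hr = 500 - 2 * ca + rng.normal(0, 20, 300)
        table = _toy_table(ca, hr)
        table["lat"] = np.where(np.arange(300) < 150, 48.0, 52.0)
        res = cv.group_compare(table, lambda t: t["lat"] < 50.65, "C1")
        significant += res.p_slope_diff < 0.05
    assert significant <= 10


def test_distinct_slopes_are_detected():
    rng = np.random.default_rng(7)
    ca = rng.uniform(50, 150, 1000)
    south = np.arange(1000) < 500
    hr = np.where(south, 500 - 2 * ca, 700 - 4 * ca) + rng.normal(0, 10, 1000)
    table = _toy_table(ca, hr)
    table["lat"] = np.where(south, 48.0, 52.0)
    res = cv.group_compare(table, lambda t: t["lat"] < 50.65, "C1")
    assert res.p_slope_diff < 1e-6
    assert res.slope_diff == pytest.approx(2.0, abs=0.3)


def test_empty_group_is_an_explicit_error():
    table = _toy_table(np.arange(10.0), np.arange(10.0))
    with pytest.raises(ValueError, match="nonempty"):
        cv.group_compare(table, lambda t: t["lat"] < 0.0, "C1")
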