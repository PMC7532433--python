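"""Shared fixtures: the valid-mechanism synthetic study and small helpers."""

import numpy as np
import pandas as pd
import pytest

from phenochill import accumulation as acc
from phenochill import synthetic_data as sd
from phenochill.rate_models import FORCING_IDS


@pytest.fixture(scope="session")
def valid_mechanism_data():
    """Full valid-mechanism study: 100 locations x 60 years, seed 42.

    Onsets are generated by HR = 600 - 2*CA(C1) plus 2-day observation
    noise on a warming Central-European-like climate.
    """
    scenario, mech = sd.valid_mechanism_scenario(seed=42)
    series = sd.generate_temperature(scenario)
    records, n_dropped = sd.generate_phenology(series, mech)
    return scenario, mech, series, records, n_dropped


@pytest.fixture(scope="session")
def valid_mechanism_table(valid_mechanism_data):
    """CAHR table of the valid-mechanism study, HR under all 8 forcing models."""
    _, _, series, records, _ = valid_mechanism_data
    series_by_station = {s.location_id: s for s in series}
    table, n_dropped = acc.build_cahr_table(
        records, series_by_station, forcing_ids=FORCING_IDS
    )
    assert n_dropped == 0
    return table


@pytest.fixture(scope="session")
def small_mechanism_table():
    """A fast, small variant of the valid-mechanism study (12 locations x 25 years)."""
    scenario, mech = sd.valid_mechanism_scenario(seed=5, n_locations=12, n_years=25)
    series = sd.generate_temperature(scenario)
    records, _ = sd.generate_phenology(series, mech)
    table, _ = acc.build_cahr_table(records, {s.location_id: s for s in series})
    return table


@pytest.fixture()
def constant_series():
    """Two-year daily series at a constant 3 degC with max/min = +-5."""
    dates = pd.date_range("2000-07-01", "2001-12-31", freq="D")
    t = np.full(len(dates), 3.0)
    return acc.DailySeries("const3", 50.0, 10.0, 200.0, dates, t, t + 5.0, t - 5.0)
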