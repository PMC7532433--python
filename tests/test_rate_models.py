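"""Unit and property tests for the chilling/forcing rate functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenochill import rate_models as rm

TEMPS = st.floats(min_value=-40.0, max_value=45.0, allow_nan=False)


# ---------------------------------------------------------------------------
# printed piecewise values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model_id, t, expected",
    [
        ("C1", 3.0, 1.0),
        ("C1", 5.0, 1.0),  # boundary is inclusive as printed
        ("C1", 5.01, 0.0),
        ("C2", -10.0, 1.0),
        ("C2", -10.5, 0.0),
        ("C3", -0.5, 0.0),
        ("C4", 7.0, 1.0),
        ("C5", -4.0, 1.0),
        ("C6", 6.0, 1.0),
        ("C7", 10.0, 0.5),
        ("C7", 18.0, -0.5),
        ("C7", 20.0, -1.0),
        ("C7", 1.0, 0.0),
        ("C8", 20.0, 0.0),
        ("C8", 5.0, 1.0),
        ("C10", 5.0, 1.0),  # plateau
        ("C10", -10.0, 0.0),
        ("C11", 0.0, 0.40476),
        ("C11", 5.0, 1.0),
        ("C12", 3.0, 0.58209),
        ("C12", 0.2, 1.0),
        ("C12", 6.9, 0.0),
        ("C12", -6.5, 0.0),
    ],
)
def test_chilling_rate_piecewise_values(model_id, t, expected):
    assert rm.chilling_rate(model_id, t) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize(
    "model_id, kwargs, expected",
    [
        ("F1", {"t_mean": 10.0}, 10.0),
        ("F1", {"t_mean": -3.0}, 0.0),
        ("F2", {"t_mean": 7.0}, 2.0),
        ("F2", {"t_mean": 5.0}, 0.0),
        ("F3", {"t_max": -1.0}, 0.0),
        ("F3", {"t_max": 12.0}, 12.0),
        ("F4", {"t_max": 12.0}, 7.0),
        ("F5", {"t_max": 15.0, "t_min": 3.0}, 7.5),
        ("F5", {"t_max": 15.0, "t_min": 9.0}, 8.5),
        ("F6", {"t_mean": 18.5}, 14.2),
        ("F6", {"t_mean": -2.0}, 0.0),
        ("F8", {"t_mean": 25.0}, 21.0),
        ("F8", {"t_mean": 4.0}, 0.0),
        ("F8", {"t_mean": 36.0}, 0.0),
        ("F8", {"t_mean": 40.0}, 0.0),
    ],
)
def test_forcing_rate_piecewise_values(model_id, kwargs, expected):
    assert rm.forcing_rate(model_id, **kwargs) == pytest.approx(expected, abs=1e-9)


def test_f6_asymptote_is_its_printed_numerator():
    assert rm.forcing_rate("F6", t_mean=100.0) == pytest.approx(28.4, abs=1e-3)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def test_registry_lists_all_twenty_models_once():
    specs = rm.list_models()
    assert len(specs) == 20
    assert [s.model_id for s in specs] == list(rm.CHILLING_IDS + rm.FORCING_IDS)
    assert sum(s.stateful for s in specs) == 1
    assert next(s for s in specs if s.stateful).model_id == "C9"


def test_required_inputs_follow_model_definitions():
    for spec in rm.list_models():
        if spec.model_id in ("F3", "F4"):
            assert spec.required_inputs == {"t_max"}
        elif spec.model_id == "F5":
            assert spec.required_inputs == {"t_max", "t_min"}
        else:
            assert spec.required_inputs == {"t_mean"}


def test_model_table_is_machine_readable():
    table = rm.model_table()
    assert list(table["model_id"]) == list(rm.CHILLING_IDS + rm.FORCING_IDS)
    assert set(table["kind"]) == {"chilling", "forcing"}


def test_registry_errors():
    with pytest.raises(rm.UnknownModelError):
        rm.chilling_rate("C13", 0.0)
    with pytest.raises(rm.StatefulModelError):
        rm.chilling_rate("C9", 0.0)
    with pytest.raises(rm.MissingInputError):
        rm.forcing_rate("F5", t_max=10.0)
    with pytest.raises(rm.UnknownModelError):
        rm.forcing_rate("C1", t_mean=3.0)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=200)
@given(t=TEMPS)
def test_stateless_rates_are_pure_finite_and_in_range(t):
    for model_id in rm.CHILLING_IDS:
        if model_id == "C9":
            continue
        lo = -1.0 if model_id == "C7" else 0.0
        first = rm.chilling_rate(model_id, t)
        assert lo <= first <= 1.0
        assert first == rm.chilling_rate(model_id, t)
    for model_id in rm.FORCING_IDS:
        spec = rm.get_spec(model_id)
        kwargs = {name: t for name in spec.required_inputs}
        rate = rm.forcing_rate(model_id, **kwargs)
        assert rate >= 0.0
        assert math.isfinite(rate)


@settings(derandomize=True, max_examples=200)
@given(t=TEMPS)
def test_wider_threshold_windows_dominate_narrower(t):
    assert rm.chilling_rate("C1", t) >= rm.chilling_rate("C2", t)
    assert rm.chilling_rate("C1", t) >= rm.chilling_rate("C3", t)
    assert rm.chilling_rate("C4", t) >= rm.chilling_rate("C5", t)
    assert rm.chilling_rate("C4", t) >= rm.chilling_rate("C6", t)


def test_c12_peaks_uniquely_at_optimum():
    grid = np.round(np.arange(-1000, 1501) * 0.01, 2)
    rates = rm.chilling_rate("C12", grid)
    assert grid[np.argmax(rates)] == pytest.approx(0.2)
    assert np.sum(rates == rates.max()) == 1
    assert np.all(rates[grid >= 6.9] == 0.0)
    assert np.all(rates[grid <= -6.5] == 0.0)


@settings(derandomize=True, max_examples=100)
@given(t=st.floats(min_value=5.0, max_value=45.0))
def test_f2_is_f1_shifted_by_its_threshold(t):
    assert rm.forcing_rate("F2", t_mean=t) == pytest.approx(
        rm.forcing_rate("F1", t_mean=t - 5.0), abs=1e-12
    )


def test_f8_is_continuous_at_the_optimum():
    eps = 1e-12
    left = rm.forcing_rate("F8", t_mean=25.0 - eps)
    right = rm.forcing_rate("F8", t_mean=25.0 + eps)
    assert abs(left - right) <= 1e-9
    assert rm.forcing_rate("F8", t_mean=25.0) == pytest.approx(21.0)


def test_vectorized_rates_match_scalar_evaluation():
    grid = np.linspace(-20, 40, 301)
    for model_id in rm.CHILLING_IDS:
        if model_id == "C9":
            continue
        vec = rm.chilling_rate(model_id, grid)
        scal = np.array([rm.chilling_rate(model_id, float(t)) for t in grid])
        np.testing.assert_allclose(vec, scal, atol=1e-12)


# ---------------------------------------------------------------------------
# dynamic model (C9)
# ---------------------------------------------------------------------------

def _oracle_portions(temps):
    # independent transliteration of the precursor/portion recursion
    e0, e1 = 4153.5, 12888.8
    a0, a1 = 139500.0, 2.567e18
    slp, tetmlt = 1.6, 277.0
    inter_s, total = 0.0, 0.0
    for t in temps:
        tk = t + 273.0
        xi = 1.0 / (1.0 + math.exp(-slp * tetmlt * (tk - tetmlt) / tk))
        xs = (a0 / a1) * math.exp((e1 - e0) / tk)
        ak1 = a1 * math.exp(-e1 / tk)
        inter_e = xs - (xs - inter_s) * math.exp(-ak1)
        if inter_e >= 1.0:
            total += xi * inter_e
            inter_s = inter_e * (1.0 - xi)
        else:
            inter_s = inter_e
    return total


def test_single_step_from_fresh_state_yields_no_portion():
    for t in (-5.0, 0.0, 6.0, 12.0):
        _, delta = rm.dynamic_chill_step(rm.DynamicChillState(), t)
        assert delta == 0.0


def test_portions_accumulate_and_never_decrease_at_chilling_temperatures():
    state = rm.DynamicChillState()
    previous = 0.0
    for _ in range(90):
        state, delta = rm.dynamic_chill_step(state, 6.0)
        assert delta >= 0.0
        assert state.portions >= previous
        previous = state.portions
    assert state.portions > 0.0


def test_dynamic_recursion_matches_independent_oracle():
    temps = np.full(60, 6.0)
    assert rm.dynamic_chill_portions(temps)[-1] == pytest.approx(
        _oracle_portions(temps), abs=1e-9
    )
    rng = np.random.default_rng(11)
    temps = rng.uniform(-5.0, 20.0, 120)
    np.testing.assert_allclose(
        rm.dynamic_chill_portions(temps)[-1], _oracle_portions(temps), atol=1e-9
    )


def test_sustained_heat_destroys_the_intermediate_pool():
    state = rm.DynamicChillState()
    for _ in range(40):
        state, _ = rm.dynamic_chill_step(state, 6.0)  # build up some pool
    for _ in range(30):
        state, delta = rm.dynamic_chill_step(state, 32.0)
        assert delta == 0.0
    assert state.intermediate_pool < 1.0


def test_interleaved_warm_days_reduce_chill_portions():
    cold = np.full(120, 6.0)
    interleaved = cold.copy()
    interleaved[::4] = 30.0
    assert (
        rm.dynamic_chill_portions(cold)[-1]
        > rm.dynamic_chill_portions(interleaved)[-1]
    )
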