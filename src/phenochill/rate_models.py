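"""Daily rate-of-chilling and rate-of-forcing functions.

Twelve chilling models (``C1``–``C12``) and eight forcing models
(``F1``–``F8``) are exposed as a uniform registry of pure functions.  A
chilling model maps the daily mean temperature to a rate of chilling
(chill units per day); a forcing model maps daily mean (or, for ``F3``,
``F4`` and ``F5``, daily maximum/minimum) temperature to a rate of
forcing (forcing units per day).

The threshold models ``C1``–``C6`` assign a rate of 1 inside a
temperature band and 0 outside.  ``C7`` is the Utah model, which weights
temperature ranges and penalises warm days with negative chill units;
``C8`` is the Utah model with the negative weights removed.  ``C9`` is
the dynamic (chill-portions) model: a two-step precursor/portion scheme
whose current rate depends on an intermediate state, so it is the only
*stateful* model in the registry and must be driven through
:func:`dynamic_chill_step` (or :func:`dynamic_chill_portions`).  ``C10``
is a three-parameter Weibull-shaped rate, and ``C11``/``C12`` are
triangular rates (``C12`` with optimum 0.2 °C and upper limit 6.9 °C).

``F1``–``F5`` are growing-degree-day variants, ``F6``/``F7`` logistic
rates, and ``F8`` a growing-degree-hour-style bell applied at daily
step.

All stateless rates are vectorized: scalars in, scalar out; arrays in,
element-wise array out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHILLING_IDS",
    "FORCING_IDS",
    "RateModelSpec",
    "DynamicChillState",
    "UnknownModelError",
    "StatefulModelError",
    "MissingInputError",
    "chilling_rate",
    "forcing_rate",
    "dynamic_chill_step",
    "dynamic_chill_portions",
    "list_models",
    "get_spec",
    "model_table",
]

CHILLING_IDS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 13))
FORCING_IDS: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 9))


class UnknownModelError(KeyError):
    """Raised when a model id is not in the registry."""


class StatefulModelError(TypeError):
    """Raised when the stateful model C9 is passed to a stateless entry point."""


class MissingInputError(ValueError):
    """Raised when a forcing model lacks one of its required temperature inputs."""


# ---------------------------------------------------------------------------
# chilling rates (stateless)
# ---------------------------------------------------------------------------

def _cu1(t):
    return np.where(t <= 5.0, 1.0, 0.0)


def _cu2(t):
    return np.where((t >= -10.0) & (t <= 5.0), 1.0, 0.0)


def _cu3(t):
    return np.where((t >= 0.0) & (t <= 5.0), 1.0, 0.0)


def _cu4(t):
    return np.where(t <= 7.0, 1.0, 0.0)


def _cu5(t):
    return np.where((t >= -10.0) & (t <= 7.0), 1.0, 0.0)


def _cu6(t):
    return np.where((t >= 0.0) & (t <= 7.0), 1.0, 0.0)


def _cu7(t):
    # Utah model: weighted ranges, negative chill for warm days.
    return np.select(
        [t <= 1.4, t <= 2.4, t <= 9.1, t <= 12.4, t <= 15.9, t <= 18.0],
        [0.0, 0.5, 1.0, 0.5, 0.0, -0.5],
        default=-1.0,
    )


def _cu8(t):
    # Utah model without the negative contributions.
    return np.select(
        [t <= 1.4, t <= 2.4, t <= 9.1, t <= 12.4],
        [0.0, 0.5, 1.0, 0.5],
        default=0.0,
    )


def _cu10(t):
    # Weibull-shaped rate; plateau of 1 on the open interval (2.5, 7.4),
    # zero outside [-4.7, 16].  The printed expression has a negative base
    # on the sliver [-4.7, -4.66); the rate is taken as 0 there (the
    # expression vanishes continuously as T -> -4.66 from above).
    t = np.asarray(t, dtype=float)
    z = (t + 4.66) / 10.93
    zp = np.where(z > 0.0, z, np.nan)
    with np.errstate(invalid="ignore"):
        weib = 3.13 * zp ** 2.10 * np.exp(-(zp ** 3.10))
    weib = np.where(np.isfinite(weib), weib, 0.0)
    out = np.where((t > 2.5) & (t < 7.4), 1.0, weib)
    return np.where((t < -4.7) | (t > 16.0), 0.0, out)


def _cu11(t):
    # Triangular, optimum 5 degC, support (-3.4, 10.4).
    return np.select(
        [(t <= -3.4) | (t >= 10.4), t <= 5.0],
        [0.0, (np.asarray(t, dtype=float) + 3.4) / (5.0 + 3.4)],
        default=(10.4 - np.asarray(t, dtype=float)) / (10.4 - 5.0),
    )


def _cu12(t):
    # Triangular, optimum 0.2 degC, support (-6.5, 6.9).
    return np.select(
        [(t <= -6.5) | (t >= 6.9), t <= 0.2],
        [0.0, (np.asarray(t, dtype=float) + 6.5) / (6.9 - 0.2)],
        default=(6.9 - np.asarray(t, dtype=float)) / (6.9 - 0.2),
    )


_CHILL_FUNCS: dict[str, Callable] = {
    "C1": _cu1,
    "C2": _cu2,
    "C3": _cu3,
    "C4": _cu4,
    "C5": _cu5,
    "C6": _cu6,
    "C7": _cu7,
    "C8": _cu8,
    "C10": _cu10,
    "C11": _cu11,
    "C12": _cu12,
}


# ---------------------------------------------------------------------------
# dynamic model (C9)
# ---------------------------------------------------------------------------

# Published constant set of the two-step precursor/portion recursion.
DYNAMIC_PARAMS: Mapping[str, float] = {
    "slope": 1.6,
    "tetmlt": 277.0,  # K
    "e0": 4153.5,
    "e1": 12888.8,
    "a0": 139500.0,
    "a1": 2.567e18,
}


@dataclass
class DynamicChillState:
    """State of the dynamic chilling model.

    ``intermediate_pool`` is the unaccumulated thermal precursor;
    ``portions`` is the irreversibly banked chill-portion total, which is
    non-decreasing over successive steps.  A fresh season starts at zero
    pool and zero portions.
    """

    intermediate_pool: float = 0.0
    portions: float = 0.0


def dynamic_chill_step(
    state: DynamicChillState, t_mean: float
) -> tuple[DynamicChillState, float]:
    """Advance the dynamic model by one day at temperature ``t_mean``.

    Returns the new state and the chill-portion increment of the step
    (``>= 0``).  The precursor pool relaxes toward a temperature-dependent
    equilibrium; once the pool exceeds 1 a temperature-dependent fraction
    is converted irreversibly into portions.  Sustained warmth (>= ~30 degC)
    drives the equilibrium below 1, destroying the pool without yielding
    portions.
    """
    if not math.isfinite(t_mean):
        raise ValueError("t_mean must be finite")
    p = DYNAMIC_PARAMS
    tk = float(t_mean) + 273.0
    ftmprt = p["slope"] * p["tetmlt"] * (tk - p["tetmlt"]) / tk
    sr = math.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = p["a0"] / p["a1"] * math.exp((p["e1"] - p["e0"]) / tk)
    ak1 = p["a1"] * math.exp(-p["e1"] / tk)
    inter_e = xs - (xs - state.intermediate_pool) * math.exp(-ak1)
    if inter_e < 1.0:
        delta = 0.0
        pool = inter_e
    else:
        delta = xi * inter_e
        pool = inter_e - delta
    return DynamicChillState(pool, state.portions + delta), delta


def dynamic_chill_portions(t_mean: np.ndarray) -> np.ndarray:
    """Cumulative chill portions over a daily temperature sequence.

    The season starts fresh (zero pool, zero portions).  NaN days leave
    the state unchanged and repeat the running total.  Returns an array
    of the same length with the portions total *after* each day.
    """
    p = DYNAMIC_PARAMS
    slope, tetmlt = p["slope"], p["tetmlt"]
    e0, e1, a0, a1 = p["e0"], p["e1"], p["a0"], p["a1"]
    aa = a0 / a1
    ee = e1 - e0
    exp = math.exp
    pool = 0.0
    total = 0.0
    out = np.empty(len(t_mean), dtype=float)
    for i, t in enumerate(np.asarray(t_mean, dtype=float)):
        if not math.isnan(t):
            tk = t + 273.0
            sr = exp(slope * tetmlt * (tk - tetmlt) / tk)
            xi = sr / (1.0 + sr)
            xs = aa * exp(ee / tk)
            ak1 = a1 * exp(-e1 / tk)
            inter_e = xs - (xs - pool) * exp(-ak1)
            if inter_e < 1.0:
                pool = inter_e
            else:
                delta = xi * inter_e
                pool = inter_e - delta
                total += delta
        out[i] = total
    return out


# ---------------------------------------------------------------------------
# forcing rates
# ---------------------------------------------------------------------------

def _fu1(t_mean, t_max, t_min):
    return np.maximum(np.asarray(t_mean, dtype=float), 0.0)


def _fu2(t_mean, t_max, t_min):
    return np.maximum(np.asarray(t_mean, dtype=float) - 5.0, 0.0)


def _fu3(t_mean, t_max, t_min):
    return np.maximum(np.asarray(t_max, dtype=float), 0.0)


def _fu4(t_mean, t_max, t_min):
    return np.maximum(np.asarray(t_max, dtype=float) - 5.0, 0.0)


def _fu5(t_mean, t_max, t_min):
    return 0.75 * np.maximum(np.asarray(t_max, dtype=float) - 5.0, 0.0) + \
        0.25 * np.maximum(np.asarray(t_min, dtype=float) - 5.0, 0.0)


def _fu6(t_mean, t_max, t_min):
    t = np.asarray(t_mean, dtype=float)
    return np.where(t > 0.0, 28.4 / (1.0 + np.exp(-0.185 * (t - 18.5))), 0.0)


def _fu7(t_mean, t_max, t_min):
    t = np.asarray(t_mean, dtype=float)
    return 1.0 / (1.0 + np.exp(-0.47 * t + 6.49))


_GDH_TL, _GDH_TU, _GDH_TC = 4.0, 25.0, 36.0


def _fu8(t_mean, t_max, t_min):
    # Bell-shaped GDH rate at daily step, stress factor ignored.  The
    # middle branch applies on T_L <= T <= T_u (the only reading that
    # makes the three branches partition the temperature axis).
    t = np.asarray(t_mean, dtype=float)
    mid = (_GDH_TU - _GDH_TL) / 2.0 * (
        1.0 + np.cos(np.pi + np.pi * (t - _GDH_TL) / (_GDH_TU - _GDH_TL))
    )
    high = (_GDH_TU - _GDH_TL) * (
        1.0 + np.cos(np.pi / 2.0 + np.pi / 2.0 * (t - _GDH_TU) / (_GDH_TC - _GDH_TU))
    )
    return np.select(
        [(t < _GDH_TL) | (t > _GDH_TC), t <= _GDH_TU, t <= _GDH_TC],
        [0.0, mid, high],
    )


_FORCE_FUNCS: dict[str, Callable] = {
    "F1": _fu1,
    "F2": _fu2,
    "F3": _fu3,
    "F4": _fu4,
    "F5": _fu5,
    "F6": _fu6,
    "F7": _fu7,
    "F8": _fu8,
}


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateModelSpec:
    """Registry entry for one chilling or forcing rate model."""

    model_id: str
    kind: str  # "chilling" | "forcing"
    required_inputs: frozenset[str]
    stateful: bool
    params: Mapping[str, float] = field(default_factory=dict)


def _spec(model_id, kind, inputs, stateful, params):
    return RateModelSpec(model_id, kind, frozenset(inputs), stateful, dict(params))


_SPECS: dict[str, RateModelSpec] = {}
for _mid, _params in [
    ("C1", {"t_upper": 5.0}),
    ("C2", {"t_lower": -10.0, "t_upper": 5.0}),
    ("C3", {"t_lower": 0.0, "t_upper": 5.0}),
    ("C4", {"t_upper": 7.0}),
    ("C5", {"t_lower": -10.0, "t_upper": 7.0}),
    ("C6", {"t_lower": 0.0, "t_upper": 7.0}),
    ("C7", {"breaks": (1.4, 2.4, 9.1, 12.4, 15.9, 18.0)}),
    ("C8", {"breaks": (1.4, 2.4, 9.1, 12.4)}),
    ("C9", dict(DYNAMIC_PARAMS)),
    ("C10", {"scale": 3.13, "shift": 4.66, "width": 10.93,
             "exp1": 2.10, "exp2": 3.10, "plateau": (2.5, 7.4),
             "support": (-4.7, 16.0)}),
    ("C11", {"t_lower": -3.4, "t_opt": 5.0, "t_upper": 10.4}),
    ("C12", {"t_lower": -6.5, "t_opt": 0.2, "t_upper": 6.9}),
]:
    _SPECS[_mid] = _spec(_mid, "chilling", {"t_mean"}, _mid == "C9", _params)

for _mid, _inputs, _params in [
    ("F1", {"t_mean"}, {"threshold": 0.0}),
    ("F2", {"t_mean"}, {"threshold": 5.0}),
    ("F3", {"t_max"}, {"threshold": 0.0}),
    ("F4", {"t_max"}, {"threshold": 5.0}),
    ("F5", {"t_max", "t_min"}, {"threshold": 5.0, "w_day": 0.75, "w_night": 0.25}),
    ("F6", {"t_mean"}, {"asymptote": 28.4, "steepness": 0.185, "midpoint": 18.5}),
    ("F7", {"t_mean"}, {"steepness": 0.47, "offset": 6.49}),
    ("F8", {"t_mean"}, {"t_low": _GDH_TL, "t_opt": _GDH_TU, "t_crit": _GDH_TC}),
]:
    _SPECS[_mid] = _spec(_mid, "forcing", _inputs, False, _params)


def get_spec(model_id: str) -> RateModelSpec:
    """Return the registry entry for ``model_id`` (raises for unknown ids)."""
    try:
        return _SPECS[model_id]
    except KeyError:
        raise UnknownModelError(f"unknown rate model {model_id!r}") from None


def list_models() -> list[RateModelSpec]:
    """All 20 model specs in fixed order C1..C12, F1..F8."""
    return [_SPECS[m] for m in CHILLING_IDS + FORCING_IDS]


def model_table() -> pd.DataFrame:
    """Machine-readable model table (id, kind, stateful, inputs, params)."""
    rows = []
    for spec in list_models():
        rows.append(
            {
                "model_id": spec.model_id,
                "kind": spec.kind,
                "stateful": spec.stateful,
                "required_inputs": ",".join(sorted(spec.required_inputs)),
                "params": ";".join(f"{k}={v}" for k, v in sorted(spec.params.items())),
            }
        )
    return pd.DataFrame(rows)


def _as_result(x, scalar_in):
    x = np.asarray(x, dtype=float)
    if scalar_in:
        return float(x)
    return x


def chilling_rate(model_id: str, t_mean):
    """Daily rate of chilling for a stateless chilling model.

    Parameters
    ----------
    model_id : one of ``C1``–``C8``, ``C10``–``C12``
    t_mean : daily mean temperature in degC (scalar or array)

    ``C9`` is stateful and must be driven through
    :func:`dynamic_chill_step` / :func:`dynamic_chill_portions`.
    """
    spec = get_spec(model_id)
    if spec.kind != "chilling":
        raise UnknownModelError(f"{model_id} is not a chilling model")
    if spec.stateful:
        raise StatefulModelError(
            "C9 is stateful; use dynamic_chill_step or dynamic_chill_portions"
        )
    scalar_in = np.isscalar(t_mean) or np.ndim(t_mean) == 0
    t = np.asarray(t_mean, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t_mean must be finite")
    return _as_result(_CHILL_FUNCS[model_id](t), scalar_in)


def forcing_rate(model_id: str, t_mean=None, t_max=None, t_min=None):
    """Daily rate of forcing for models ``F1``–``F8``.

    ``F3``/``F4`` require ``t_max``; ``F5`` requires ``t_max`` and
    ``t_min``; all others require ``t_mean``.  Missing required inputs
    raise :class:`MissingInputError`.
    """
    spec = get_spec(model_id)
    if spec.kind != "forcing":
        raise UnknownModelError(f"{model_id} is not a forcing model")
    provided = {"t_mean": t_mean, "t_max": t_max, "t_min": t_min}
    arrays = {}
    scalar_in = True
    for name in sorted(spec.required_inputs):
        value = provided[name]
        if value is None:
            raise MissingInputError(f"{model_id} requires {name}")
        if not (np.isscalar(value) or np.ndim(value) == 0):
            scalar_in = False
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
        arrays[name] = arr
    out = _FORCE_FUNCS[model_id](
        arrays.get("t_mean"), arrays.get("t_max"), arrays.get("t_min")
    )
    return _as_result(out, scalar_in)
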