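"""Process-based onset simulation from the CA–HR rule, with evaluation metrics.

The empirical onset model couples a chilling model and a forcing model
through the fitted linear CA–HR rule ``HR(CA) = a + b * CA``.  Running
at daily step for one event year:

* chilling accumulates from 1 November of the previous year,
* heat accumulates from the forcing start date (default 1 January),
* on each day the current heat requirement is ``max(a + b * CA_t, 0)``
  (required heat is floored at zero — a negative requirement is
  physiologically meaningless),
* the onset is the first day whose heat accumulation is *strictly
  larger* than the requirement; exact equality does not trigger.

If the threshold is never crossed by 31 July the year yields a sentinel
(``None`` scalar / NaN in series form) rather than an error.  The
simulation is deterministic.

Evaluation mirrors the spatial and temporal skill measures used for
hindcasts: OLS R^2 and RMSE between simulated and observed mean onset
dates across locations, and between simulated and observed per-location
trends (days per year).  ``moving_average`` (11-year centered) and
``decadal_advance`` (mean reference-decade DOY minus mean target-decade
DOY, positive = earlier) summarise projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accumulation import (
    CoverageError,
    DailySeries,
    cumulative_chill,
    cumulative_forcing,
)
from .cahr_validity import RegressionFit, fit_ca_hr

__all__ = [
    "PhenoModelParams",
    "OnsetSeries",
    "fit",
    "predict_onset",
    "simulate_series",
    "evaluate_spatial",
    "evaluate_trends",
    "moving_average",
    "decadal_advance",
]

_SIM_END_MONTH_DAY = (7, 31)  # onset search horizon

_FORCE_START = {"jan1": (1, 1), "jan15": (1, 15), "feb1": (2, 1)}


@dataclass(frozen=True)
class PhenoModelParams:
    """Fitted CA–HR rule plus model and window choices driving simulation."""

    chilling_model: str
    forcing_model: str
    a: float
    b: float
    force_start: str = "jan1"

    def __post_init__(self):
        if self.force_start not in _FORCE_START:
            raise ValueError(f"unknown force_start {self.force_start!r}")
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("parameters must be finite")


@dataclass
class OnsetSeries:
    """Simulated onset day-of-year per year for one location (NaN = no onset)."""

    location_id: str
    onsets: pd.Series  # index: year, values: float DOY or NaN


def fit(
    table: pd.DataFrame,
    chilling_model: str,
    forcing_model: str = "F1",
    force_start: str = "jan1",
) -> tuple[PhenoModelParams, RegressionFit]:
    """Fit the CA–HR rule on raw records of a CAHR table."""
    reg = fit_ca_hr(table, chilling_model, forcing_model)
    params = PhenoModelParams(chilling_model, forcing_model, reg.a, reg.b, force_start)
    return params, reg


def predict_onset(
    params: PhenoModelParams, series: DailySeries, year: int
) -> int | None:
    """Simulated onset DOY for one event year, or ``None`` if never reached.

    Requires series coverage from 1 Nov (year-1) through 31 Jul (year).
    """
    chill_start = pd.Timestamp(year=year - 1, month=11, day=1)
    fs_month, fs_day = _FORCE_START[params.force_start]
    force_start = pd.Timestamp(year=year, month=fs_month, day=fs_day)
    sim_end = pd.Timestamp(year=year, month=_SIM_END_MONTH_DAY[0], day=_SIM_END_MONTH_DAY[1])
    if not series.covers(chill_start, sim_end):
        raise CoverageError(
            f"series {series.location_id} must cover "
            f"{chill_start.date()}..{sim_end.date()}"
        )
    t_mean, t_max, t_min = series.slice_arrays(chill_start, sim_end)
    ca_cum = cumulative_chill(params.chilling_model, t_mean)
    offset = (force_start - chill_start).days
    heat_cum = cumulative_forcing(
        params.forcing_model,
        t_mean[offset:],
        None if t_max is None else t_max[offset:],
        None if t_min is None else t_min[offset:],
    )
    hr_required = np.maximum(params.a + params.b * ca_cum[offset:], 0.0)
    hit = np.flatnonzero(heat_cum > hr_required)
    if len(hit) == 0:
        return None
    onset_date = force_start + pd.Timedelta(days=int(hit[0]))
    return int(onset_date.dayofyear)


def simulate_series(
    params: PhenoModelParams,
    series: DailySeries,
    years: Sequence[int] | None = None,
) -> OnsetSeries:
    """Apply :func:`predict_onset` to every coverable year of a series."""
    if years is None:
        start_year = series.start.year
        first = start_year + 1 if series.start <= pd.Timestamp(
            year=start_year, month=11, day=1
        ) else start_year + 2
        last = series.end.year if series.end >= pd.Timestamp(
            year=series.end.year, month=7, day=31
        ) else series.end.year - 1
        years = range(first, last + 1)
    onsets = {}
    for year in years:
        doy = predict_onset(params, series, int(year))
        onsets[int(year)] = float("nan") if doy is None else float(doy)
    return OnsetSeries(series.location_id, pd.Series(onsets, dtype=float))


def _r2_rmse(sim: Sequence[float], obs: Sequence[float]) -> tuple[float, float]:
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(sim) != len(obs):
        raise ValueError("simulated and observed vectors differ in length")
    if len(sim) < 3:
        raise ValueError("need at least 3 locations")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    if np.ptp(sim) == 0 or np.ptp(obs) == 0:
        r2 = 1.0 if np.allclose(sim - sim.mean(), obs - obs.mean()) else 0.0
    else:
        r2 = float(stats.linregress(sim, obs).rvalue ** 2)
    return r2, rmse


def evaluate_spatial(sim_means, obs_means) -> tuple[float, float]:
    """R^2 and RMSE (days) between simulated and observed mean onset dates."""
    return _r2_rmse(sim_means, obs_means)


def evaluate_trends(sim_trends, obs_trends) -> tuple[float, float]:
    """R^2 and RMSE (days/year) between simulated and observed onset trends."""
    return _r2_rmse(sim_trends, obs_trends)


def moving_average(values: pd.Series, window: int = 11) -> pd.Series:
    """Centered moving average; edges truncate to the available years."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    return values.rolling(window, center=True, min_periods=1).mean()


def decadal_advance(
    onsets: pd.Series,
    ref_years: Sequence[int] = range(2010, 2019),
    target_years: Sequence[int] = range(2090, 2100),
) -> float:
    """Days of advance between decades: mean(ref) - mean(target), positive = earlier."""
    ref = onsets.reindex(list(ref_years)).dropna()
    target = onsets.reindex(list(target_years)).dropna()
    if len(ref) == 0 or len(target) == 0:
        raise ValueError("both decades need at least one simulated year")
    return float(ref.mean() - target.mean())
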