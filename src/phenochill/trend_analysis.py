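"""Linear trends in chilling accumulation and inter-model correlation.

Per station, CA over a fixed winter window (1 Nov – 30 Apr) is regressed
on calendar year by ordinary least squares.  Significance of the slope
comes from the regression F-test of zero slope, which for simple linear
regression is identical to the two-sided t-test on the slope.  Each
station is then classified into one of four classes (significant /
insignificant x negative / positive) at alpha = 0.05.

``model_intercorrelation`` computes pairwise Pearson correlations
between the yearly CA series of the 12 chilling models at one station,
to show whether the models agree on the direction of change in chilling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accumulation import DailySeries, SeasonWindow, accumulate
from .rate_models import CHILLING_IDS

__all__ = [
    "TrendResult",
    "TREND_CLASSES",
    "InsufficientDataError",
    "linear_trend",
    "classify_trend",
    "model_intercorrelation",
    "ca_series",
    "trend_table",
]

TREND_CLASSES = ("sig_neg", "insig_neg", "sig_pos", "insig_pos")

DEFAULT_ALPHA = 0.05


class InsufficientDataError(ValueError):
    """Fewer than 3 points, or no variance in the regressor."""


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    n_years: int
    trend_class: str


def classify_trend(slope: float, p_value: float, alpha: float = DEFAULT_ALPHA) -> str:
    """Four-way trend class; a slope of exactly 0 is insig_neg by convention."""
    significant = p_value < alpha
    if slope > 0:
        return "sig_pos" if significant else "insig_pos"
    # ties (slope == 0) fall to the negative side and are never significant
    if slope == 0:
        return "insig_neg"
    return "sig_neg" if significant else "insig_neg"


def linear_trend(
    years: Sequence[float], values: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> TrendResult:
    """OLS trend of ``values`` against ``years`` with two-sided p-value.

    The p-value is from the F-test of the regression (equivalently the
    two-sided t-test of zero slope).  A constant response yields slope 0,
    p = 1 by convention.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) != len(values):
        raise ValueError("years and values must have equal length")
    if len(years) < 3:
        raise InsufficientDataError("need at least 3 points for a trend")
    if np.ptp(years) == 0:
        raise InsufficientDataError("years have zero variance")
    if np.ptp(values) == 0:
        result = TrendResult(0.0, float(values[0]), 1.0, len(years), "insig_neg")
        return result
    fit = stats.linregress(years, values)
    p = float(fit.pvalue)
    slope = float(fit.slope)
    return TrendResult(
        slope, float(fit.intercept), p, len(years), classify_trend(slope, p, alpha)
    )


def ca_series(
    series: DailySeries,
    model_id: str,
    years: Sequence[int],
    *,
    max_missing_frac: float = 0.0,
) -> pd.Series:
    """Yearly CA over the fixed 1 Nov – 30 Apr window for one station."""
    values = {}
    for year in years:
        window = SeasonWindow("nov1_prev_year", "apr30", int(year))
        values[int(year)] = accumulate(
            series, model_id, window, max_missing_frac=max_missing_frac
        ).value
    return pd.Series(values, name=model_id)


def model_intercorrelation(ca_by_model: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between yearly CA series of chilling models.

    ``ca_by_model`` is years x models (one column per chilling model).
    Every model pair must share at least 3 years of data.  The result is
    symmetric with unit diagonal; a constant column yields NaN against
    the others (undefined correlation).
    """
    if ca_by_model.shape[1] < 2:
        raise ValueError("need at least two model columns")
    counts = ca_by_model.notna().astype(int)
    common = counts.T @ counts
    if (common.values < 3).any():
        raise InsufficientDataError("every model pair needs >= 3 common years")
    corr = ca_by_model.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def trend_table(
    series_by_station: Mapping[str, DailySeries],
    years: Sequence[int],
    model_ids: Sequence[str] = CHILLING_IDS,
    alpha: float = DEFAULT_ALPHA,
    *,
    max_missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-station, per-model CA trend table (station, model, slope, p, class)."""
    rows = []
    for station_id, series in series_by_station.items():
        for model_id in model_ids:
            ca = ca_series(
                series, model_id, years, max_missing_frac=max_missing_frac
            )
            res = linear_trend(ca.index.values, ca.values, alpha)
            rows.append(
                {
                    "station_id": station_id,
                    "model_id": model_id,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "p_value": res.p_value,
                    "n_years": res.n_years,
                    "trend_class": res.trend_class,
                }
            )
    return pd.DataFrame(rows)
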