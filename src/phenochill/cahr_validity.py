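"""CA–HR relationship analysis and chilling-model validity classification.

The physiological assumption is that more winter chilling lowers the
heat requirement of a spring event, i.e. CA and HR are negatively
related.  A chilling model is classified *valid* for a species when the
pooled Pearson correlation between its CA (1 Nov previous year to
onset) and the HR of a forcing model (default F1, 1 Jan to onset) is
significantly negative (r < 0 and two-sided p < 0.05); otherwise it is
*invalid*.

Also provided: the station-level analysis (fraction of stations with at
least ``min_years`` records showing a significantly negative r), the
20-equal-count-group binned summary used for presentation, the raw-record
OLS regression of HR on CA with Wald 95% confidence intervals, and a
two-group comparison of the CA–HR slope (e.g. a latitude split) via an
interaction term.

All record-level functions operate on a "CAHR table": a DataFrame with
one row per phenological record and columns ``station_id, species,
bbch, year, onset_doy, lat, lon, alt`` plus ``ca_<model>`` and
``hr_<model>`` value columns as produced by
:func:`phenochill.accumulation.build_cahr_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .accumulation import ca_column, hr_column
from .rate_models import CHILLING_IDS

__all__ = [
    "ValidityVerdict",
    "StationFractionResult",
    "RegressionFit",
    "GroupComparison",
    "UndefinedCorrelationError",
    "DegenerateDesignError",
    "pearson_test",
    "classify_model_validity",
    "validity_table",
    "station_level_fraction",
    "bin_equal_count",
    "fit_ca_hr_regression",
    "fit_ca_hr",
    "group_compare",
]

DEFAULT_ALPHA = 0.05


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a degenerate (zero-variance or tiny) sample."""


class DegenerateDesignError(ValueError):
    """Regression requested with a constant regressor."""


@dataclass(frozen=True)
class ValidityVerdict:
    species: str
    chilling_model: str
    forcing_model: str
    r: float
    p: float
    n: int
    verdict: str  # "valid" | "invalid"


@dataclass(frozen=True)
class StationFractionResult:
    fraction: float
    stations: tuple[str, ...]
    significant_stations: tuple[str, ...]
    empty: bool


@dataclass(frozen=True)
class RegressionFit:
    a: float  # intercept
    b: float  # slope
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    n: int
    r2: float


@dataclass(frozen=True)
class GroupComparison:
    fit_in: RegressionFit
    fit_out: RegressionFit
    slope_diff: float
    p_slope_diff: float


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_model_validity(
    table: pd.DataFrame,
    chilling_model: str,
    forcing_model: str = "F1",
    alpha: float = DEFAULT_ALPHA,
    species: str | None = None,
) -> ValidityVerdict:
    """Pooled CA–HR validity verdict for one chilling model.

    Records are pooled over all stations and years (per species if the
    table holds several and ``species`` is given).  ``valid`` iff
    r < 0 and p < alpha.
    """
    if species is not None:
        table = table[table["species"] == species]
    elif table["species"].nunique() == 1:
        species = str(table["species"].iloc[0])
    else:
        species = "all"
    ca = table[ca_column(chilling_model)].to_numpy()
    hr = table[hr_column(forcing_model)].to_numpy()
    r, p = pearson_test(ca, hr)
    verdict = "valid" if (r < 0 and p < alpha) else "invalid"
    return ValidityVerdict(species, chilling_model, forcing_model, r, p, len(ca), verdict)


def validity_table(
    table: pd.DataFrame,
    chilling_ids: Sequence[str] = CHILLING_IDS,
    forcing_model: str = "F1",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Tidy verdict table over chilling models (one species or pooled)."""
    rows = []
    for cm in chilling_ids:
        v = classify_model_validity(table, cm, forcing_model, alpha)
        rows.append(
            {
                "species": v.species,
                "chilling_model": v.chilling_model,
                "forcing_model": v.forcing_model,
                "r": v.r,
                "p": v.p,
                "n": v.n,
                "verdict": v.verdict,
            }
        )
    return pd.DataFrame(rows)


def station_level_fraction(
    table: pd.DataFrame,
    chilling_model: str,
    forcing_model: str = "F1",
    min_years: int = 15,
    alpha: float = DEFAULT_ALPHA,
) -> StationFractionResult:
    """Fraction of long-record stations with significantly negative CA–HR r.

    Stations are kept only if they contribute at least ``min_years``
    records.  If no station qualifies, the result carries ``empty=True``
    and a NaN fraction.
    """
    ca_col, hr_col = ca_column(chilling_model), hr_column(forcing_model)
    qualifying, significant = [], []
    for station_id, grp in table.groupby("station_id", sort=True):
        if len(grp) < min_years:
            continue
        qualifying.append(str(station_id))
        try:
            r, p = pearson_test(grp[ca_col].to_numpy(), grp[hr_col].to_numpy())
        except UndefinedCorrelationError:
            continue
        if r < 0 and p < alpha:
            significant.append(str(station_id))
    if not qualifying:
        return StationFractionResult(float("nan"), (), (), True)
    return StationFractionResult(
        len(significant) / len(qualifying), tuple(qualifying), tuple(significant), False
    )


def bin_equal_count(
    table: pd.DataFrame,
    chilling_model: str,
    forcing_model: str = "F1",
    k: int = 20,
) -> pd.DataFrame:
    """Split records into ``k`` equal-count groups along CA.

    Records are ordered by (CA, station_id, year) — the deterministic
    tie-break — and cut into ``k`` contiguous groups whose sizes differ
    by at most one; when ``n`` is not divisible by ``k`` the larger
    groups sit at the low-CA end.  Returns per-group mean and sample SD
    (ddof=1; NaN for singleton groups) of CA and HR.
    """
    n = len(table)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    ca_col, hr_col = ca_column(chilling_model), hr_column(forcing_model)
    ordered = table.sort_values(
        [ca_col, "station_id", "year"], kind="mergesort"
    ).reset_index(drop=True)
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    rows = []
    start = 0
    for g, size in enumerate(sizes, start=1):
        chunk = ordered.iloc[start : start + size]
        start += size
        ca = chunk[ca_col].to_numpy()
        hr = chunk[hr_col].to_numpy()
        rows.append(
            {
                "group": g,
                "n": size,
                "ca_mean": float(ca.mean()),
                "ca_sd": float(np.std(ca, ddof=1)) if size > 1 else float("nan"),
                "hr_mean": float(hr.mean()),
                "hr_sd": float(np.std(hr, ddof=1)) if size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fit_ca_hr_regression(ca: Sequence[float], hr: Sequence[float]) -> RegressionFit:
    """OLS fit of HR on CA with Wald 95% confidence intervals.

    The regression is fitted on raw records; equal-count binning is a
    presentation device only.  A constant CA vector raises
    :class:`DegenerateDesignError`.
    """
    ca = np.asarray(ca, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if len(ca) != len(hr):
        raise ValueError("ca and hr must have equal length")
    if len(ca) < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(ca) == 0:
        raise DegenerateDesignError("CA values are all identical")
    X = sm.add_constant(ca)
    res = sm.OLS(hr, X).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionFit(
        a=float(res.params[0]),
        b=float(res.params[1]),
        ci95_a=(float(ci[0, 0]), float(ci[0, 1])),
        ci95_b=(float(ci[1, 0]), float(ci[1, 1])),
        n=len(ca),
        r2=float(res.rsquared),
    )


def fit_ca_hr(
    table: pd.DataFrame, chilling_model: str, forcing_model: str = "F1"
) -> RegressionFit:
    """Raw-record CA–HR regression for a model pair on a CAHR table."""
    return fit_ca_hr_regression(
        table[ca_column(chilling_model)].to_numpy(),
        table[hr_column(forcing_model)].to_numpy(),
    )


def group_compare(
    table: pd.DataFrame,
    split: Callable[[pd.DataFrame], pd.Series] | pd.Series,
    chilling_model: str,
    forcing_model: str = "F1",
) -> GroupComparison:
    """Compare CA–HR slopes between two record groups.

    ``split`` is a boolean mask (or a callable producing one, e.g.
    ``lambda t: t["lat"] < 50.65``).  Fits the regression in each group
    and tests slope equality two-sided via the interaction term of
    ``HR ~ CA * group``.
    """
    mask = split(table) if callable(split) else split
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("split must leave both groups nonempty")
    ca = table[ca_column(chilling_model)].to_numpy()
    hr = table[hr_column(forcing_model)].to_numpy()
    fit_in = fit_ca_hr_regression(ca[mask], hr[mask])
    fit_out = fit_ca_hr_regression(ca[~mask], hr[~mask])
    g = mask.astype(float)
    X = np.column_stack([np.ones_like(ca), ca, g, ca * g])
    res = sm.OLS(hr, X).fit()
    return GroupComparison(
        fit_in=fit_in,
        fit_out=fit_out,
        slope_diff=float(res.params[3]),
        p_slope_diff=float(res.pvalues[3]),
    )
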