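"""Windowed accumulation of chilling and forcing over daily temperature series.

Chilling accumulation (CA) is the sum of a model's daily rate of
chilling over a winter window; the paper-style default runs from
1 November of the previous year either to 30 April (for trend analysis)
or to the observed onset date (for the CA–HR analysis).  The heat
requirement (HR) is the sum of a forcing model's daily rate from a
forcing start date (default 1 January, alternatives 15 January and
1 February) to the onset date.

Day-of-year is 1-based (1 Jan = 1) and windows are closed intervals
``[start, end]``.  The dynamic model ``C9`` starts each window from a
fresh state (zero precursor pool, zero portions); its accumulation value
is the chill-portion total at the window end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import rate_models
from .rate_models import (
    CHILLING_IDS,
    FORCING_IDS,
    dynamic_chill_portions,
    get_spec,
)

__all__ = [
    "DailySeries",
    "SeasonWindow",
    "AccumulationResult",
    "PhenoRecord",
    "CAHRRecord",
    "CoverageError",
    "QualityError",
    "EmptyWindowError",
    "resolve_window",
    "accumulate",
    "cumulative_chill",
    "cumulative_forcing",
    "ca_hr_for_record",
    "build_cahr_table",
    "ca_column",
    "hr_column",
]

START_RULES = ("nov1_prev_year", "jan1", "jan15", "feb1")
END_RULES = ("apr30", "onset_date")

_START_MONTH_DAY = {
    "nov1_prev_year": (11, 1, -1),  # month, day, year offset
    "jan1": (1, 1, 0),
    "jan15": (1, 15, 0),
    "feb1": (2, 1, 0),
}


class CoverageError(ValueError):
    """The temperature series does not cover the requested window."""


class QualityError(ValueError):
    """Too many missing days inside the requested window."""


class EmptyWindowError(ValueError):
    """The resolved window is empty (end before start)."""


@dataclass
class DailySeries:
    """Dated daily mean/max/min temperatures for one location.

    ``dates`` must be strictly increasing contiguous calendar days.
    Where mean, max and min are all present, ``t_min <= t_mean <= t_max``
    is enforced.  Missing days inside the covered span are represented
    as NaN values, not as gaps.
    """

    location_id: str
    lat: float
    lon: float
    alt: float
    dates: pd.DatetimeIndex
    t_mean: np.ndarray
    t_max: np.ndarray | None = None
    t_min: np.ndarray | None = None

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.t_mean = np.asarray(self.t_mean, dtype=float)
        if self.t_max is not None:
            self.t_max = np.asarray(self.t_max, dtype=float)
        if self.t_min is not None:
            self.t_min = np.asarray(self.t_min, dtype=float)
        n = len(self.dates)
        for name in ("t_mean", "t_max", "t_min"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} dates")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("dates must be contiguous daily with no gaps")
        if self.t_max is not None and self.t_min is not None:
            ok = np.isfinite(self.t_mean) & np.isfinite(self.t_max) & np.isfinite(self.t_min)
            if np.any(self.t_min[ok] > self.t_mean[ok] + 1e-9) or np.any(
                self.t_mean[ok] > self.t_max[ok] + 1e-9
            ):
                raise ValueError("require t_min <= t_mean <= t_max where all present")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return self.start <= pd.Timestamp(start) and pd.Timestamp(end) <= self.end

    def slice_arrays(
        self, start: pd.Timestamp, end: pd.Timestamp
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        """Inclusive-slice (t_mean, t_max, t_min) for ``[start, end]``."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if not self.covers(start, end):
            raise CoverageError(
                f"series {self.location_id} covers {self.start.date()}..{self.end.date()}, "
                f"requested {start.date()}..{end.date()}"
            )
        i0 = self.dates.searchsorted(start)
        i1 = self.dates.searchsorted(end) + 1
        return (
            self.t_mean[i0:i1],
            None if self.t_max is None else self.t_max[i0:i1],
            None if self.t_min is None else self.t_min[i0:i1],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"date": self.dates, "tmean": self.t_mean}
        if self.t_max is not None:
            data["tmax"] = self.t_max
        if self.t_min is not None:
            data["tmin"] = self.t_min
        return pd.DataFrame(data)


@dataclass(frozen=True)
class SeasonWindow:
    """A calendar accumulation window attached to an event year.

    ``nov1_prev_year`` resolves to 1 November of ``event_year - 1``; the
    ``onset_date`` end rule resolves a 1-based day-of-year within the
    event year.
    """

    start_rule: str
    end_rule: str
    event_year: int
    onset_doy: int | None = None

    def __post_init__(self):
        if self.start_rule not in START_RULES:
            raise ValueError(f"unknown start rule {self.start_rule!r}")
        if self.end_rule not in END_RULES:
            raise ValueError(f"unknown end rule {self.end_rule!r}")
        if self.end_rule == "onset_date" and self.onset_doy is None:
            raise ValueError("onset_date end rule requires onset_doy")


@dataclass(frozen=True)
class AccumulationResult:
    value: float
    model_id: str
    window: SeasonWindow
    n_days: int
    n_missing: int


@dataclass(frozen=True)
class PhenoRecord:
    """One observed or simulated spring event."""

    station_id: str
    species: str
    bbch: int
    year: int
    onset_doy: int

    ALLOWED_BBCH = (10, 11, 60, 69)

    def __post_init__(self):
        if self.bbch not in self.ALLOWED_BBCH:
            raise ValueError(f"BBCH stage {self.bbch} not in {self.ALLOWED_BBCH}")
        if not 1 <= self.onset_doy <= 366:
            raise ValueError(f"onset_doy {self.onset_doy} outside [1, 366]")


@dataclass(frozen=True)
class CAHRRecord:
    """Per-event chilling accumulation and heat requirement."""

    record: PhenoRecord
    ca: Mapping[str, float]
    hr: Mapping[str, float]


def resolve_window(window: SeasonWindow) -> tuple[pd.Timestamp, pd.Timestamp, int]:
    """Resolve a :class:`SeasonWindow` to inclusive (start, end, n_days)."""
    month, day, yoff = _START_MONTH_DAY[window.start_rule]
    start = pd.Timestamp(year=window.event_year + yoff, month=month, day=day)
    if window.end_rule == "apr30":
        end = pd.Timestamp(year=window.event_year, month=4, day=30)
    else:
        end = pd.Timestamp(year=window.event_year, month=1, day=1) + pd.Timedelta(
            days=int(window.onset_doy) - 1
        )
    if end < start:
        raise EmptyWindowError(
            f"window end {end.date()} before start {start.date()} "
            f"(event year {window.event_year})"
        )
    n_days = (end - start).days + 1
    return start, end, n_days


def cumulative_chill(model_id: str, t_mean: np.ndarray) -> np.ndarray:
    """Running CA over a daily mean-temperature array (fresh C9 state).

    NaN days contribute a rate of 0 (callers enforce the missing-data
    policy before getting here).
    """
    if model_id == "C9":
        return dynamic_chill_portions(t_mean)
    rate = rate_models.chilling_rate(model_id, np.nan_to_num(t_mean, nan=0.0))
    rate = np.where(np.isnan(t_mean), 0.0, rate)
    return np.cumsum(rate)


def cumulative_forcing(
    model_id: str,
    t_mean: np.ndarray | None,
    t_max: np.ndarray | None = None,
    t_min: np.ndarray | None = None,
) -> np.ndarray:
    """Running heat accumulation over daily arrays for one forcing model."""
    spec = get_spec(model_id)
    arrays = {"t_mean": t_mean, "t_max": t_max, "t_min": t_min}
    missing_mask = None
    clean = {}
    for name in spec.required_inputs:
        arr = arrays[name]
        if arr is None:
            raise rate_models.MissingInputError(f"{model_id} requires {name}")
        arr = np.asarray(arr, dtype=float)
        m = np.isnan(arr)
        missing_mask = m if missing_mask is None else (missing_mask | m)
        clean[name] = np.nan_to_num(arr, nan=0.0)
    rate = rate_models.forcing_rate(model_id, **clean)
    rate = np.where(missing_mask, 0.0, rate)
    return np.cumsum(rate)


def _window_missing(spec, t_mean, t_max, t_min):
    mask = np.zeros(len(t_mean), dtype=bool)
    arrays = {"t_mean": t_mean, "t_max": t_max, "t_min": t_min}
    for name in spec.required_inputs:
        arr = arrays[name]
        if arr is None:
            raise rate_models.MissingInputError(f"{spec.model_id} requires {name}")
        mask |= np.isnan(np.asarray(arr, dtype=float))
    return mask


def accumulate(
    series: DailySeries,
    model_id: str,
    window: SeasonWindow,
    *,
    max_missing_frac: float = 0.0,
) -> AccumulationResult:
    """Sum the daily rate of ``model_id`` over ``window`` on ``series``.

    By default any missing day inside the window raises
    :class:`QualityError`; with ``max_missing_frac`` > 0 up to that
    fraction of missing days is tolerated and treated as rate 0 (for
    ``C9``, as days on which the state does not advance).
    """
    spec = get_spec(model_id)
    start, end, n_days = resolve_window(window)
    t_mean, t_max, t_min = series.slice_arrays(start, end)
    missing = _window_missing(spec, t_mean, t_max, t_min)
    n_missing = int(missing.sum())
    if n_missing > max_missing_frac * n_days:
        raise QualityError(
            f"{n_missing}/{n_days} missing days in {start.date()}..{end.date()} "
            f"for {series.location_id} exceed tolerance {max_missing_frac}"
        )
    if spec.kind == "chilling":
        cum = cumulative_chill(model_id, t_mean)
    else:
        cum = cumulative_forcing(model_id, t_mean, t_max, t_min)
    return AccumulationResult(float(cum[-1]), model_id, window, n_days, n_missing)


def ca_hr_for_record(
    record: PhenoRecord,
    series: DailySeries,
    chilling_ids: Sequence[str] = CHILLING_IDS,
    forcing_ids: Sequence[str] = ("F1",),
    hr_start: str = "jan1",
    *,
    max_missing_frac: float = 0.0,
) -> CAHRRecord:
    """CA (1 Nov prev year -> onset) and HR (``hr_start`` -> onset) for one event."""
    ca_window = SeasonWindow("nov1_prev_year", "onset_date", record.year, record.onset_doy)
    hr_window = SeasonWindow(hr_start, "onset_date", record.year, record.onset_doy)
    ca, hr = {}, {}
    try:
        for mid in chilling_ids:
            ca[mid] = accumulate(
                series, mid, ca_window, max_missing_frac=max_missing_frac
            ).value
        for mid in forcing_ids:
            hr[mid] = accumulate(
                series, mid, hr_window, max_missing_frac=max_missing_frac
            ).value
    except (CoverageError, QualityError) as err:
        raise type(err)(
            f"record ({record.station_id}, {record.species}, {record.year}): {err}"
        ) from err
    return CAHRRecord(record, ca, hr)


def ca_column(model_id: str) -> str:
    return f"ca_{model_id}"


def hr_column(model_id: str) -> str:
    return f"hr_{model_id}"


def build_cahr_table(
    records: pd.DataFrame,
    series_by_station: Mapping[str, DailySeries],
    chilling_ids: Sequence[str] = CHILLING_IDS,
    forcing_ids: Sequence[str] = ("F1",),
    hr_start: str = "jan1",
    *,
    max_missing_frac: float = 0.0,
    errors: str = "drop",
) -> tuple[pd.DataFrame, int]:
    """Tabulate CA and HR for a frame of phenological records.

    ``records`` needs columns ``station_id, species, bbch, year,
    onset_doy``.  Returns the augmented table (one ``ca_*`` column per
    chilling model, one ``hr_*`` per forcing model, plus station
    coordinates) and the count of records dropped for coverage/quality
    reasons (``errors="drop"``) — with ``errors="raise"`` the first
    failure propagates.
    """
    if errors not in ("drop", "raise"):
        raise ValueError("errors must be 'drop' or 'raise'")
    rows = []
    n_dropped = 0
    for rec in records.itertuples(index=False):
        series = series_by_station[str(rec.station_id)]
        pr = PhenoRecord(
            str(rec.station_id), str(rec.species), int(rec.bbch), int(rec.year),
            int(rec.onset_doy),
        )
        try:
            cahr = ca_hr_for_record(
                pr, series, chilling_ids, forcing_ids, hr_start,
                max_missing_frac=max_missing_frac,
            )
        except (CoverageError, QualityError):
            if errors == "raise":
                raise
            n_dropped += 1
            continue
        row = {
            "station_id": pr.station_id,
            "species": pr.species,
            "bbch": pr.bbch,
            "year": pr.year,
            "onset_doy": pr.onset_doy,
            "lat": series.lat,
            "lon": series.lon,
            "alt": series.alt,
        }
        row.update({ca_column(m): v for m, v in cahr.ca.items()})
        row.update({hr_column(m): v for m, v in cahr.hr.items()})
        rows.append(row)
    return pd.DataFrame(rows), n_dropped
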