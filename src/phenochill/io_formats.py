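"""File formats and station matching.

Phenology files are PEP725-like CSVs with header
``station_id, species, bbch, year, doy`` (day-of-year is 1-based);
station tables carry ``station_id, lat, lon, alt``.  Temperature comes
either from a per-station CSV (``date, tmean, tmax, tmin``, ISO-8601
dates) or from a gridded NetCDF-style file with CF-like
``time``/``lat``/``lon`` dimensions (read and written through xarray;
nearest-cell extraction uses great-circle distance with a deterministic
tie-break toward the lower flat index).

Readers reject rows violating the type invariants rather than silently
coercing, and report the rejection count.

Station matching follows the strict rule used to pair phenological and
meteorological stations: nearest met station at distance < 5 km *and*
altitude difference < 100 m, else unmatched.  Distances are haversine
great-circle on a spherical Earth, R = 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .accumulation import DailySeries, PhenoRecord

__all__ = [
    "PhenologyReadReport",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "read_phenology",
    "write_phenology",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_temperature_grid",
    "series_to_grid",
    "write_temperature_grid",
    "validate_station_table",
    "match_stations",
]

EARTH_RADIUS_KM = 6371.0

PHENO_COLUMNS = ["station_id", "species", "bbch", "year", "doy"]


@dataclass(frozen=True)
class PhenologyReadReport:
    """Accepted records plus a count (and copy) of rejected rows."""

    records: pd.DataFrame
    n_rejected: int
    rejected: pd.DataFrame


def read_phenology(path) -> PhenologyReadReport:
    """Read a phenology CSV, rejecting invalid rows with a report.

    Valid rows have BBCH in {10, 11, 60, 69} and 1 <= doy <= 366.  The
    returned frame uses the internal column name ``onset_doy``.
    """
    raw = pd.read_csv(path, comment="#")
    missing = [c for c in PHENO_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"phenology CSV missing columns {missing}")
    bbch = pd.to_numeric(raw["bbch"], errors="coerce")
    year = pd.to_numeric(raw["year"], errors="coerce")
    doy = pd.to_numeric(raw["doy"], errors="coerce")
    ok = (
        bbch.isin(PhenoRecord.ALLOWED_BBCH)
        & year.notna()
        & doy.between(1, 366)
    )
    records = raw.loc[ok].copy()
    records["bbch"] = bbch[ok].astype(int)
    records["year"] = year[ok].astype(int)
    records["onset_doy"] = doy[ok].astype(int)
    records["station_id"] = records["station_id"].astype(str)
    records = records.drop(columns=["doy"]).reset_index(drop=True)
    rejected = raw.loc[~ok].reset_index(drop=True)
    return PhenologyReadReport(records, int((~ok).sum()), rejected)


def write_phenology(records: pd.DataFrame, path) -> None:
    """Write records (internal ``onset_doy`` naming) to the CSV dialect."""
    out = records[["station_id", "species", "bbch", "year", "onset_doy"]].rename(
        columns={"onset_doy": "doy"}
    )
    out.to_csv(path, index=False)


def read_temperature_csv(
    path, location_id: str | None = None, lat=np.nan, lon=np.nan, alt=np.nan
) -> DailySeries:
    """Read a station temperature CSV (date, tmean[, tmax, tmin])."""
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    if "tmean" not in df.columns:
        raise ValueError("temperature CSV needs a 'tmean' column")
    df = df.sort_values("date")
    return DailySeries(
        location_id=location_id or Path(str(path)).stem,
        lat=float(lat),
        lon=float(lon),
        alt=float(alt),
        dates=pd.DatetimeIndex(df["date"]),
        t_mean=df["tmean"].to_numpy(dtype=float),
        t_max=df["tmax"].to_numpy(dtype=float) if "tmax" in df.columns else None,
        t_min=df["tmin"].to_numpy(dtype=float) if "tmin" in df.columns else None,
    )


def write_temperature_csv(series: DailySeries, path) -> None:
    series.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(h))


def series_to_grid(series_list) -> xr.Dataset:
    """Stack per-location series sharing a calendar into a lat/lon grid.

    Locations are snapped onto the dataset's (lat, lon) coordinate
    axes; intended for synthetic grids where each location occupies its
    own cell.
    """
    if not series_list:
        raise ValueError("need at least one series")
    dates = series_list[0].dates
    lats = sorted({round(s.lat, 6) for s in series_list})
    lons = sorted({round(s.lon, 6) for s in series_list})
    shape = (len(dates), len(lats), len(lons))
    data = {v: np.full(shape, np.nan) for v in ("tmean", "tmax", "tmin")}
    for s in series_list:
        if not s.dates.equals(dates):
            raise ValueError("all series must share the same calendar")
        i = lats.index(round(s.lat, 6))
        j = lons.index(round(s.lon, 6))
        data["tmean"][:, i, j] = s.t_mean
        if s.t_max is not None:
            data["tmax"][:, i, j] = s.t_max
        if s.t_min is not None:
            data["tmin"][:, i, j] = s.t_min
    return xr.Dataset(
        {v: (("time", "lat", "lon"), a) for v, a in data.items()},
        coords={"time": dates, "lat": lats, "lon": lons},
    )


def write_temperature_grid(dataset: xr.Dataset, path) -> None:
    """Write a gridded dataset as NetCDF3 (scipy engine)."""
    dataset.to_netcdf(path, engine="scipy")


def read_temperature_grid(
    source, lat: float, lon: float, location_id: str = "cell", alt: float = np.nan
) -> DailySeries:
    """Extract the nearest grid cell to (lat, lon) as a :class:`DailySeries`.

    ``source`` is a path to a NetCDF-style file or an open
    :class:`xarray.Dataset` with ``time``/``lat``/``lon`` dimensions and
    a ``tmean`` variable (``tmax``/``tmin`` optional).  Nearest cell by
    great-circle distance; exact ties resolve to the lower flat index
    (lat-major ordering).
    """
    ds = source if isinstance(source, xr.Dataset) else xr.open_dataset(source)
    glat = ds["lat"].to_numpy()
    glon = ds["lon"].to_numpy()
    lat2d, lon2d = np.meshgrid(glat, glon, indexing="ij")
    dist = haversine_km(lat, lon, lat2d, lon2d)
    i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
    tmean = ds["tmean"].isel(lat=i, lon=j).to_numpy().astype(float)
    out = DailySeries(
        location_id=location_id,
        lat=float(glat[i]),
        lon=float(glon[j]),
        alt=float(alt),
        dates=pd.DatetimeIndex(ds["time"].to_numpy()),
        t_mean=tmean,
        t_max=ds["tmax"].isel(lat=i, lon=j).to_numpy().astype(float)
        if "tmax" in ds
        else None,
        t_min=ds["tmin"].isel(lat=i, lon=j).to_numpy().astype(float)
        if "tmin" in ds
        else None,
    )
    if not isinstance(source, xr.Dataset):
        ds.close()
    return out


def validate_station_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a station table (unique ids, coordinates in range)."""
    required = {"station_id", "lat", "lon", "alt"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"station table missing columns {sorted(missing)}")
    if table["station_id"].duplicated().any():
        raise ValueError("duplicate station_id in station table")
    if not table["lat"].between(-90, 90).all():
        raise ValueError("lat outside [-90, 90]")
    if not table["lon"].between(-180, 180).all():
        raise ValueError("lon outside [-180, 180]")
    out = table.copy()
    out["station_id"] = out["station_id"].astype(str)
    return out


def match_stations(
    pheno: pd.DataFrame,
    met: pd.DataFrame,
    max_dist_km: float = 5.0,
    max_alt_diff_m: float = 100.0,
) -> pd.DataFrame:
    """Match each phenological station to its nearest qualifying met station.

    Both thresholds are strict (< 5 km and < 100 m); a station with no
    qualifying met neighbour appears with ``met_id`` = NA.  Matching is
    deterministic under fixed input order (distance ties resolve to the
    first met row).
    """
    pheno = validate_station_table(pheno)
    met = validate_station_table(met)
    rows = []
    met_lat = met["lat"].to_numpy(dtype=float)
    met_lon = met["lon"].to_numpy(dtype=float)
    met_alt = met["alt"].to_numpy(dtype=float)
    met_ids = met["station_id"].to_numpy()
    for rec in pheno.itertuples(index=False):
        dist = haversine_km(rec.lat, rec.lon, met_lat, met_lon)
        alt_diff = np.abs(met_alt - rec.alt)
        ok = (dist < max_dist_km) & (alt_diff < max_alt_diff_m)
        if ok.any():
            cand = np.flatnonzero(ok)
            best = cand[np.argmin(dist[cand])]
            rows.append(
                {
                    "pheno_id": rec.station_id,
                    "met_id": met_ids[best],
                    "distance_km": float(dist[best]),
                    "alt_diff_m": float(alt_diff[best]),
                }
            )
        else:
            rows.append(
                {
                    "pheno_id": rec.station_id,
                    "met_id": pd.NA,
                    "distance_km": float("nan"),
                    "alt_diff_m": float("nan"),
                }
            )
    return pd.DataFrame(rows)
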