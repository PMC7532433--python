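"""Synthetic daily climate and mechanism-driven phenology generation.

The climate generator emulates Central-European daily mean temperature
as a seasonal cycle (annual mean ~9 degC, amplitude ~9 degC, coldest
day in mid-January) plus stationary AR(1) Gaussian noise and a secular
warming ramp; daily max/min are the mean plus/minus a constant diurnal
half-range.  The seasonal cycle is a *saturated* cosine,

    g(theta) = clip(s * cos(theta), -1, 1),

which for ``plateau_sharpness`` s > 1 produces the characteristic
Central-European shape of a long, flat winter plateau (Dec-Feb all near
the minimum) and a fast spring/autumn transition; s = 1 recovers a pure
sinusoid.  The plateau shape matters scientifically: the contrast
between chilling models that do and do not count freezing days rests on
winters spending many days just below 0 degC with a short transit
through the 2-8 degC band, which a slow sinusoidal dip does not emulate.

Locations are independent draws with a random offset of their annual
mean (maritime-warm vs cold stations) *and* a random seasonal amplitude
(``amplitude_spread``, the maritime-continental gradient: mild-winter
west vs cold-winter east), plus randomised coordinates within a
Central-European box.  ``noise_sd`` is the *stationary* (marginal)
standard deviation of the AR(1) noise; innovations are scaled by
``sqrt(1 - phi^2)`` accordingly.

The phenology generator inverts the onset rule: onset dates are
produced by the deterministic CA–HR threshold simulation under a known
mechanism (chilling model, forcing model, true intercept/slope) on the
noise-bearing climate, then jittered by a rounded normal observation
error.  Because the generating mechanism is explicit, downstream
analyses (trend classes, validity verdicts, parameter recovery,
projection contrasts) have known ground truth.

Presets:

* ``central_europe_historical`` — 1951–2018, warming 0.025 degC/yr
  (0.25 degC/decade, the observed Central-European winter rate).
* ``rcp45_like`` — 2006–2099, ramp of 0.034 degC/yr flattening after
  2065 (about +2 degC total), a moderate-pathway shape.
* ``rcp85_like`` — 2006–2099, monotone ramp of 0.048 degC/yr (about
  +4.5 degC by 2099), a high-pathway shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .accumulation import DailySeries
from .phenology_model import PhenoModelParams, predict_onset

__all__ = [
    "ClimateScenario",
    "MechanismSpec",
    "PRESET_NAMES",
    "generate_temperature",
    "generate_phenology",
    "preset",
    "valid_mechanism_scenario",
]

PRESET_NAMES = ("central_europe_historical", "rcp45_like", "rcp85_like")

_AR_BURN_IN = 200  # days discarded so the AR(1) state is stationary


@dataclass(frozen=True)
class ClimateScenario:
    """Parameters of one synthetic daily-temperature experiment."""

    n_locations: int = 100
    year_start: int = 1951
    year_end: int = 2018
    annual_mean: float = 9.0  # degC
    seasonal_amplitude: float = 9.0  # degC
    coldest_day: int = 15  # day-of-year of the seasonal minimum
    plateau_sharpness: float = 2.0  # cosine saturation; 1.0 = pure sinusoid
    ar1_phi: float = 0.7
    noise_sd: float = 3.0  # stationary SD of the AR(1) noise, degC
    warming_rate: float = 0.025  # degC per year
    warming_stop_year: int | None = None  # ramp flattens after this year
    winter_warming_weight: float = 1.0  # multiplier on warming in Nov-Feb
    diurnal_half_range: float = 5.0  # degC
    location_spread: float = 2.0  # degC, uniform offset of location means
    amplitude_spread: float = 2.5  # degC, uniform spread of location amplitudes
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        if self.n_locations < 1:
            raise ValueError("need at least one location")
        if self.plateau_sharpness < 1.0:
            raise ValueError("plateau_sharpness must be >= 1")
        if self.amplitude_spread < 0 or self.location_spread < 0:
            raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class MechanismSpec:
    """Ground-truth CA–HR mechanism generating onset dates."""

    chilling_model: str = "C1"
    forcing_model: str = "F1"
    a_true: float = 600.0
    b_true: float = -2.0
    obs_noise_sd: float = 2.0  # days
    seed: int = 0

    def __post_init__(self):
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")


def generate_temperature(scenario: ClimateScenario) -> list[DailySeries]:
    """Generate one :class:`DailySeries` per location for a scenario.

    Reproducible: the same scenario (including seed) yields bitwise
    identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    dates = pd.date_range(
        f"{scenario.year_start}-01-01", f"{scenario.year_end}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()
    shape = np.clip(
        scenario.plateau_sharpness
        * np.cos(2.0 * np.pi * (doy - scenario.coldest_day) / 365.25),
        -1.0,
        1.0,
    )
    warm_years = years.astype(float)
    if scenario.warming_stop_year is not None:
        warm_years = np.minimum(warm_years, float(scenario.warming_stop_year))
    warming = scenario.warming_rate * (warm_years - scenario.year_start)
    if scenario.winter_warming_weight != 1.0:
        months = dates.month.to_numpy()
        winter = (months >= 11) | (months <= 2)
        warming = warming * np.where(winter, scenario.winter_warming_weight, 1.0)

    innov_sd = scenario.noise_sd * np.sqrt(1.0 - scenario.ar1_phi ** 2)
    n = len(dates)
    out = []
    for i in range(scenario.n_locations):
        offset = rng.uniform(-scenario.location_spread, scenario.location_spread)
        amplitude = rng.uniform(
            scenario.seasonal_amplitude - scenario.amplitude_spread,
            scenario.seasonal_amplitude + scenario.amplitude_spread,
        )
        lat = rng.uniform(46.5, 54.5)
        lon = rng.uniform(6.0, 16.0)
        alt = rng.uniform(50.0, 600.0)
        innov = rng.normal(0.0, innov_sd, n + _AR_BURN_IN)
        noise = lfilter([1.0], [1.0, -scenario.ar1_phi], innov)[_AR_BURN_IN:]
        t_mean = scenario.annual_mean - amplitude * shape + warming + offset + noise
        out.append(
            DailySeries(
                location_id=f"S{i:04d}",
                lat=float(lat),
                lon=float(lon),
                alt=float(alt),
                dates=dates,
                t_mean=t_mean,
                t_max=t_mean + scenario.diurnal_half_range,
                t_min=t_mean - scenario.diurnal_half_range,
            )
        )
    return out


def generate_phenology(
    series_list: Sequence[DailySeries],
    mech: MechanismSpec,
    species: str = "Betula pendula",
    bbch: int = 11,
    years: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Onset records from the ground-truth mechanism, plus dropped-year count.

    For each location and event year the onset is simulated under
    ``(a_true, b_true)`` with the mechanism's chilling/forcing models,
    then jittered by rounding a normal perturbation of SD
    ``obs_noise_sd`` days (clipped to DOY >= 1).  Years whose threshold
    is never reached (sentinel) are dropped and counted.
    """
    params = PhenoModelParams(
        mech.chilling_model, mech.forcing_model, mech.a_true, mech.b_true
    )
    rng = np.random.default_rng(mech.seed)
    rows = []
    n_dropped = 0
    for series in series_list:
        if years is None:
            yrs = range(series.start.year + 1, series.end.year + 1)
        else:
            yrs = years
        for year in yrs:
            doy = predict_onset(params, series, int(year))
            if doy is None:
                n_dropped += 1
                continue
            if mech.obs_noise_sd > 0:
                doy = int(round(doy + rng.normal(0.0, mech.obs_noise_sd)))
                doy = max(doy, 1)
            rows.append(
                {
                    "station_id": series.location_id,
                    "species": species,
                    "bbch": bbch,
                    "year": int(year),
                    "onset_doy": int(doy),
                    "lat": series.lat,
                    "lon": series.lon,
                    "alt": series.alt,
                }
            )
    return pd.DataFrame(rows), n_dropped


def preset(name: str) -> ClimateScenario:
    """Named, fully populated scenario with fixed default seed."""
    if name == "central_europe_historical":
        return ClimateScenario(
            n_locations=200,
            year_start=1951,
            year_end=2018,
            warming_rate=0.025,
            seed=202,
            name=name,
        )
    if name == "rcp45_like":
        return ClimateScenario(
            n_locations=50,
            year_start=2006,
            year_end=2099,
            warming_rate=0.034,
            warming_stop_year=2065,
            seed=451,
            name=name,
        )
    if name == "rcp85_like":
        return ClimateScenario(
            n_locations=50,
            year_start=2006,
            year_end=2099,
            warming_rate=0.048,
            seed=851,
            name=name,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def valid_mechanism_scenario(
    seed: int = 42,
    n_locations: int = 100,
    n_years: int = 60,
) -> tuple[ClimateScenario, MechanismSpec]:
    """The valid-mechanism study conditions used throughout the tests.

    A Central-European-like warming climate (warming 0.04 degC/yr,
    winter plateau near 0-1 degC, maritime-continental amplitude
    gradient) with onset dates generated by a negative C1-based CA–HR
    rule (HR = 600 - 2 * CA(C1)) plus 2-day observation noise.  Under
    these conditions the freezing-inclusive chilling models track the
    mechanism while the freezing-excluding ones see *increasing*
    chilling as winters warm, reproducing the valid/invalid partition
    of the twelve models.
    """
    scenario = ClimateScenario(
        n_locations=n_locations,
        year_start=1959,
        year_end=1959 + n_years - 1,
        annual_mean=9.0,
        seasonal_amplitude=9.0,
        coldest_day=15,
        ar1_phi=0.7,
        noise_sd=3.0,
        warming_rate=0.04,
        seed=seed,
        name="valid_mechanism",
    )
    mech = MechanismSpec(
        chilling_model="C1",
        forcing_model="F1",
        a_true=600.0,
        b_true=-2.0,
        obs_noise_sd=2.0,
        seed=seed + 1,
    )
    return scenario, mech
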