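"""Potential evapotranspiration (PET) and the climatic water balance.

The default PET is the FAO-56 Penman-Monteith reference evapotranspiration
(Allen et al. 1998), whose input list — maximum/minimum temperature, dew
point, wind speed, solar radiation, air pressure, latitude and elevation —
is exactly what a reanalysis-driven drought index needs.  A
temperature-only Hargreaves-Samani estimate is available as a fallback when
humidity, wind or radiation are missing.

All functions are vectorised over numpy arrays; scalars work too.  Monthly
totals are the daily reference value scaled by the (leap-aware) number of
days in the month.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "CellMonthMet",
    "pet_penman_monteith",
    "pet_hargreaves",
    "water_balance",
    "extraterrestrial_radiation",
    "days_in_month",
]

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1 (FAO-56).
STEFAN_BOLTZMANN = 4.903e-9
#: Albedo of the reference grass surface.
ALBEDO = 0.23


@dataclass(frozen=True)
class CellMonthMet:
    """Meteorology of one grid cell in one calendar month.

    Units: precip mm/month; temperatures degC; wind m/s (at ``wind_height``
    m above ground); solar MJ m-2 day-1; pressure kPa; latitude degrees;
    elevation m.  ``year``/``month`` locate the month in the calendar
    (month is 1-12).
    """

    precip: float
    tmax: float
    tmin: float
    tdew: float
    wind: float
    solar: float
    pressure: float
    latitude: float
    elevation: float
    year: int
    month: int
    wind_height: float = 10.0


def days_in_month(year, month):
    """Gregorian days in month, leap-aware; vectorised."""
    year = np.asarray(year)
    month = np.asarray(month)
    base = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    days = base[month.astype(int) - 1].astype(float)
    leap = (year % 4 == 0) & ((year % 100 != 0) | (year % 400 == 0))
    return np.where((month == 2) & leap, 29.0, days)


def _mid_month_doy(month):
    """Day of year of the (non-leap) mid-month day, per FAO-56 practice."""
    cum = np.concatenate(([0], np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30])))
    month = np.asarray(month).astype(int)
    mid = cum[month - 1] + 15
    return mid.astype(float)


def _sat_vapour_pressure(t):
    """Saturation vapour pressure (kPa) at temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(latitude, month):
    """Extraterrestrial radiation Ra (MJ m-2 day-1) at the mid-month day.

    Standard FAO-56 astronomy: inverse relative Earth-Sun distance,
    solar declination, and the sunset hour angle (clipped for polar
    day/night).
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    j = _mid_month_doy(month)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def _wind_at_2m(wind, height):
    """Log-profile conversion of wind speed to the 2 m reference height."""
    height = np.asarray(height, dtype=float)
    factor = np.where(
        np.isclose(height, 2.0), 1.0, 4.87 / np.log(67.8 * height - 5.42)
    )
    return np.asarray(wind) * factor


def _validate_finite(**fields):
    for name, value in fields.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite values in '{name}'")


def pet_penman_monteith(
    tmax,
    tmin,
    tdew,
    wind,
    solar,
    pressure,
    latitude,
    year,
    month,
    elevation=0.0,
    wind_height=10.0,
):
    """FAO-56 Penman-Monteith reference evapotranspiration, mm/month.

    Parameters are as in :class:`CellMonthMet`; all broadcastable arrays.
    The full FAO-56 chain is applied: psychrometric constant from air
    pressure, slope of the saturation curve at the mean temperature,
    actual vapour pressure from dew point, net shortwave radiation with
    grass albedo, net longwave radiation bounded by clear-sky radiation
    (relative shortwave ratio clipped to [0.3, 1]), soil heat flux taken
    as zero on the monthly timescale, and the aerodynamic term with wind
    converted to 2 m.  The daily reference value is clipped at zero and
    scaled by the number of days in the month.

    Raises
    ------
    ValidationError
        If any input is non-finite, ``tmax < tmin``, or latitude is
        outside [-90, 90].
    """
    _validate_finite(
        tmax=tmax, tmin=tmin, tdew=tdew, wind=wind, solar=solar,
        pressure=pressure, latitude=latitude,
    )
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValidationError("tmax < tmin")
    lat = np.asarray(latitude, dtype=float)
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValidationError("latitude outside [-90, 90]")
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= 0):
        raise ValidationError("pressure must be positive")

    tmean = (tmax + tmin) / 2.0
    delta = 4098.0 * _sat_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    gamma = 0.000665 * pressure
    es = (_sat_vapour_pressure(tmax) + _sat_vapour_pressure(tmin)) / 2.0
    ea = _sat_vapour_pressure(np.asarray(tdew, dtype=float))
    u2 = _wind_at_2m(wind, wind_height)

    ra = extraterrestrial_radiation(lat, month)
    elev = np.asarray(elevation, dtype=float)
    rso = (0.75 + 2e-5 * elev) * ra
    rs = np.asarray(solar, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, rs / rso, 0.3)
    rel = np.clip(rel, 0.3, 1.0)
    rns = (1.0 - ALBEDO) * rs
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
    rnl = (
        STEFAN_BOLTZMANN
        * tk4
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0_daily = np.maximum(num / den, 0.0)
    return et0_daily * days_in_month(year, month)


def pet_hargreaves(tmax, tmin, tmean, latitude, year, month):
    """Hargreaves-Samani reference evapotranspiration, mm/month.

    ``ET0 = 0.0023 * 0.408 * Ra * (tmean + 17.8) * sqrt(tmax - tmin)`` in
    mm/day, scaled by days in month and clipped at zero.  Needs only
    temperatures, latitude and the calendar position.
    """
    _validate_finite(tmax=tmax, tmin=tmin, tmean=tmean, latitude=latitude)
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValidationError("tmax < tmin")
    lat = np.asarray(latitude, dtype=float)
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValidationError("latitude outside [-90, 90]")
    ra_mm = 0.408 * extraterrestrial_radiation(lat, month)
    et0_daily = 0.0023 * ra_mm * (np.asarray(tmean, dtype=float) + 17.8) * np.sqrt(
        tmax - tmin
    )
    et0_daily = np.maximum(et0_daily, 0.0)
    return et0_daily * days_in_month(year, month)


def pet_from_met(met: CellMonthMet) -> float:
    """Penman-Monteith PET for one :class:`CellMonthMet` record."""
    return float(
        pet_penman_monteith(
            met.tmax, met.tmin, met.tdew, met.wind, met.solar, met.pressure,
            met.latitude, met.year, met.month, elevation=met.elevation,
            wind_height=met.wind_height,
        )
    )


def water_balance(precip, pet):
    """Climatic water balance D = precipitation - PET, mm/month.

    May be negative; shape and missing pattern follow the inputs.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    bad = ~(np.isfinite(precip) | np.isnan(precip)) | ~(np.isfinite(pet) | np.isnan(pet))
    if np.any(bad):
        raise ValidationError("infinite values in water-balance inputs")
    return precip - pet
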