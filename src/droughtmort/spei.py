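"""Standardized Precipitation-Evapotranspiration Index (SPEI).

The index turns a monthly climatic water-balance series (precipitation
minus potential evapotranspiration) into a dimensionless z-scale anomaly:

1. accumulate the balance over the preceding ``k`` months (default 24,
   i.e. SPEI-24: the current month plus the 23 before it);
2. for each of the 12 calendar months separately, fit a three-parameter
   log-logistic distribution to the accumulated values by unbiased
   probability-weighted moments (PWM); fitting per calendar month removes
   the local seasonal cycle as well as the local climate mean;
3. map each value through the fitted CDF and the standard-normal inverse
   CDF, so that over the calibration period the index has mean ~0 and
   standard deviation ~1.

Drought classes follow the MeteoSwiss-style severity cut-offs used
throughout the pipeline: any drought SPEI <= -0.5, mild drought
-1.3 < SPEI <= -0.5, severe drought SPEI <= -1.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import xarray as xr
from scipy import special, stats

from .errors import (
    DegenerateSampleError,
    FitFailureError,
    InsufficientCalibrationError,
    InsufficientSeriesError,
    ValidationError,
)
from . import pet as _pet

__all__ = [
    "accumulate",
    "fit_loglogistic_pwm",
    "loglogistic_cdf",
    "standardize",
    "classify",
    "spei_pipeline",
    "LogLogisticParams",
    "SpeiConfig",
    "CLASS_NONE",
    "CLASS_MILD",
    "CLASS_SEVERE",
    "CLASS_MISSING",
]

#: Integer drought-class codes used in tables and NetCDF output.
CLASS_MISSING = -1
CLASS_NONE = 0
CLASS_MILD = 1
CLASS_SEVERE = 2

ANY_THRESHOLD = -0.5
SEVERE_THRESHOLD = -1.3


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic fit, F(x) = [1 + (alpha/(x-gamma))^beta]^-1.

    ``alpha`` is the scale, ``beta`` the shape (must exceed 1 for the PWM
    moment equations to be valid), ``gamma`` the origin; ``n`` records the
    fitted sample size (used for the probability floor/cap).
    """

    alpha: float
    beta: float
    gamma: float
    n: int
    calendar_month: Optional[int] = None
    reflected: bool = False


def accumulate(d, k: int = 24):
    """Sliding inclusive sum of the water balance over ``k`` months.

    ``X_k[t] = sum(D[t-k+1 .. t])``; the first ``k-1`` entries are NaN.
    ``k=1`` is the identity.  Works on 1-d series or on arrays whose
    first axis is time.
    """
    d = np.asarray(d, dtype=float)
    if k < 1:
        raise ValidationError("timescale k must be >= 1")
    if d.shape[0] < k:
        raise InsufficientSeriesError(
            f"series length {d.shape[0]} shorter than timescale k={k}"
        )
    csum = np.cumsum(d, axis=0)
    out = np.full_like(d, np.nan)
    out[k - 1] = csum[k - 1]
    if d.shape[0] > k:
        out[k:] = csum[k:] - csum[:-k]
    return out


def _pwm_unbiased(sorted_sample):
    """Unbiased (Hosking) probability-weighted moments b0, b1, b2.

    ``sorted_sample`` is ascending along the first axis; extra axes are
    broadcast (one sample per trailing index).
    """
    x = np.asarray(sorted_sample, dtype=float)
    n = x.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    w1 = (i - 1) / (n - 1)
    w2 = w1 * (i - 2) / (n - 2)
    shape = (n,) + (1,) * (x.ndim - 1)
    b0 = x.mean(axis=0)
    b1 = (x * w1.reshape(shape)).sum(axis=0) / n
    b2 = (x * w2.reshape(shape)).sum(axis=0) / n
    return b0, b1, b2


def _loglogistic_from_pwm(b0, b1, b2):
    """Log-logistic (alpha, beta, gamma) from PWMs; invalid fits -> NaN.

    Takes the F-type moments ``b_r = E[X F(X)^r]`` and converts to the
    (1-F)-type moments ``w_r = E[X (1-F)^r]`` the log-logistic moment
    equations are written in (w0 = b0, w1 = b0 - b1, w2 = b0 - 2b1 + b2).
    """
    w0 = b0
    w1 = b0 - b1
    w2 = b0 - 2.0 * b1 + b2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (2.0 * w1 - w0) / (6.0 * w1 - w0 - 6.0 * w2)
        valid = np.asarray(beta > 1.0)
        beta_safe = np.where(valid, beta, 2.0)
        g1 = special.gamma(1.0 + 1.0 / beta_safe)
        g2 = special.gamma(1.0 - 1.0 / beta_safe)
        alpha = (w0 - 2.0 * w1) * beta_safe / (g1 * g2)
        gamma = w0 - alpha * g1 * g2
    alpha = np.where(valid & (alpha > 0), alpha, np.nan)
    beta = np.where(valid, beta, np.nan)
    gamma = np.where(np.isfinite(alpha), gamma, np.nan)
    return alpha, beta, gamma


def fit_loglogistic_pwm(sample, calendar_month: Optional[int] = None) -> LogLogisticParams:
    """Fit the three-parameter log-logistic by unbiased PWMs.

    Raises
    ------
    DegenerateSampleError
        For samples with zero variance or fewer than 10 values.
    FitFailureError
        If the implied shape parameter is not positive (or does not
        exceed 1, where the PWM moment relations break down) or the
        scale is not positive.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateSampleError(f"need >= 10 values, got {x.size}")
    if np.var(x) == 0.0:
        raise DegenerateSampleError("zero-variance sample")
    b0, b1, b2 = _pwm_unbiased(np.sort(x))
    w0, w1, w2 = b0, b0 - b1, b0 - 2.0 * b1 + b2
    raw_beta = (2.0 * w1 - w0) / (6.0 * w1 - w0 - 6.0 * w2)
    if not np.isfinite(raw_beta) or raw_beta <= 0:
        raise FitFailureError(f"non-positive shape parameter beta={raw_beta:.4g}")
    alpha, beta, gamma = _loglogistic_from_pwm(b0, b1, b2)
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise FitFailureError(
            f"invalid log-logistic fit (beta={raw_beta:.4g} must exceed 1, alpha > 0)"
        )
    return LogLogisticParams(float(alpha), float(beta), float(gamma), int(x.size),
                             calendar_month)


def loglogistic_cdf(x, params: LogLogisticParams):
    """CDF of the fitted (possibly reflected) log-logistic.

    Direct fit: 0 for x <= gamma.  A reflected fit (used for
    left-skewed samples, where no direct log-logistic exists) stores the
    parameters of the distribution of -X; its CDF is 1 - F_r(-x).
    """
    x = np.asarray(x, dtype=float)
    arg = -x if params.reflected else x
    z = arg - params.gamma
    out = np.zeros_like(x, dtype=float)
    pos = z > 0
    out[pos] = 1.0 / (1.0 + (params.alpha / z[pos]) ** params.beta)
    if params.reflected:
        out = 1.0 - out
    out[~np.isfinite(x)] = np.nan
    return out


def _spei_from_cdf(prob, n):
    """Normal quantile with the 1/(2n) probability floor/cap applied."""
    floor = 1.0 / (2.0 * n)
    clipped = np.clip(prob, floor, 1.0 - floor)
    return stats.norm.ppf(clipped)


def standardize(x_acc, calibration=None, min_per_month: int = 10):
    """Standardize an accumulated series to SPEI values, per calendar month.

    Parameters
    ----------
    x_acc : 1-d array
        Accumulated water balance; NaN for undefined leading months.  The
        series is assumed to start at calendar-month phase 0 (whatever
        month the caller's index origin is) and to advance one month per
        entry; phase is taken modulo 12.
    calibration : (start, stop) month-index interval, optional
        Half-open slice of the series used for fitting; default the full
        series.
    min_per_month : int
        Minimum defined calibration values per calendar month (>= 10).

    Returns
    -------
    values : ndarray of SPEI (NaN where the input is NaN)
    params : list of 12 LogLogisticParams (by calendar phase)
    """
    x = np.asarray(x_acc, dtype=float)
    t = np.arange(x.size)
    if calibration is None:
        cal_mask = np.ones(x.size, dtype=bool)
    else:
        start, stop = calibration
        cal_mask = (t >= start) & (t < stop)
    values = np.full_like(x, np.nan)
    params_by_month = []
    for phase in range(12):
        sel = (t % 12) == phase
        cal = x[sel & cal_mask]
        cal = cal[np.isfinite(cal)]
        if cal.size < min_per_month:
            raise InsufficientCalibrationError(
                f"calendar phase {phase}: only {cal.size} calibration values "
                f"(need >= {min_per_month})"
            )
        try:
            params = fit_loglogistic_pwm(cal, calendar_month=phase)
        except FitFailureError:
            # left-skewed sample: fit the reflected series -X instead
            try:
                pr = fit_loglogistic_pwm(-cal, calendar_month=phase)
            except (DegenerateSampleError, FitFailureError) as exc:
                raise FitFailureError(f"calendar phase {phase}: {exc}") from exc
            params = LogLogisticParams(pr.alpha, pr.beta, pr.gamma, pr.n,
                                       phase, reflected=True)
        except DegenerateSampleError as exc:
            raise DegenerateSampleError(f"calendar phase {phase}: {exc}") from exc
        params_by_month.append(params)
        idx = sel & np.isfinite(x)
        values[idx] = _spei_from_cdf(loglogistic_cdf(x[idx], params), params.n)
    return values, params_by_month


def classify(spei_values):
    """Map SPEI values to integer drought classes.

    none (0) for SPEI > -0.5, mild (1) for -1.3 < SPEI <= -0.5, severe (2)
    for SPEI <= -1.3; NaN maps to missing (-1), never to a default class.
    """
    s = np.asarray(spei_values, dtype=float)
    out = np.full(s.shape, CLASS_MISSING, dtype=np.int8)
    defined = np.isfinite(s)
    out[defined & (s > ANY_THRESHOLD)] = CLASS_NONE
    out[defined & (s <= ANY_THRESHOLD) & (s > SEVERE_THRESHOLD)] = CLASS_MILD
    out[defined & (s <= SEVERE_THRESHOLD)] = CLASS_SEVERE
    if np.isscalar(spei_values) or np.ndim(spei_values) == 0:
        return int(out)
    return out


@dataclass(frozen=True)
class SpeiConfig:
    """Settings for the grid pipeline.

    ``k`` is the accumulation timescale in months; ``pet_method`` one of
    ``"penman_monteith"``, ``"hargreaves"`` or ``"none"`` (SPI mode,
    D = P); ``calibration`` an optional (start, stop) month-index window
    (default: full record); ``on_cell_error`` either ``"raise"`` or
    ``"mask"`` (failed cells become all-missing).
    """

    k: int = 24
    pet_method: str = "penman_monteith"
    calibration: Optional[tuple] = None
    min_months: int = 0
    on_cell_error: str = "raise"
    wind_height: float = 10.0


def _grid_pet(climate: xr.Dataset, config: SpeiConfig) -> np.ndarray:
    """PET field (time, lat, lon) for a climate grid, mm/month."""
    years = climate["time.year"].values[:, None, None]
    months = climate["time.month"].values[:, None, None]
    lat2d = np.broadcast_to(
        climate["lat"].values[:, None], (climate.sizes["lat"], climate.sizes["lon"])
    )
    if config.pet_method == "penman_monteith":
        return np.asarray(
            _pet.pet_penman_monteith(
                climate["tmax"].values, climate["tmin"].values,
                climate["tdew"].values, climate["wind"].values,
                climate["solar"].values, climate["pressure"].values,
                lat2d, years, months,
                elevation=climate["elevation"].values,
                wind_height=config.wind_height,
            )
        )
    if config.pet_method == "hargreaves":
        tmean = (climate["tmax"].values + climate["tmin"].values) / 2.0
        return np.asarray(
            _pet.pet_hargreaves(
                climate["tmax"].values, climate["tmin"].values, tmean,
                lat2d, years, months,
            )
        )
    if config.pet_method == "none":
        return np.zeros_like(climate["precip"].values)
    raise ValidationError(f"unknown pet_method {config.pet_method!r}")


def spei_pipeline(climate: xr.Dataset, config: SpeiConfig = SpeiConfig()) -> xr.Dataset:
    """Compute per-cell SPEI and drought classes for a climate grid.

    Expects the grid layout produced by :func:`droughtmort.synth.generate_climate`
    (variables precip/tmax/tmin/tdew/wind/solar/pressure over
    (time, lat, lon) plus static elevation).  Returns a Dataset with
    ``spei`` (float, NaN for the first k-1 months) and ``drought_class``
    (int8, -1 missing) and provenance attributes.

    The per-calendar-month log-logistic fits are vectorised across cells;
    a cell whose fit fails either aborts the run (``on_cell_error="raise"``,
    reporting coordinates) or is masked to all-missing.
    """
    n_time = climate.sizes["time"]
    min_required = config.min_months or (config.k + 120)
    if n_time < max(config.k, 1):
        raise InsufficientSeriesError(
            f"{n_time} months < timescale k={config.k}"
        )
    if config.min_months == 0 and n_time < min_required:
        raise InsufficientCalibrationError(
            f"{n_time} months < recommended {min_required} (k + 120); "
            "set min_months explicitly to override"
        )

    pet_field = _grid_pet(climate, config)
    d = _pet.water_balance(climate["precip"].values, pet_field)
    x_acc = accumulate(d, k=config.k)

    t = np.arange(n_time)
    month0 = int(climate["time.month"].values[0]) - 1
    phase = (t + month0) % 12
    if config.calibration is None:
        cal_mask = np.ones(n_time, dtype=bool)
    else:
        start, stop = config.calibration
        cal_mask = (t >= start) & (t < stop)

    spei_vals = np.full_like(x_acc, np.nan)
    nlat, nlon = x_acc.shape[1], x_acc.shape[2]
    failed = np.zeros((nlat, nlon), dtype=bool)
    for ph in range(12):
        sel = phase == ph
        cal_sel = sel & cal_mask
        sample = x_acc[cal_sel]                       # (n_cal, lat, lon)
        defined = np.isfinite(sample)
        n_def = defined.sum(axis=0)
        if np.any(n_def < 10):
            bad = np.argwhere(n_def < 10)[0]
            raise InsufficientCalibrationError(
                f"cell (lat={float(climate['lat'][bad[0]]):.2f}, "
                f"lon={float(climate['lon'][bad[1]]):.2f}), phase {ph}: "
                f"{int(n_def[bad[0], bad[1]])} calibration values < 10"
            )
        # sort with NaN pushed to the front so the defined tail is ascending
        filled = np.where(defined, sample, -np.inf)
        s = np.sort(filled, axis=0)
        n_cal = sample.shape[0]
        if np.any(n_def != n_cal):
            # ragged defined counts can only come from the leading k-1
            # window; restrict to the common defined tail
            n_min = int(n_def.min())
            s = s[n_cal - n_min:]
        b0, b1, b2 = _pwm_unbiased(s)
        alpha, beta, gamma = _loglogistic_from_pwm(b0, b1, b2)
        # left-skewed cells: reflected fit on -X (same normalization,
        # CDF becomes 1 - F_r(-x))
        need_reflect = ~np.isfinite(alpha)
        if np.any(need_reflect):
            rb0, rb1, rb2 = _pwm_unbiased(-s[::-1])
            ralpha, rbeta, rgamma = _loglogistic_from_pwm(rb0, rb1, rb2)
            alpha = np.where(need_reflect, ralpha, alpha)
            beta = np.where(need_reflect, rbeta, beta)
            gamma = np.where(need_reflect, rgamma, gamma)
        bad_fit = ~np.isfinite(alpha)
        if np.any(bad_fit):
            if config.on_cell_error == "raise":
                i, j = np.argwhere(bad_fit)[0]
                raise FitFailureError(
                    f"log-logistic fit failed at cell (lat="
                    f"{float(climate['lat'][i]):.2f}, "
                    f"lon={float(climate['lon'][j]):.2f}), phase {ph}"
                )
            failed |= bad_fit
        n_fit = s.shape[0]
        arg = np.where(need_reflect, -x_acc[sel], x_acc[sel])
        z = arg - gamma
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            prob = np.where(z > 0, 1.0 / (1.0 + (alpha / np.where(z > 0, z, 1.0)) ** beta), 0.0)
        prob = np.where(need_reflect, 1.0 - prob, prob)
        prob = np.where(np.isfinite(x_acc[sel]), prob, np.nan)
        floor = 1.0 / (2.0 * n_fit)
        vals = stats.norm.ppf(np.clip(prob, floor, 1.0 - floor))
        vals = np.where(np.isfinite(x_acc[sel]), vals, np.nan)
        spei_vals[sel] = vals

    if np.any(failed):
        spei_vals[:, failed] = np.nan

    classes = classify(spei_vals)
    out = xr.Dataset(
        {
            "spei": (("time", "lat", "lon"), spei_vals),
            "drought_class": (("time", "lat", "lon"), classes),
        },
        coords={"time": climate["time"], "lat": climate["lat"], "lon": climate["lon"]},
        attrs={
            "timescale_months": config.k,
            "pet_method": config.pet_method,
            "calibration": "full record" if config.calibration is None
            else f"months [{config.calibration[0]}, {config.calibration[1]})",
            "class_codes": "-1 missing, 0 none, 1 mild, 2 severe",
            "class_thresholds": "any <= -0.5; mild (-1.3, -0.5]; severe <= -1.3",
            "origin": climate.attrs.get("origin", ""),
            "resolution_deg": climate.attrs.get("resolution_deg", 0.1),
        },
    )
    if "month_index" in climate.coords:
        out = out.assign_coords(month_index=("time", climate["month_index"].values))
    return out


def spei_to_netcdf(spei: xr.Dataset, path) -> None:
    """Write a SPEI grid to netCDF (classic format, variables spei24/drought_class)."""
    ds = spei.rename({"spei": "spei24"}) if "spei" in spei else spei
    ds.to_netcdf(path, engine="scipy")
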