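"""Synthetic gridded climate and DHS-like survey data with known ground truth.

The generator exists so that every downstream stage — PET, SPEI, exposure
linkage, survival models — can be exercised end-to-end without restricted
reanalysis or survey microdata.  Two pieces:

* :func:`generate_climate` draws seasonal monthly meteorology on a 0.1
  degree grid.  Precipitation is Gamma-distributed around a configurable
  seasonal-mean cycle (so the long-run per-calendar-month mean is known in
  closed form); an optional :class:`DroughtScenario` lowers the
  precipitation mean inside a region x period box to impose a multi-year
  dry anomaly.

* :func:`generate_survey` draws clustered survey data: geocoded clusters
  with urban/rural flags and sampling weights, children with birth dates,
  covariates, and household asset indicators.  Infant deaths follow a
  discrete-time proportional-hazards process: in each postnatal age-month
  ``a`` (0-11) the death probability is ``h0[a] * exp(lp)`` where the
  linear predictor contains the child's covariate effects, a Gaussian
  cluster random intercept on the log-hazard scale, and the drought-class
  effect of the calendar month actually realised at the cluster's grid
  cell.  Because the realised drought classes drive the hazard, parameter
  recovery by the downstream models is a meaningful end-to-end test.

Deaths are simulated on the monthly grid that matches the exposure
resolution; the day of death is drawn uniformly within the fatal month
(month 1 deaths get days 0-27) so the 27-day neonatal cut-off is
exercisable.  Interview dates are drawn so children are born within the 5
years before the interview, which produces the alive-but-young children
the month-specific exclusion rules need; deaths occurring after the
interview are recorded as alive (the cross-sectional design's
misclassification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .errors import CoverageError, InsufficientCalibrationError, ValidationError
from .spei import CLASS_MILD, CLASS_SEVERE

__all__ = [
    "GridSpec",
    "DroughtScenario",
    "DGPParams",
    "generate_climate",
    "generate_survey",
    "climate_to_netcdf",
]

DAYS_PER_MONTH = 30.44
NEONATAL_CUTOFF_DAYS = 27
GESTATION_MONTHS = 9


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of the synthetic climate grid.

    Cell centres sit at ``lat_min + i*resolution`` (ERA5-style node
    grid); ``start_year`` anchors month index 0 at January of that year.
    """

    lat_min: float = -2.0
    lon_min: float = 10.0
    n_lat: int = 5
    n_lon: int = 5
    resolution: float = 0.1
    start_year: int = 1980

    @property
    def lats(self):
        return self.lat_min + np.arange(self.n_lat) * self.resolution

    @property
    def lons(self):
        return self.lon_min + np.arange(self.n_lon) * self.resolution


@dataclass(frozen=True)
class DroughtScenario:
    """A dry anomaly imposed on a region x period box.

    ``balance_shift`` (mm/month, negative = drying) is applied to the
    seasonal precipitation mean inside the box, floored at 1 mm so the
    Gamma draw stays valid; with the default seasonal cycle (60-140 mm)
    the realised mean shift equals ``balance_shift`` exactly.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    month_start: int
    month_stop: int
    balance_shift: float = -30.0


@dataclass
class DGPParams:
    """Ground-truth parameters of the mortality data-generating process.

    ``baseline_monthly_hazard`` gives the 12 postnatal age-month death
    probabilities for a reference child (all in (0,1)); the defaults are
    calibrated so that the marginal infant mortality rate under the
    default covariate and drought effects is roughly 60 per 1,000 live
    births with ~57% of deaths neonatal.  ``log_hr_mild`` /
    ``log_hr_severe`` act on the current month's realised drought class;
    ``covariate_log_hrs`` maps covariate names (sex_male, rural,
    edu_primary/secondary/higher, wealth_latent) to log hazard ratios;
    ``cluster_re_sd`` is the SD of the Gaussian cluster random intercept
    on the log-hazard scale.  ``prenatal_lag_log_hrs`` (keys -9..-1) and
    ``prenatal_count_log_hr`` add purely gestational effects that
    multiply every postnatal hazard — used by the lagged-association
    simulations.  ``drought_interaction_log_hrs`` adds modifier-specific
    extra log-HRs for any-drought exposure (e.g. ``{"rural": 0.4}``).
    """

    baseline_monthly_hazard: tuple = (
        0.026, 0.0022, 0.0021, 0.0020, 0.0019, 0.0018,
        0.0017, 0.0016, 0.0015, 0.0014, 0.0013, 0.0012,
    )
    log_hr_mild: float = float(np.log(1.2))
    log_hr_severe: float = float(np.log(1.5))
    covariate_log_hrs: Dict[str, float] = field(default_factory=lambda: {
        "sex_male": float(np.log(1.2)),
        "rural": float(np.log(1.2)),
        "edu_primary": -0.10,
        "edu_secondary": -0.25,
        "edu_higher": -0.40,
        "wealth_latent": -0.08,
    })
    cluster_re_sd: float = 0.25
    gestation_months: int = GESTATION_MONTHS
    prenatal_lag_log_hrs: Dict[int, float] = field(default_factory=dict)
    prenatal_count_log_hr: float = 0.0
    drought_interaction_log_hrs: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        h = np.asarray(self.baseline_monthly_hazard, dtype=float)
        if h.size != 12 or np.any(h <= 0) or np.any(h >= 1):
            raise ValidationError(
                "baseline_monthly_hazard must be 12 probabilities in (0, 1)"
            )
        if self.gestation_months != GESTATION_MONTHS:
            raise ValidationError("gestation_months is fixed at 9")
        if self.cluster_re_sd < 0:
            raise ValidationError("cluster_re_sd must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "DGPParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["baseline_monthly_hazard"] = tuple(data["baseline_monthly_hazard"])
        data["prenatal_lag_log_hrs"] = {
            int(k): v for k, v in (data.get("prenatal_lag_log_hrs") or {}).items()
        }
        return cls(**data)


# ---------------------------------------------------------------------------
# climate


@dataclass(frozen=True)
class ClimateGenConfig:
    """Seasonal-cycle parameters of the climate generator (documented means).

    Precipitation in month-of-year m has mean
    ``precip_mean + precip_amp * cos(2*pi*(m - precip_phase)/12)`` plus a
    smooth mean-zero spatial offset, and is drawn Gamma with shape
    ``precip_shape`` (so the mean is exact in closed form).
    """

    precip_mean: float = 100.0
    precip_amp: float = 40.0
    precip_phase: float = 2.0
    precip_shape: float = 4.0
    tmax_mean: float = 30.0
    tmax_amp: float = 4.0
    diurnal_range: float = 10.0
    dew_depression: float = 2.5
    solar_mean: float = 18.0
    solar_amp: float = 5.0


def seasonal_precip_mean(month_of_year, config: ClimateGenConfig = ClimateGenConfig()):
    """Closed-form seasonal precipitation mean (mm/month), spatial offset aside."""
    m = np.asarray(month_of_year, dtype=float)
    return config.precip_mean + config.precip_amp * np.cos(
        2.0 * np.pi * (m - config.precip_phase) / 12.0
    )


def generate_climate(
    grid_spec: GridSpec,
    years: int,
    scenario: Optional[DroughtScenario] = None,
    seed: int = 0,
    config: ClimateGenConfig = ClimateGenConfig(),
) -> xr.Dataset:
    """Draw a synthetic monthly climate grid.

    Returns an xarray Dataset with (time, lat, lon) variables precip,
    tmax, tmin, tdew, wind, solar, pressure, and static elevation;
    deterministic given ``seed``.  The time axis is monthly from January
    of ``grid_spec.start_year`` with an integer ``month_index``
    coordinate.
    """
    if years < 3:
        raise InsufficientCalibrationError(
            f"{years} years of climate cannot calibrate a drought index (need >= 3)"
        )
    rng = np.random.default_rng(seed)
    n_time = years * 12
    lats, lons = grid_spec.lats, grid_spec.lons
    nlat, nlon = lats.size, lons.size
    time = pd.date_range(f"{grid_spec.start_year}-01-01", periods=n_time, freq="MS")
    moy = time.month.values  # 1..12

    lat2 = lats[:, None]
    lon2 = lons[None, :]
    smooth = np.sin(2 * np.pi * (lat2 - lats.min()) / max(np.ptp(lats), 1e-6)) * \
        np.cos(2 * np.pi * (lon2 - lons.min()) / max(np.ptp(lons), 1e-6))
    elevation = 300.0 + 150.0 * smooth + rng.normal(0, 10, (nlat, nlon))
    elevation = np.clip(elevation, 0.0, None)
    precip_offset = 8.0 * smooth

    mean_p = seasonal_precip_mean(moy, config)[:, None, None] + precip_offset[None]
    if scenario is not None:
        if scenario.month_start < 0 or scenario.month_stop > n_time:
            raise ValidationError("scenario period outside the simulated calendar")
        in_lat = (lats >= scenario.lat_min) & (lats <= scenario.lat_max)
        in_lon = (lons >= scenario.lon_min) & (lons <= scenario.lon_max)
        if not (in_lat.any() and in_lon.any()):
            raise ValidationError("scenario region does not intersect the grid")
        box = np.zeros((n_time, nlat, nlon), dtype=bool)
        t_sel = np.zeros(n_time, dtype=bool)
        t_sel[scenario.month_start:scenario.month_stop] = True
        box[np.ix_(t_sel, in_lat, in_lon)] = True
        mean_p = np.where(box, np.maximum(mean_p + scenario.balance_shift, 1.0), mean_p)
    mean_p = np.maximum(mean_p, 1.0)
    shape = config.precip_shape
    precip = rng.gamma(shape, mean_p / shape)

    season_t = np.cos(2.0 * np.pi * (moy - 4.0) / 12.0)[:, None, None]
    tmax = config.tmax_mean + config.tmax_amp * season_t \
        - 0.0065 * elevation[None] + rng.normal(0, 1.0, precip.shape)
    dtr = np.maximum(config.diurnal_range + rng.normal(0, 1.0, precip.shape), 1.0)
    tmin = tmax - dtr
    tdew = tmin - np.abs(rng.normal(config.dew_depression, 1.0, precip.shape))
    wind = rng.lognormal(np.log(2.5), 0.3, precip.shape)
    solar = np.clip(
        config.solar_mean + config.solar_amp * season_t
        + rng.normal(0, 1.5, precip.shape),
        2.0, None,
    )
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    pressure = pressure[None] + rng.normal(0, 0.05, precip.shape)

    ds = xr.Dataset(
        {
            "precip": (("time", "lat", "lon"), precip),
            "tmax": (("time", "lat", "lon"), tmax),
            "tmin": (("time", "lat", "lon"), tmin),
            "tdew": (("time", "lat", "lon"), tdew),
            "wind": (("time", "lat", "lon"), wind),
            "solar": (("time", "lat", "lon"), solar),
            "pressure": (("time", "lat", "lon"), pressure),
            "elevation": (("lat", "lon"), elevation),
        },
        coords={
            "time": time,
            "lat": lats,
            "lon": lons,
            "month_index": ("time", np.arange(n_time)),
        },
        attrs={
            "resolution_deg": grid_spec.resolution,
            "origin": f"{grid_spec.start_year}-01",
            "seed": seed,
        },
    )
    return ds


def climate_to_netcdf(climate: xr.Dataset, path) -> None:
    """Write the climate grid to netCDF (classic format via scipy)."""
    climate.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# survey


EDU_LEVELS = ("none", "primary", "secondary", "higher")
EDU_PROBS = (0.466, 0.333, 0.181, 0.020)
ZONE_LEVELS = ("tropical", "temperate", "dry")
ZONE_PROBS = (0.59, 0.16, 0.25)
P_MALE = 0.506
P_URBAN = 0.27
N_ASSETS = 10

#: Minimum gap (months) between the latest interview and the record end,
#: so every child's 21-month window has defined index values.
_TAIL_MONTHS = 12
#: Width (months) of the interview window before that tail.
_INTERVIEW_SPAN = 12
#: Children are born within this many months before their interview.
BIRTH_SPAN_MONTHS = 60


def _nearest_cell(lat, lon, lats, lons, res):
    """Nearest cell-centre indices (ties toward the lower index)."""
    fi = (np.asarray(lat) - lats[0]) / res
    fj = (np.asarray(lon) - lons[0]) / res
    i = np.ceil(fi - 0.5).astype(int)
    j = np.ceil(fj - 0.5).astype(int)
    return np.clip(i, 0, lats.size - 1), np.clip(j, 0, lons.size - 1)


def _death_day_within_month(a, u):
    """Uniform day of death inside postnatal month ``a`` (0-based).

    Month 0 maps to days 0-27 (the neonatal window); later months to the
    day range whose floor(days/30.44) equals ``a``, capped at 364.
    """
    a = np.asarray(a)
    lo = np.where(a == 0, 0, np.ceil(DAYS_PER_MONTH * a)).astype(int)
    hi = np.where(
        a == 0, NEONATAL_CUTOFF_DAYS,
        np.minimum(np.ceil(DAYS_PER_MONTH * (a + 1)) - 1, 364),
    ).astype(int)
    return (lo + np.floor(u * (hi - lo + 1)).astype(int)).clip(max=364)


def generate_survey(
    n_clusters: int,
    children_per_cluster: int,
    climate: xr.Dataset,
    spei: xr.Dataset,
    dgp: DGPParams,
    jitter_km: float = 0.0,
):
    """Draw clusters, children and household assets; simulate infant deaths.

    Returns ``(clusters, children, assets)`` pandas DataFrames.  Children
    carry ``birth_month_index`` / ``interview_month_index`` on the climate
    grid's month axis, ``age_at_death_days`` (NaN if recorded alive), the
    analysis covariates and a positive sampling weight.  ``assets`` has
    one row per household (one household per child) with binary asset
    indicators driven by a latent wealth score.

    Raises :class:`CoverageError` naming the first child whose
    conception-to-month-12 window is not covered by defined SPEI values.
    """
    rng = np.random.default_rng(dgp.seed)
    lats = climate["lat"].values
    lons = climate["lon"].values
    res = float(climate.attrs.get("resolution_deg", 0.1))
    n_time = climate.sizes["time"]
    classes = spei["drought_class"].values  # (time, lat, lon)

    # clusters ------------------------------------------------------------
    lat_lo, lat_hi = lats.min() - res / 2, lats.max() + res / 2
    lon_lo, lon_hi = lons.min() - res / 2, lons.max() + res / 2
    clat = rng.uniform(lat_lo, lat_hi, n_clusters)
    clon = rng.uniform(lon_lo, lon_hi, n_clusters)
    if jitter_km > 0.0:
        # optional DHS-style displacement (2-10 km ~ 0.02-0.09 deg), off by default
        ang = rng.uniform(0, 2 * np.pi, n_clusters)
        dist = rng.uniform(2.0, jitter_km, n_clusters) / 111.0
        clat = np.clip(clat + dist * np.sin(ang), lat_lo, lat_hi)
        clon = np.clip(clon + dist * np.cos(ang), lon_lo, lon_hi)
    country = np.array(["C%d" % (1 + int(3 * (x - lon_lo) / (lon_hi - lon_lo + 1e-9)))
                        for x in clon])
    urban = rng.random(n_clusters) < P_URBAN
    zone = rng.choice(ZONE_LEVELS, n_clusters, p=ZONE_PROBS)
    interview = rng.integers(
        n_time - _TAIL_MONTHS - _INTERVIEW_SPAN, n_time - _TAIL_MONTHS, n_clusters
    )
    cluster_wealth = rng.normal(0, 0.6, n_clusters) + 0.5 * urban
    cluster_b = rng.normal(0.0, dgp.cluster_re_sd, n_clusters)
    cluster_wt = rng.lognormal(0.0, 0.3, n_clusters)
    ci, cj = _nearest_cell(clat, clon, lats, lons, res)

    clusters = pd.DataFrame({
        "cluster_id": np.arange(n_clusters),
        "country": country,
        "lat": clat,
        "lon": clon,
        "urban": urban,
        "climate_zone": zone,
        "interview_month_index": interview,
        "cell_lat_idx": ci,
        "cell_lon_idx": cj,
    })

    # children ------------------------------------------------------------
    n = n_clusters * children_per_cluster
    cl = np.repeat(np.arange(n_clusters), children_per_cluster)
    child_id = np.arange(n)
    iv = interview[cl]
    birth = iv - rng.integers(1, BIRTH_SPAN_MONTHS + 1, n)
    sex_male = rng.random(n) < P_MALE
    edu = rng.choice(len(EDU_LEVELS), n, p=np.asarray(EDU_PROBS) / np.sum(EDU_PROBS))
    latent_wealth = (
        cluster_wealth[cl] + 0.8 * rng.normal(0, 1, n)
    )
    weight = cluster_wt[cl] * rng.lognormal(0.0, 0.2, n)
    weight = weight / weight.mean()

    conception = birth - dgp.gestation_months
    first_defined = int(np.argmax(np.any(np.isfinite(spei["spei"].values), axis=(1, 2))))
    bad = conception < first_defined
    if np.any(bad) or np.any(birth + 11 >= n_time):
        k = int(np.argmax(bad)) if np.any(bad) else int(np.argmax(birth + 11 >= n_time))
        raise CoverageError(
            f"child {k}: exposure window [{conception[k]}, {birth[k] + 11}] not "
            f"covered by defined SPEI months [{first_defined}, {n_time - 1}]"
        )

    # linear predictor (time-invariant part)
    c = dgp.covariate_log_hrs
    lp = (
        c.get("sex_male", 0.0) * sex_male
        + c.get("rural", 0.0) * (~urban[cl])
        + np.select(
            [edu == 1, edu == 2, edu == 3],
            [c.get("edu_primary", 0.0), c.get("edu_secondary", 0.0),
             c.get("edu_higher", 0.0)], 0.0,
        )
        + c.get("wealth_latent", 0.0) * latent_wealth
        + cluster_b[cl]
    )

    # purely gestational effects (multiply every postnatal hazard)
    cls_child = classes[:, ci[cl], cj[cl]]  # (time, n) realised classes at cell
    if dgp.prenatal_lag_log_hrs or dgp.prenatal_count_log_hr:
        pren_any = np.stack(
            [cls_child[birth + lag, np.arange(n)] >= CLASS_MILD for lag in range(-9, 0)],
            axis=1,
        )
        for lag, coef in dgp.prenatal_lag_log_hrs.items():
            lp = lp + coef * pren_any[:, lag + 9]
        lp = lp + dgp.prenatal_count_log_hr * pren_any.sum(axis=1)

    inter = 0.0
    if dgp.drought_interaction_log_hrs:
        inter = np.zeros(n)
        for name, coef in dgp.drought_interaction_log_hrs.items():
            if name == "rural":
                inter = inter + coef * (~urban[cl])
            elif name == "sex_male":
                inter = inter + coef * sex_male
            else:
                raise ValidationError(f"unknown interaction modifier {name!r}")

    # sequential monthly death process
    h0 = np.asarray(dgp.baseline_monthly_hazard, dtype=float)
    alive = np.ones(n, dtype=bool)
    death_month = np.full(n, -1)
    u = rng.random((12, n))
    rows = np.arange(n)
    for a in range(12):
        cal = birth + a
        cls_a = cls_child[cal, rows]
        drought_lp = np.select(
            [cls_a == CLASS_MILD, cls_a == CLASS_SEVERE],
            [dgp.log_hr_mild, dgp.log_hr_severe], 0.0,
        )
        any_d = cls_a >= CLASS_MILD
        hazard = np.clip(h0[a] * np.exp(lp + drought_lp + inter * any_d), 0.0, 0.99)
        dies = alive & (u[a] < hazard)
        death_month[dies] = a
        alive &= ~dies

    died = death_month >= 0
    age_days = np.full(n, np.nan)
    age_days[died] = _death_day_within_month(death_month[died], rng.random(died.sum()))
    # right truncation: deaths at or after the interview go unobserved
    attained = iv - birth
    observed = died & (death_month < attained)
    age_days[~observed] = np.nan

    children = pd.DataFrame({
        "child_id": child_id,
        "cluster_id": cl,
        "household_id": child_id,
        "sex": np.where(sex_male, "male", "female"),
        "mother_education": np.asarray(EDU_LEVELS)[edu],
        "residence": np.where(urban[cl], "urban", "rural"),
        "birth_month_index": birth,
        "age_at_death_days": age_days,
        "interview_month_index": iv,
        "sampling_weight": weight,
        "climate_zone": zone[cl],
        # generator ground truth (never a model input): simulated death
        # month before interview truncation, -1 = survived all 12 months
        "true_death_month": death_month,
    })

    # household assets ----------------------------------------------------
    thresholds = np.linspace(-1.6, 1.6, N_ASSETS)
    p_asset = 1.0 / (1.0 + np.exp(-(latent_wealth[:, None] - thresholds[None, :])))
    assets = (rng.random((n, N_ASSETS)) < p_asset).astype(int)
    asset_cols = [f"asset_{i:02d}" for i in range(N_ASSETS)]
    assets = pd.DataFrame(assets, columns=asset_cols)
    assets.insert(0, "household_id", child_id)

    return clusters, children, assets
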