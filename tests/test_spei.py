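"""Drought-index checks: accumulation, PWM fit, standardization, classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import droughtmort as dm
from droughtmort import spei as sp
from droughtmort.errors import (
    DegenerateSampleError,
    FitFailureError,
    InsufficientSeriesError,
)


# --- accumulation ----------------------------------------------------------

def test_accumulate_constant_series():
    out = sp.accumulate(np.ones(60), k=24)
    assert np.isnan(out[:23]).all()
    np.testing.assert_allclose(out[23:], 24.0)


def test_accumulate_difference_identity():
    """X_k[t] - X_k[t-1] = D[t] - D[t-24], checked against resummation."""
    rng = np.random.default_rng(1)
    d = rng.normal(0, 30, 120)
    x = sp.accumulate(d, k=24)
    brute = np.array([d[t - 23:t + 1].sum() for t in range(23, 120)])
    np.testing.assert_allclose(x[23:], brute, rtol=1e-12)
    diff = x[24:] - x[23:-1]
    np.testing.assert_allclose(diff, d[24:] - d[:-24], atol=1e-9)


def test_accumulate_k1_is_identity():
    d = np.arange(30, dtype=float)
    np.testing.assert_allclose(sp.accumulate(d, k=1), d)


def test_accumulate_too_short_raises():
    with pytest.raises(InsufficientSeriesError):
        sp.accumulate(np.ones(10), k=24)


# --- log-logistic PWM fit --------------------------------------------------

def test_pwm_fit_constant_sample_raises():
    with pytest.raises(DegenerateSampleError):
        sp.fit_loglogistic_pwm(np.full(50, 3.0))


def test_pwm_fit_recovers_parameters_against_mle_oracle():
    """PWM estimates on 10k log-logistic draws agree with the independent
    maximum-likelihood fit (scipy.stats.fisk) within 5% relative error."""
    rng = np.random.default_rng(42)
    alpha, beta, gamma = 50.0, 4.0, -10.0
    x = stats.fisk.rvs(beta, loc=gamma, scale=alpha, size=10_000,
                       random_state=rng)
    fit = sp.fit_loglogistic_pwm(x)
    c_mle, loc_mle, scale_mle = stats.fisk.fit(x)
    assert fit.alpha == pytest.approx(scale_mle, rel=0.05)
    assert fit.beta == pytest.approx(c_mle, rel=0.05)
    assert fit.gamma == pytest.approx(loc_mle, abs=0.05 * alpha)
    # and against the true values
    assert fit.alpha == pytest.approx(alpha, rel=0.05)
    assert fit.beta == pytest.approx(beta, rel=0.05)


def test_pwm_fit_cdf_at_median_is_half():
    rng = np.random.default_rng(3)
    x = stats.fisk.rvs(3.0, loc=5.0, scale=30.0, size=5_000, random_state=rng)
    fit = sp.fit_loglogistic_pwm(x)
    f_med = float(sp.loglogistic_cdf(np.median(x), fit))
    assert f_med == pytest.approx(0.5, abs=0.02)


def test_pwm_fit_left_skewed_sample_raises_then_reflection_standardizes():
    """A left-skewed sample has no direct log-logistic fit (shape <= 0);
    standardize() falls back to the reflected fit and stays monotone."""
    rng = np.random.default_rng(9)
    x = -stats.fisk.rvs(3.0, loc=0.0, scale=50.0, size=480, random_state=rng)
    with pytest.raises(FitFailureError):
        sp.fit_loglogistic_pwm(x)
    vals, params = sp.standardize(x)
    assert all(p.reflected for p in params)
    assert np.isfinite(vals).all()
    assert abs(vals.mean()) < 0.1


# --- standardization -------------------------------------------------------

@pytest.fixture(scope="module")
def balance_series():
    """45 years of seasonal water balance with noise (phase-0 start)."""
    rng = np.random.default_rng(17)
    t = np.arange(45 * 12)
    seasonal = 40.0 * np.cos(2 * np.pi * t / 12)
    d = seasonal + rng.gamma(4.0, 25.0, t.size) - 100.0
    return sp.accumulate(d, k=24)


def test_standardize_mean_zero_sd_one(balance_series):
    vals, _ = sp.standardize(balance_series)
    defined = vals[np.isfinite(vals)]
    assert abs(defined.mean()) <= 0.05
    assert 0.9 <= defined.std() <= 1.1


def test_standardize_median_maps_near_zero():
    """On genuinely log-logistic data the calendar-month median maps to
    SPEI ~ 0 (F(median) ~ 0.5); checked at n = 1000 per month where the
    sampling error of the fitted CDF at the median is well below 0.05."""
    rng = np.random.default_rng(23)
    n_years = 1000
    series = np.empty(12 * n_years)
    for phase in range(12):
        series[phase::12] = stats.fisk.rvs(
            5.0 + phase / 4, loc=-600 - 10 * phase, scale=400.0,
            size=n_years, random_state=rng,
        )
    vals, params = sp.standardize(series)
    for phase in range(12):
        x_ph = series[phase::12]
        med_spei = sp._spei_from_cdf(
            sp.loglogistic_cdf(np.median(x_ph), params[phase]), params[phase].n
        )
        assert abs(float(med_spei)) < 0.05


def test_standardize_strictly_increasing_within_month(balance_series):
    vals, params = sp.standardize(balance_series)
    for phase in range(12):
        x_ph = balance_series[phase::12]
        v_ph = vals[phase::12]
        m = np.isfinite(x_ph)
        order = np.argsort(x_ph[m])
        assert np.all(np.diff(v_ph[m][order]) > 0)


# --- classification --------------------------------------------------------

@pytest.mark.parametrize("value,expected", [
    (-0.5, sp.CLASS_MILD),      # boundary included by "<= -0.5"
    (-1.3, sp.CLASS_SEVERE),    # boundary included by "<= -1.3"
    (0.0, sp.CLASS_NONE),
    (-0.49, sp.CLASS_NONE),
    (-1.29, sp.CLASS_MILD),
    (-5.0, sp.CLASS_SEVERE),
    (np.nan, sp.CLASS_MISSING),
])
def test_classify_boundaries(value, expected):
    assert sp.classify(value) == expected


@given(st.floats(min_value=-6, max_value=6, allow_nan=False))
def test_classify_partition(value):
    """Every finite value gets exactly one class; any = mild or severe."""
    c = sp.classify(value)
    assert c in (sp.CLASS_NONE, sp.CLASS_MILD, sp.CLASS_SEVERE)
    assert (c in (sp.CLASS_MILD, sp.CLASS_SEVERE)) == (value <= -0.5)


@given(st.lists(st.floats(min_value=-6, max_value=6, allow_nan=False),
                min_size=2, max_size=50))
@settings(max_examples=50, deadline=None)
def test_classify_monotone_in_value(values):
    """A wetter (higher) index never yields a more severe class."""
    v = np.sort(np.asarray(values))
    c = sp.classify(v).astype(int)
    # severity codes (none=0 < mild=1 < severe=2) never increase as the
    # index gets wetter
    assert np.all(np.diff(c) <= 0)


# --- grid pipeline ---------------------------------------------------------

def test_pipeline_first_23_months_missing(spei_grid):
    v = spei_grid["spei"].values
    assert np.isnan(v[:23]).all()
    assert np.isfinite(v[23:]).all()
    assert (spei_grid["drought_class"].values[:23] == sp.CLASS_MISSING).all()


def test_pipeline_class_counts_partition(spei_grid):
    cls = spei_grid["drought_class"].values
    v = spei_grid["spei"].values
    n_any = int(((cls == sp.CLASS_MILD) | (cls == sp.CLASS_SEVERE)).sum())
    assert n_any == int((v <= -0.5).sum())
    assert int((cls == sp.CLASS_MILD).sum()) + int((cls == sp.CLASS_SEVERE).sum()) == n_any


def test_pipeline_matches_per_cell_scalar_path(climate, spei_grid):
    """The vectorised grid equals the scalar per-cell pipeline (loop oracle)."""
    from droughtmort.spei import SpeiConfig, _grid_pet
    from droughtmort import pet as petmod
    cfg = SpeiConfig()
    pet_field = _grid_pet(climate, cfg)
    d = petmod.water_balance(climate["precip"].values, pet_field)
    month0 = int(climate["time.month"].values[0]) - 1
    assert month0 == 0
    for (i, j) in [(0, 0), (1, 3), (3, 2)]:
        x = sp.accumulate(d[:, i, j], k=24)
        vals, _ = sp.standardize(x)
        np.testing.assert_allclose(
            vals, spei_grid["spei"].values[:, i, j], rtol=1e-9, atol=1e-9,
            equal_nan=True,
        )


def test_pipeline_scenario_raises_drought_counts(grid_spec):
    """A dry anomaly increases any-drought months inside the box."""
    scen = dm.DroughtScenario(
        lat_min=-2.0, lat_max=-1.8, lon_min=10.0, lon_max=10.2,
        month_start=400, month_stop=460, balance_shift=-45.0,
    )
    base = dm.spei_pipeline(dm.generate_climate(grid_spec, 45, seed=21))
    shifted = dm.spei_pipeline(
        dm.generate_climate(grid_spec, 45, scenario=scen, seed=21)
    )
    sel = dict(time=slice(400, 460), lat=slice(0, 3), lon=slice(0, 3))
    n_base = int((base["drought_class"][400:460, :3, :3].values >= 1).sum())
    n_shift = int((shifted["drought_class"][400:460, :3, :3].values >= 1).sum())
    assert n_shift > n_base
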