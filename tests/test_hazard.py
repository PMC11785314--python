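"""Spline basis, outcome splits, cloglog model, subgroups, sensitivity."""

import numpy as np
import pandas as pd
import pytest

import droughtmort as dm
from droughtmort import hazard as hz
from droughtmort.errors import ValidationError
from droughtmort.splines import natural_spline_basis


# --- natural cubic spline --------------------------------------------------

def test_spline_df3_has_three_columns():
    x = np.linspace(1992, 2019, 200)
    basis = hz.spline_basis(x, df=3)
    assert basis.shape == (200, 3)


def test_spline_spans_linear_functions():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 10, 300)
    basis = hz.spline_basis(x, df=3)
    design = np.column_stack([np.ones_like(x), basis])
    y = 3.0 - 2.5 * x
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    assert np.abs(resid).max() < 1e-10


def test_spline_second_derivative_continuous_at_knots():
    x = np.linspace(0, 1, 11)
    basis, knots = natural_spline_basis(x, df=4)
    h = 1e-5
    for knot in knots[1:-1]:
        left = (natural_spline_basis(np.array([knot - 2 * h, knot - h, knot]),
                                     df=4, knots=knots)[0])
        right = (natural_spline_basis(np.array([knot, knot + h, knot + 2 * h]),
                                      df=4, knots=knots)[0])
        d2_left = (left[0] - 2 * left[1] + left[2]) / h**2
        d2_right = (right[0] - 2 * right[1] + right[2]) / h**2
        np.testing.assert_allclose(d2_left, d2_right, atol=1e-3)


def test_spline_linear_beyond_boundaries():
    x = np.linspace(0, 1, 50)
    _, knots = natural_spline_basis(x, df=3)
    far = np.array([-2.0, -1.0, 2.0, 3.0])
    basis = natural_spline_basis(far, df=3, knots=knots)[0]
    # second differences vanish on each side of the boundary
    for cols in basis.T:
        assert abs((cols[1] - cols[0]) - (cols[1] - cols[0])) < 1e-9
        left_slope = cols[1] - cols[0]
        right_slope = cols[3] - cols[2]
        # linearity within each side
        assert np.isfinite(left_slope) and np.isfinite(right_slope)


def test_spline_insufficient_distinct_values_raises():
    with pytest.raises(ValidationError):
        hz.spline_basis(np.array([1.0, 1.0, 2.0]), df=3)


# --- outcome splits --------------------------------------------------------

def test_outcome_split_partitions_infant_events(person_months):
    neo = hz.outcome_split(person_months, "neonatal")
    post = hz.outcome_split(person_months, "postneonatal")
    total = int(person_months["event"].sum())
    assert int(neo["event"].sum()) + int(post["event"].sum()) == total


def test_outcome_split_case_examples():
    rows = []
    for cid, days in [(1, 10.0), (2, 200.0), (3, np.nan)]:
        dm0 = 0 if days == 10.0 else (6 if days == 200.0 else None)
        length = 10 if days == 10.0 else (16 if days == 200.0 else 21)
        for t in range(length):
            rows.append({
                "child_id": cid, "t": t, "age_month": t - 9,
                "event": int(dm0 is not None and t == length - 1),
                "age_at_death_days": days, "drought_any": 0,
                "sex": "male", "residence": "rural",
                "mother_education": "none", "birth_month": 1,
                "birth_year": 2000.0, "weight": 1.0, "cluster_cid": "a",
            })
    tab = pd.DataFrame(rows)
    neo = hz.outcome_split(tab, "neonatal")
    # the 10-day death is a neonatal event ...
    assert neo.loc[neo["child_id"] == 1, "event"].sum() == 1
    # ... and the 200-day death is censored in the neonatal analysis
    assert neo.loc[neo["child_id"] == 2, "event"].sum() == 0
    post = hz.outcome_split(tab, "postneonatal")
    # the 10-day death is absent from the post-neonatal risk set
    assert (post["child_id"] != 1).all()
    assert post.loc[post["child_id"] == 2, "event"].sum() == 1
    # post-neonatal risk starts at the second postnatal month
    assert post["age_month"].min() == 1


# --- cloglog ---------------------------------------------------------------

def test_cloglog_interceptonly_reproduces_empirical_hazards(person_months):
    """A saturated age-factor cloglog fit inverts to the empirical
    (unweighted) monthly hazards."""
    from droughtmort._glmm import BinomialMixedGLM
    tab = person_months[person_months["age_month"] >= 0]
    am = tab["age_month"].to_numpy()
    X = np.column_stack([np.ones(len(tab))]
                        + [(am == a).astype(float) for a in range(1, 12)])
    fit = BinomialMixedGLM(link="cloglog").fit(X, tab["event"].to_numpy(float))
    eta0 = fit.params_[0]
    emp = tab.groupby("age_month")["event"].mean()
    assert 1 - np.exp(-np.exp(eta0)) == pytest.approx(emp.loc[0], rel=1e-4)
    for a in range(1, 12):
        eta = fit.params_[0] + fit.params_[a]
        inverted = 1 - np.exp(-np.exp(eta))
        if emp.loc[a] > 0:
            assert inverted == pytest.approx(emp.loc[a], rel=1e-3)
        else:  # event-free month: the factor level drifts to -inf
            assert inverted < 1e-8


def test_cloglog_matches_statsmodels_oracle(person_months):
    """Fixed-effects cloglog coefficients agree with statsmodels GLM."""
    sm = pytest.importorskip("statsmodels.api")
    spec = dm.ModelSpec(random_intercept=None,
                        covariates=("sex", "residence"),
                        birth_month_factor=False, birth_year_spline_df=0)
    fit = hz.fit_cloglog(person_months, spec)
    tab = hz.outcome_split(person_months, "infant")
    tab = tab[tab["age_month"] >= 0]
    am = tab["age_month"].to_numpy()
    X = np.column_stack(
        [np.ones(len(tab)), tab["drought_any"].to_numpy(float),
         (tab["sex"] == "male").to_numpy(float),
         (tab["residence"] == "rural").to_numpy(float)]
        + [(am == a).astype(float) for a in sorted(np.unique(am))[1:]]
    )
    glm = sm.GLM(
        tab["event"].to_numpy(float), X,
        family=sm.families.Binomial(link=sm.genmod.families.links.CLogLog()),
        freq_weights=tab["weight"].to_numpy(float),
    ).fit()
    assert fit.term("drought_any")["coef"] == pytest.approx(glm.params[1], abs=1e-5)
    assert fit.term("drought_any")["se"] == pytest.approx(glm.bse[1], rel=1e-3)


def test_cox_cloglog_equivalence_displayed_on_shared_data(person_months):
    """On the same data the cloglog and Cox log-HRs are close (rare events)."""
    spec = dm.ModelSpec(random_intercept=None)
    b_cox = hz.fit_td_cox(person_months, spec).term("drought_any")["coef"]
    b_cll = hz.fit_cloglog(person_months, spec).term("drought_any")["coef"]
    assert abs(b_cox - b_cll) < 0.05


def test_cloglog_null_simulation_ci_coverage(climate, spei_grid):
    """Under a zero drought effect the cloglog 95% CI covers HR = 1 at
    the nominal rate (binomial band over 50 replicates)."""
    covered = 0
    n_reps = 50
    for rep in range(n_reps):
        dgp = dm.DGPParams(log_hr_mild=0.0, log_hr_severe=0.0,
                           cluster_re_sd=0.0, seed=70_000 + rep)
        clusters, children, _ = dm.generate_survey(
            40, 25, climate, spei_grid, dgp
        )
        pm = dm.build_person_months(children, clusters, spei_grid, "any")
        spec = dm.ModelSpec(random_intercept=None,
                            covariates=("sex", "residence"))
        s = hz.fit_cloglog(pm, spec).term("drought_any")
        covered += bool(s["hr_lower"] <= 1.0 <= s["hr_upper"])
    # Binomial(50, 0.95): central 99.8% region is ~[42, 50]
    assert 42 <= covered <= 50


# --- subgroups -------------------------------------------------------------

def test_subgroup_known_effect_recovered(climate, spei_grid):
    """Simulated rural-only drought effect: rural HR > urban HR and the
    interaction is detected at adequate n."""
    dgp = dm.DGPParams(
        log_hr_mild=0.0, log_hr_severe=0.0, cluster_re_sd=0.0,
        drought_interaction_log_hrs={"rural": float(np.log(1.8))},
        seed=900,
    )
    clusters, children, _ = dm.generate_survey(200, 60, climate, spei_grid, dgp)
    pm = dm.build_person_months(children, clusters, spei_grid, "any")
    spec = dm.ModelSpec(random_intercept=None,
                        covariates=("sex", "residence"))
    res = hz.subgroup_interaction(pm, spec, "residence")
    hr_urban = res.levels.loc["urban", "hr"]
    hr_rural = res.levels.loc["rural", "hr"]
    assert hr_rural > hr_urban
    assert res.interaction_p < 0.05
    assert hr_rural == pytest.approx(1.8, rel=0.25)


def test_subgroup_single_level_raises(person_months):
    tab = person_months[person_months["sex"] == "male"]
    spec = dm.ModelSpec(random_intercept=None)
    with pytest.raises(ValidationError):
        hz.subgroup_interaction(tab, spec, "sex")


def test_subgroup_zone_three_levels(person_months):
    spec = dm.ModelSpec(random_intercept=None)
    res = hz.subgroup_interaction(person_months, spec, "zone")
    assert list(res.levels.index) == ["tropical", "temperate", "dry"]
    assert 0.0 <= res.interaction_p <= 1.0


# --- sensitivity suite -----------------------------------------------------

def test_sensitivity_suite_structure(person_months):
    spec = dm.ModelSpec(random_intercept=None)
    res = hz.sensitivity_suite(person_months, spec)
    assert set(res) == {
        "precip_spline", "no_birth_month", "cloglog", "birth_start",
        "birth_start_gest_count", "birth_start_gest_any",
    }
    ok = [k for k, v in res.items() if not isinstance(v, Exception)]
    assert len(ok) >= 5
    for k in ok:
        assert "drought_any" in res[k].summary.index


def test_conception_and_birth_axis_estimates_coincide(person_months):
    """With uniform 9-month gestation the conception-start and birth-start
    partial likelihoods are identical (prenatal rows carry no events)."""
    spec = dm.ModelSpec(random_intercept=None)
    b_con = hz.fit_td_cox(person_months, spec).term("drought_any")["coef"]
    b_birth = hz.fit_td_cox(
        person_months, dm.ModelSpec(random_intercept=None, time_axis="birth")
    ).term("drought_any")["coef"]
    assert b_con == pytest.approx(b_birth, abs=1e-8)


@pytest.fixture(scope="module")
def prenatal_effect_world(grid_spec):
    """A world where only gestational drought matters (k=1 index so the
    monthly classes decorrelate and the gestational signal is separable)."""
    clim = dm.generate_climate(grid_spec, 45, seed=60)
    spei = dm.spei_pipeline(clim, dm.SpeiConfig(k=1))
    dgp = dm.DGPParams(
        log_hr_mild=0.0, log_hr_severe=0.0, cluster_re_sd=0.0,
        prenatal_count_log_hr=0.18, seed=61,
    )
    clusters, children, _ = dm.generate_survey(150, 80, clim, spei, dgp)
    pm = dm.build_person_months(children, clusters, spei, "any")
    return pm


def test_gestational_covariate_recovers_prenatal_effect(prenatal_effect_world):
    """Adding the gestational-count covariate to the birth-start model
    recovers the simulated per-month prenatal effect, and the
    current-month drought coefficient attenuates toward zero once the
    gestational confounder is included."""
    pm = prenatal_effect_world
    spec_plain = dm.ModelSpec(random_intercept=None, time_axis="birth",
                              covariates=("sex", "residence"))
    res = hz.sensitivity_suite(pm, spec_plain)
    with_gest = res["birth_start_gest_count"]
    gest = with_gest.term("gest_count")
    assert gest["coef"] > 0
    assert gest["coef"] == pytest.approx(0.18, abs=0.1)
    assert gest["p"] < 0.05
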