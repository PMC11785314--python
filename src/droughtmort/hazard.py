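"""Survival models for drought exposure and infant mortality.

The main model is a weighted extended Cox regression on the person-month
table: a time-dependent drought indicator (any drought, or mild/severe
dummies against no drought), the child's sex, area of residence,
mother's education and wealth quintile, a categorical birth month, a
natural cubic spline of birth year with three degrees of freedom, and a
Gaussian random intercept for the composite country-cluster id; DHS-style
sampling weights are applied as case weights.  The same specification is
refitted for neonatal (first 27 days) and post-neonatal (day 28 through
month 12) mortality, as a discrete-time complementary log-log binomial
model, with subgroup interaction terms, and across the sensitivity
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import BinomialMixedGLM
from .cox import CoxTimeVaryingFrailty
from .errors import DroughtMortError, ValidationError
from .splines import natural_spline_basis
from .synth import NEONATAL_CUTOFF_DAYS

__all__ = [
    "ModelSpec",
    "FitResult",
    "spline_basis",
    "fit_td_cox",
    "fit_cloglog",
    "outcome_split",
    "subgroup_interaction",
    "sensitivity_suite",
    "SubgroupResult",
]


def spline_basis(x, df: int = 3, knots=None):
    """Natural cubic spline basis of e.g. birth year (df columns)."""
    return natural_spline_basis(x, df=df, knots=knots)[0]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one survival-model fit.

    ``severity_mode``: "any" (single binary indicator) or "stratified"
    (mild and severe dummies vs no drought).  ``outcome``: "infant",
    "neonatal" or "postneonatal" (risk sets per the 27-day cut-off).
    ``time_axis``: "conception" (entry at conception, deaths possible
    from month 9 — the primary design) or "birth".
    ``gestational_term``: None, "count" (number of prenatal drought
    months, continuous) or "any" (binary ever-exposed in pregnancy),
    for the birth-start sensitivity models.  ``wealth_missing``:
    "category" keeps a missing-quintile dummy, "complete_case" drops
    those rows.
    """

    severity_mode: str = "any"
    outcome: str = "infant"
    covariates: tuple = ("sex", "residence", "mother_education", "wealth_quintile")
    birth_month_factor: bool = True
    birth_year_spline_df: int = 3
    random_intercept: Optional[str] = "cluster_cid"
    weighted: bool = True
    time_axis: str = "conception"
    precip_spline: bool = False
    gestational_term: Optional[str] = None
    ties: str = "efron"
    wealth_missing: str = "category"
    frailty_sd: Optional[float] = None

    def __post_init__(self):
        if self.birth_year_spline_df < 0:
            raise ValidationError("spline df must be >= 1 (0 disables the term)")
        if self.outcome not in ("infant", "neonatal", "postneonatal"):
            raise ValidationError(f"unknown outcome {self.outcome!r}")


@dataclass
class FitResult:
    """Estimates of one fitted model.

    ``summary`` is indexed by term with columns coef, se, z, p, hr,
    hr_lower, hr_upper (hazard ratios for Cox/cloglog, odds ratios for
    logistic fits — the exp(coef) scale either way).
    """

    summary: pd.DataFrame
    re_sd: Optional[float]
    loglik: float
    converged: bool
    n_events: int
    n_obs: int
    model: str
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        return self.summary.loc[name]

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "re_sd": self.re_sd,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_events": self.n_events,
            "n_obs": self.n_obs,
            "flags": self.flags,
            "terms": self.summary.reset_index().to_dict(orient="records"),
        }


def _make_summary(names, coef, se):
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        lo = np.exp(coef - 1.959963984540054 * se)
        hi = np.exp(coef + 1.959963984540054 * se)
    return pd.DataFrame(
        {"coef": coef, "se": se, "z": z, "p": p,
         "hr": np.exp(coef), "hr_lower": lo, "hr_upper": hi},
        index=pd.Index(names, name="term"),
    )


# ---------------------------------------------------------------------------
# design construction


def drought_terms(spec: ModelSpec):
    return (["drought_any"] if spec.severity_mode == "any"
            else ["drought_mild", "drought_severe"])


def build_covariate_design(df: pd.DataFrame, spec: ModelSpec, spline_knots=None):
    """Time-invariant covariate columns shared by every model.

    Returns (matrix, names, spline_knots).  Reference categories: female,
    urban, no education, lowest wealth quintile, January birth.
    """
    cols, names = [], []
    if "sex" in spec.covariates:
        cols.append((df["sex"] == "male").to_numpy(float))
        names.append("sex_male")
    if "residence" in spec.covariates:
        cols.append((df["residence"] == "rural").to_numpy(float))
        names.append("rural")
    if "mother_education" in spec.covariates:
        for lev in ("primary", "secondary", "higher"):
            cols.append((df["mother_education"] == lev).to_numpy(float))
            names.append(f"edu_{lev}")
    if "wealth_quintile" in spec.covariates and "wealth_quintile" in df:
        wq = df["wealth_quintile"].to_numpy(float)
        for qv in (2, 3, 4, 5):
            cols.append((wq == qv).astype(float))
            names.append(f"wealth_q{qv}")
        if spec.wealth_missing == "category":
            cols.append((~np.isfinite(wq)).astype(float))
            names.append("wealth_missing")
    if spec.birth_month_factor:
        bm = df["birth_month"].to_numpy()
        for mv in range(2, 13):
            cols.append((bm == mv).astype(float))
            names.append(f"birth_month_{mv}")
    if spec.birth_year_spline_df:
        basis, spline_knots = natural_spline_basis(
            df["birth_year"].to_numpy(float), df=spec.birth_year_spline_df,
            knots=spline_knots,
        )
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"birth_year_ns{j + 1}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, spline_knots


def _full_design(table: pd.DataFrame, spec: ModelSpec, intercept=False,
                 age_factor=False):
    dts = drought_terms(spec)
    for c in dts:
        if c not in table:
            raise ValidationError(
                f"column {c!r} missing: rebuild person-months with "
                f"severity_mode matching the spec"
            )
    cols = [table[c].to_numpy(float) for c in dts]
    names = list(dts)
    if spec.gestational_term:
        col = f"gest_{spec.gestational_term}"
        if col not in table:
            raise ValidationError(f"column {col!r} missing from the table")
        cols.append(table[col].to_numpy(float))
        names.append(col)
    if spec.precip_spline:
        if "precip" not in table:
            raise ValidationError(
                "precip column missing: build person-months with climate data"
            )
        basis, _ = natural_spline_basis(table["precip"].to_numpy(float), df=3)
        for j in range(3):
            cols.append(basis[:, j])
            names.append(f"precip_ns{j + 1}")
    Xc, cnames, _ = build_covariate_design(table, spec)
    X = np.column_stack(cols + [Xc]) if Xc.size else np.column_stack(cols)
    names = names + cnames
    if age_factor:
        am = table["age_month"].to_numpy()
        extra = []
        for av in sorted(np.unique(am))[1:]:
            extra.append((am == av).astype(float))
            names.append(f"age_month_{av}")
        if extra:
            X = np.column_stack([X] + extra)
    if intercept:
        X = np.column_stack([np.ones(len(table)), X])
        names = ["intercept"] + names
    keep = ["intercept"] + [nm for nm in names
                            if nm.startswith(("drought", "gest"))]
    return _drop_constant(X, names, keep=keep)


def _drop_constant(X, names, keep=()):
    """Drop zero-variance columns (they carry no information and can
    destabilise the Newton solve); protected names are kept."""
    sd = X.std(axis=0)
    mask = (sd > 0) | np.isin(names, list(keep))
    if mask.all():
        return X, names
    return X[:, mask], [nm for nm, m in zip(names, mask) if m]


# ---------------------------------------------------------------------------
# risk-set handling


def outcome_split(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Restrict the person-month table to an outcome-specific risk set.

    neonatal: risk ends at the first postnatal month; the event fires iff
    death occurred within 27 days (later deaths are censored there).
    postneonatal: children dying within 27 days are removed; risk starts
    at the second postnatal month among the survivors of day 27.
    """
    days = table["age_at_death_days"].to_numpy(float)
    if outcome == "infant":
        return table
    if outcome == "neonatal":
        out = table[table["age_month"] <= 0].copy()
        d = out["age_at_death_days"].to_numpy(float)
        out["event"] = (
            (out["age_month"].to_numpy() == 0)
            & np.isfinite(d) & (d <= NEONATAL_CUTOFF_DAYS)
        ).astype(np.int8)
        return out
    if outcome == "postneonatal":
        neonatal_child = np.isfinite(days) & (days <= NEONATAL_CUTOFF_DAYS)
        out = table[~neonatal_child & (table["age_month"] >= 1)].copy()
        return out
    raise ValidationError(f"unknown outcome {outcome!r}")


def _axis_filter(table: pd.DataFrame, spec: ModelSpec) -> tuple:
    """Apply outcome split and time-axis choice; return (table, t)."""
    tab = outcome_split(table, spec.outcome)
    if spec.time_axis == "birth":
        tab = tab[tab["age_month"] >= 0]
        t = tab["age_month"].to_numpy()
    elif spec.time_axis == "conception":
        t = tab["t"].to_numpy()
    else:
        raise ValidationError(f"unknown time_axis {spec.time_axis!r}")
    return tab, t


# ---------------------------------------------------------------------------
# model fits


def fit_td_cox(table: pd.DataFrame, spec: ModelSpec = ModelSpec(),
               robust: bool = False) -> FitResult:
    """Weighted time-dependent Cox fit of a person-month table."""
    tab, t = _axis_filter(table, spec)
    X, names = _full_design(tab, spec)
    w = tab["weight"].to_numpy(float) if spec.weighted else None
    groups = tab[spec.random_intercept].to_numpy() if spec.random_intercept else None
    model = CoxTimeVaryingFrailty(ties=spec.ties)
    model.fit(X, t, tab["event"].to_numpy(), weights=w, groups=groups,
              frailty_sd=spec.frailty_sd, names=names, robust=robust)
    return FitResult(
        summary=_make_summary(names, model.params_, model.se_),
        re_sd=model.frailty_sd_,
        loglik=model.loglik_,
        converged=model.converged_,
        n_events=model.n_events_,
        n_obs=model.n_obs_,
        model=f"cox_td[{spec.outcome},{spec.severity_mode},{spec.time_axis}]",
        flags=list(model.flags_),
        meta={"spec": spec},
    )


def fit_cloglog(table: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> FitResult:
    """Discrete-time complementary log-log fit on child-month rows.

    Prenatal rows carry no event risk and are dropped; the baseline
    hazard enters as an age-month factor (plus intercept).
    """
    tab, _ = _axis_filter(table, spec)
    tab = tab[tab["age_month"] >= 0]
    X, names = _full_design(tab, spec, intercept=True, age_factor=True)
    w = tab["weight"].to_numpy(float) if spec.weighted else None
    groups = tab[spec.random_intercept].to_numpy() if spec.random_intercept else None
    model = BinomialMixedGLM(link="cloglog")
    model.fit(X, tab["event"].to_numpy(float), weights=w, groups=groups,
              re_sd=spec.frailty_sd, names=names)
    return FitResult(
        summary=_make_summary(names, model.params_, model.se_),
        re_sd=model.re_sd_,
        loglik=model.loglik_,
        converged=model.converged_,
        n_events=int(tab["event"].sum()),
        n_obs=len(tab),
        model=f"cloglog[{spec.outcome},{spec.severity_mode}]",
        flags=list(model.flags_),
        meta={"spec": spec},
    )


# ---------------------------------------------------------------------------
# subgroups


@dataclass
class SubgroupResult:
    """Level-specific any-drought HRs and the interaction test."""

    modifier: str
    levels: pd.DataFrame          # index level; hr, hr_lower, hr_upper
    interaction_p: float
    fit: FitResult


_MODIFIERS = {
    "sex": lambda df: (df["sex"] == "male").to_numpy(float),
    "residence": lambda df: (df["residence"] == "rural").to_numpy(float),
    "education": lambda df: (df["mother_education"] != "none").to_numpy(float),
    "wealth": lambda df: (df["wealth_quintile"].to_numpy(float) >= 3).astype(float),
    "period": None,   # birth-year split, handled below
    "zone": None,     # 3-level climate zone, handled below
}

_MODIFIER_LEVELS = {
    "sex": ("female", "male"),
    "residence": ("urban", "rural"),
    "education": ("no education", "any education"),
    "wealth": ("lower (Q1-Q2)", "higher (Q3-Q5)"),
    "period": ("early period", "late period"),
}


def subgroup_interaction(table: pd.DataFrame, spec: ModelSpec,
                         modifier: str, period_cut: Optional[float] = None
                         ) -> SubgroupResult:
    """Any-drought x modifier interaction on the main Cox model.

    The modifier's main effect is added to the design when the base
    covariates do not span it (period of birth, climate zone); level
    HRs combine the main and interaction coefficients; significance of
    effect modification is the Wald p of the interaction term (a joint
    2-df test for the 3-level climate zone).
    """
    if modifier not in _MODIFIERS:
        raise ValidationError(f"unknown modifier {modifier!r}")
    spec = replace(spec, severity_mode="any")
    tab, t = _axis_filter(table, spec)

    extra_cols, extra_names = [], []
    if modifier == "zone":
        zones = tab["climate_zone"].to_numpy()
        lev1 = (zones == "temperate").astype(float)
        lev2 = (zones == "dry").astype(float)
        mods = [("temperate", lev1), ("dry", lev2)]
        extra_cols += [lev1, lev2]
        extra_names += ["zone_temperate", "zone_dry"]
        level_names = ["tropical", "temperate", "dry"]
    else:
        if modifier == "period":
            by = tab["birth_year"].to_numpy(float)
            cut = period_cut if period_cut is not None else float(np.median(by))
            mcol = (by >= cut).astype(float)
            extra_cols.append(mcol)
            extra_names.append("period_late")
        elif modifier == "wealth":
            wq = tab["wealth_quintile"].to_numpy(float)
            keep = np.isfinite(wq)
            tab = tab[keep]
            t = t[keep]
            mcol = _MODIFIERS[modifier](tab)
        else:
            mcol = _MODIFIERS[modifier](tab)
        mods = [(None, mcol)]
        level_names = list(_MODIFIER_LEVELS[modifier])

    d = tab["drought_any"].to_numpy(float)
    ev = tab["event"].to_numpy()
    mask0 = np.ones(len(tab), bool)
    for _, mc in mods:
        mask0 &= mc == 0
    levels_to_check = [(level_names[0], mask0)] + [
        (level_names[k + 1], mc > 0) for k, (_, mc) in enumerate(mods)
    ]
    for name, mask in levels_to_check:
        if mask.sum() == 0 or ev[mask].sum() == 0:
            raise ValidationError(f"modifier level {name!r} has no events")

    inter_cols = [d * mc for _, mc in mods]
    inter_names = [f"drought_any:x{i}" for i in range(len(mods))]
    X, names = _full_design(tab, spec)
    X = np.column_stack([X] + extra_cols + inter_cols)
    names = names + extra_names + inter_names

    w = tab["weight"].to_numpy(float) if spec.weighted else None
    groups = tab[spec.random_intercept].to_numpy() if spec.random_intercept else None
    model = CoxTimeVaryingFrailty(ties=spec.ties)
    model.fit(X, t, ev, weights=w, groups=groups,
              frailty_sd=spec.frailty_sd, names=names)
    summary = _make_summary(names, model.params_, model.se_)

    # covariance of (drought, interactions) from the penalised information
    # is not exposed; recompute from the Wald pieces via the full Hessian:
    cov = _coef_cov(model, X, t, tab, w, groups)
    i_d = names.index("drought_any")
    i_int = [names.index(nm) for nm in inter_names]
    rows = []
    b = model.params_
    rows.append(("%s" % level_names[0], b[i_d], np.sqrt(cov[i_d, i_d])))
    for k, nm in enumerate(inter_names):
        j = i_int[k]
        est = b[i_d] + b[j]
        var = cov[i_d, i_d] + cov[j, j] + 2 * cov[i_d, j]
        rows.append((level_names[k + 1], est, np.sqrt(max(var, 0.0))))
    lev = pd.DataFrame(
        [(nm, np.exp(c), np.exp(c - 1.96 * s), np.exp(c + 1.96 * s))
         for nm, c, s in rows],
        columns=["level", "hr", "hr_lower", "hr_upper"],
    ).set_index("level")

    if len(i_int) == 1:
        j = i_int[0]
        z = b[j] / np.sqrt(cov[j, j])
        p_int = float(2 * stats.norm.sf(abs(z)))
    else:
        bb = b[i_int]
        Vi = cov[np.ix_(i_int, i_int)]
        chi2 = float(bb @ np.linalg.solve(Vi, bb))
        p_int = float(stats.chi2.sf(chi2, df=len(i_int)))

    fit = FitResult(
        summary=summary, re_sd=model.frailty_sd_, loglik=model.loglik_,
        converged=model.converged_, n_events=model.n_events_,
        n_obs=model.n_obs_, model=f"cox_td[subgroup:{modifier}]",
        flags=list(model.flags_), meta={"modifier": modifier},
    )
    return SubgroupResult(modifier, lev, p_int, fit)


def _coef_cov(model: CoxTimeVaryingFrailty, X, t, tab, w, groups):
    """Fixed-effect covariance from the penalised information at the fit."""
    from .cox import _CoxData

    frail = groups if model.frailty_sd_ not in (None, 0.0) else None
    data = _CoxData(np.asarray(X, float), np.asarray(t),
                    tab["event"].to_numpy(),
                    np.ones(len(tab)) if w is None else np.asarray(w, float),
                    frail)
    p, q = data.p, data.q
    b = np.zeros(q)
    if q and model.frailty_ is not None:
        code_pos = {c: i for i, c in enumerate(data.group_codes)}
        for c, val in model.frailty_.items():
            b[code_pos[c]] = val
    _, _, H = model._accumulate(data, model.params_, b)
    H_pen = -H
    if q:
        H_pen[p:, p:] += np.eye(q) / model.frailty_sd_**2
    return np.linalg.pinv(H_pen)[:p, :p]


# ---------------------------------------------------------------------------
# sensitivity suite


def _gestational_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Per-child prenatal any-drought count/indicator from the conception rows."""
    if "drought_any" in table:
        any_col = table["drought_any"].to_numpy(float)
    else:
        any_col = (
            table["drought_mild"].to_numpy(float)
            + table["drought_severe"].to_numpy(float)
        )
    pren = table["age_month"].to_numpy() < 0
    counts = (
        pd.Series(any_col * pren, index=table["child_id"])
        .groupby(level=0).sum()
    )
    out = table.copy()
    out["gest_count"] = counts.reindex(table["child_id"]).to_numpy()
    out["gest_any"] = (out["gest_count"] > 0).astype(float)
    return out


def sensitivity_suite(table: pd.DataFrame, base_spec: ModelSpec = ModelSpec()
                      ) -> dict:
    """Run the labelled sensitivity variants; failures are isolated.

    Variants: a 3-df natural spline of monthly precipitation as a
    time-varying covariate; dropping the birth-month factor; the
    discrete-time cloglog model; restarting the clock at birth; and the
    birth-start model with the gestational drought count (continuous) or
    any-gestational-drought (binary) covariate added.
    """
    table_g = _gestational_columns(table)
    variants = {
        "precip_spline": (fit_td_cox, replace(base_spec, precip_spline=True)),
        "no_birth_month": (fit_td_cox, replace(base_spec, birth_month_factor=False)),
        "cloglog": (fit_cloglog, base_spec),
        "birth_start": (fit_td_cox, replace(base_spec, time_axis="birth")),
        "birth_start_gest_count": (
            fit_td_cox,
            replace(base_spec, time_axis="birth", gestational_term="count"),
        ),
        "birth_start_gest_any": (
            fit_td_cox,
            replace(base_spec, time_axis="birth", gestational_term="any"),
        ),
    }
    results = {}
    for label, (fn, spec) in variants.items():
        try:
            results[label] = fn(table_g, spec)
        except DroughtMortError as exc:
            results[label] = exc
    return results
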