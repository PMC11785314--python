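"""Death-month-specific lag analysis.

For each month of death ``m`` (1-12; ``m = 1`` means death within days
0-27, the neonatal window), a weighted mixed-effects logistic model
compares the children who died in that month (cases) with the children
who survived beyond it (non-cases), with the same covariates, birth-month
factor, birth-year spline and cluster random intercept as the main
survival model.  Children who died before month ``m``, and children who
were alive but had not yet attained the age of month ``m`` at the
interview, are excluded from that month's risk set.

Exposure is either a single binary drought indicator at one lag month
(prenatal lags -9..-1 count from the first to the last month of
pregnancy; postnatal lags 1..m from the month of birth), or the number
of drought months over pregnancy, or over infancy through month ``m``.
A pooled post-neonatal analysis (deaths at 28-364 days vs children
surviving the full year) examines the nine pregnancy-month exposures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from ._glmm import BinomialMixedGLM
from .errors import DroughtMortError, ValidationError
from .exposure import link_cluster_to_cell
from .hazard import ModelSpec, build_covariate_design
from .spei import CLASS_MILD, CLASS_MISSING
from .synth import DAYS_PER_MONTH, NEONATAL_CUTOFF_DAYS

__all__ = [
    "RiskSetSpec",
    "MonthlyFit",
    "select_risk_set",
    "fit_month_specific",
    "lag_grid",
    "death_month_1based",
]


def death_month_1based(age_days):
    """1-based month of death: 1 for days 0-27, else floor(days/30.44)+1.

    Days 28-30 (possible only in externally supplied data; the generator
    never produces them) count as month 2, keeping month 1 identical to
    the 27-day neonatal window.  Deaths at >= 365 days are outside
    infancy and return 0 (treated as survivors).
    """
    days = np.asarray(age_days, dtype=float)
    m = np.minimum(np.floor(days / DAYS_PER_MONTH), 11).astype(int) + 1
    m = np.where((m == 1) & (days > NEONATAL_CUTOFF_DAYS), 2, m)
    return np.where(days >= 365, 0, m)


@dataclass(frozen=True)
class RiskSetSpec:
    """Target death month and exposure definition.

    ``exposure``: "lag" (binary drought at ``lag``), "pregnancy_count" or
    "infancy_count".  ``lag`` in -9..-1 (pregnancy months, first to last)
    or 1..``month`` (postnatal, from the month of birth).
    """

    month: int
    exposure: str = "lag"
    lag: Optional[int] = None

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise ValidationError("death month must be 1..12")
        if self.exposure == "lag":
            if self.lag is None or self.lag == 0 or not -9 <= self.lag <= 12:
                raise ValidationError("lag must be in -9..-1 or 1..12")
            if self.lag > 0 and self.lag > self.month:
                raise ValidationError(
                    f"postnatal lag {self.lag} infeasible for death month {self.month}"
                )
        elif self.exposure not in ("pregnancy_count", "infancy_count"):
            raise ValidationError(f"unknown exposure {self.exposure!r}")


@dataclass
class MonthlyFit:
    """One month-specific logistic fit."""

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    n_cases: int
    n_noncases: int
    converged: bool
    flags: list
    coef: float
    se: float


def select_risk_set(children: pd.DataFrame, m: int):
    """Partition children into (cases, non_cases, excluded) for month ``m``.

    Cases died in month ``m``; non-cases survived beyond it (including
    children recorded alive with attained age >= m months); excluded are
    prior deaths and alive children younger than month ``m`` at the
    interview.  The three frames partition the input.
    """
    if not 1 <= m <= 12:
        raise ValidationError("death month must be 1..12")
    days = children["age_at_death_days"].to_numpy(float)
    died = np.isfinite(days)
    dm = np.where(died, death_month_1based(np.where(died, days, 0.0)), 0)
    attained = (
        children["interview_month_index"].to_numpy()
        - children["birth_month_index"].to_numpy()
    )
    infant_death = died & (dm >= 1)
    case = infant_death & (dm == m)
    excluded = (infant_death & (dm < m)) | (~infant_death & (attained < m))
    non_case = ~case & ~excluded
    return children[case], children[non_case], children[excluded]


def _pooled_postneonatal(children: pd.DataFrame):
    """Cases die at 28-364 days; non-cases survive the full year."""
    days = children["age_at_death_days"].to_numpy(float)
    died = np.isfinite(days)
    infant_death = died & (days < 365)
    attained = (
        children["interview_month_index"].to_numpy()
        - children["birth_month_index"].to_numpy()
    )
    case = infant_death & (days > NEONATAL_CUTOFF_DAYS)
    excluded = (infant_death & (days <= NEONATAL_CUTOFF_DAYS)) | (
        ~infant_death & (attained < 12)
    )
    non_case = ~case & ~excluded
    return children[case], children[non_case], children[excluded]


def _exposure_values(children: pd.DataFrame, spec, classes, ci, cj):
    """Per-child exposure per the RiskSetSpec from realised drought classes."""
    birth = children["birth_month_index"].to_numpy()
    rows = np.arange(len(children))
    cls = classes[:, ci, cj]  # (time, n_children)

    def any_at(cal):
        v = cls[cal, rows]
        if np.any(v == CLASS_MISSING):
            raise ValidationError("missing drought class in exposure month")
        return (v >= CLASS_MILD).astype(float)

    if spec.exposure == "lag":
        cal = birth + spec.lag if spec.lag < 0 else birth + spec.lag - 1
        return any_at(cal)
    if spec.exposure == "pregnancy_count":
        return sum(any_at(birth + lag) for lag in range(-9, 0))
    # infancy_count: month of birth through month m
    return sum(any_at(birth + a) for a in range(spec.month))


def _fit_logistic(children_sub, exposure, model_spec: ModelSpec):
    Xc, names, _ = build_covariate_design(children_sub, model_spec)
    X = np.column_stack([np.ones(len(children_sub)), exposure, Xc])
    names = ["intercept", "exposure"] + names
    from .hazard import _drop_constant
    X, names = _drop_constant(X, names, keep=("intercept", "exposure"))
    w = (children_sub["sampling_weight"].to_numpy(float)
         if model_spec.weighted else None)
    groups = (children_sub[model_spec.random_intercept].to_numpy()
              if model_spec.random_intercept else None)
    model = BinomialMixedGLM(link="logit")
    model.fit(X, children_sub["is_case"].to_numpy(float), weights=w,
              groups=groups, re_sd=model_spec.frailty_sd, names=names)
    j = names.index("exposure")
    coef, se = model.params_[j], model.se_[j]
    z = coef / se if se > 0 else 0.0
    with np.errstate(over="ignore"):
        lo, hi = float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))
    return MonthlyFit(
        odds_ratio=float(np.exp(coef)),
        ci_lower=lo,
        ci_upper=hi,
        p=float(2 * stats.norm.sf(abs(z))),
        n_cases=int(children_sub["is_case"].sum()),
        n_noncases=int((1 - children_sub["is_case"]).sum()),
        converged=model.converged_,
        flags=list(model.flags_),
        coef=float(coef),
        se=float(se),
    )


def _prepare_children(children, clusters, spei):
    """Attach calendar columns, composite cluster id and linked cells."""
    cl = clusters.set_index("cluster_id")
    lat_idx, lon_idx = link_cluster_to_cell(
        cl["lat"].values, cl["lon"].values, spei, cluster_ids=cl.index.values
    )
    pos = children["cluster_id"].map(
        pd.Series(np.arange(len(cl)), index=cl.index)
    ).to_numpy()
    out = children.copy()
    origin = str(spei.attrs.get("origin", "1980-01"))
    start_month = int(origin.split("-")[1])
    birth = out["birth_month_index"].to_numpy()
    out["birth_month"] = (birth + start_month - 1) % 12 + 1
    out["birth_year"] = (birth + start_month - 1) // 12.0
    country = (cl["country"].to_numpy()[pos].astype(object)
               if "country" in cl else np.full(len(out), "", object))
    out["cluster_cid"] = country + ":" + out["cluster_id"].astype(str)
    return out, lat_idx[pos], lon_idx[pos]


def fit_month_specific(children, clusters, spei: xr.Dataset, spec: RiskSetSpec,
                       model_spec: ModelSpec = ModelSpec()) -> MonthlyFit:
    """Fit one death-month-specific mixed logistic model.

    ``children``/``clusters`` are the survey tables (children may carry a
    ``wealth_quintile`` column); ``spei`` the drought-class grid.
    """
    prepared, ci, cj = _prepare_children(children, clusters, spei)
    cases, noncases, _ = select_risk_set(prepared, spec.month)
    if len(cases) == 0 or len(noncases) == 0:
        raise ValidationError(
            f"death month {spec.month}: needs >= 1 case and 1 non-case"
        )
    sub = pd.concat([cases, noncases])
    sub = sub.assign(is_case=np.r_[np.ones(len(cases)), np.zeros(len(noncases))])
    idx = sub.index.to_numpy()
    pos = prepared.index.get_indexer(idx)
    expo = _exposure_values(
        sub, spec, spei["drought_class"].values, ci[pos], cj[pos]
    )
    return _fit_logistic(sub, expo, model_spec)


def lag_grid(children, clusters, spei: xr.Dataset,
             model_spec: ModelSpec = ModelSpec(),
             months=range(1, 13)) -> pd.DataFrame:
    """The full (death month x exposure) grid as a long-format table.

    For each death month ``m``: 9 prenatal binary lags, the ``m``
    feasible postnatal lags, and the two count exposures; plus the
    neonatal and pooled post-neonatal pregnancy-lag rows.  Cell failures
    are recorded (``error`` column) without aborting the grid.
    """
    prepared, ci, cj = _prepare_children(children, clusters, spei)
    classes = spei["drought_class"].values
    rows = []

    def run_cell(outcome, sub, is_case, spec_m, exposure, lag):
        sub = sub.assign(is_case=is_case)
        rec = {"outcome": outcome, "exposure": exposure, "lag": lag}
        try:
            pos = prepared.index.get_indexer(sub.index.to_numpy())
            expo = _exposure_values(
                sub, spec_m, classes, ci[pos], cj[pos]
            )
            fit = _fit_logistic(sub, expo, model_spec)
            rec.update(odds_ratio=fit.odds_ratio, ci_lower=fit.ci_lower,
                       ci_upper=fit.ci_upper, p=fit.p, n_cases=fit.n_cases,
                       n_noncases=fit.n_noncases, error="")
        except (DroughtMortError, np.linalg.LinAlgError) as exc:
            rec.update(odds_ratio=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                       p=np.nan, n_cases=np.nan, n_noncases=np.nan,
                       error=str(exc))
        rows.append(rec)

    for m in months:
        cases, noncases, _ = select_risk_set(prepared, m)
        sub = pd.concat([cases, noncases])
        is_case = np.r_[np.ones(len(cases)), np.zeros(len(noncases))]
        for lag in list(range(-9, 0)) + list(range(1, m + 1)):
            run_cell(f"month_{m}", sub, is_case,
                     RiskSetSpec(m, "lag", lag), "binary_lag", lag)
        run_cell(f"month_{m}", sub, is_case,
                 RiskSetSpec(m, "pregnancy_count"), "pregnancy_count", np.nan)
        run_cell(f"month_{m}", sub, is_case,
                 RiskSetSpec(m, "infancy_count"), "infancy_count", np.nan)

    # pregnancy-month exposures for neonatal vs pooled post-neonatal
    cases, noncases, _ = select_risk_set(prepared, 1)
    sub = pd.concat([cases, noncases])
    is_case = np.r_[np.ones(len(cases)), np.zeros(len(noncases))]
    for lag in range(-9, 0):
        run_cell("neonatal", sub, is_case, RiskSetSpec(1, "lag", lag),
                 "binary_lag", lag)
    pcases, pnoncases, _ = _pooled_postneonatal(prepared)
    sub = pd.concat([pcases, pnoncases])
    is_case = np.r_[np.ones(len(pcases)), np.zeros(len(pnoncases))]
    for lag in range(-9, 0):
        run_cell("postneonatal_pooled", sub, is_case, RiskSetSpec(12, "lag", lag),
                 "binary_lag", lag)
    return pd.DataFrame(rows)
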