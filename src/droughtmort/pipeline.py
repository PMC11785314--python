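"""End-to-end orchestration: synthesize -> SPEI -> link -> fit -> report.

A :class:`RunConfig` pins every stochastic seed and all model settings;
:func:`run_all` executes the stages and writes the output tables:

* main results: any/mild/severe drought HRs for infant, neonatal and
  post-neonatal mortality — 9 HR rows;
* subgroup table: level-specific any-drought HRs and interaction
  p-values for sex, residence, education, wealth, period of birth and
  climate zone;
* sensitivity table: one labelled row block per variant;
* the death-month x lag grid (long CSV, ready for heat-map plotting);
* a descriptive table with case/non-case counts and unweighted and
  weighted infant mortality rates per stratum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import exposure as _exposure
from . import hazard as _hazard
from . import monthly as _monthly
from . import synth as _synth
from .errors import ValidationError
from .spei import SpeiConfig, spei_pipeline

__all__ = ["RunConfig", "ReportBundle", "run_all", "imr", "descriptive_table"]

log = logging.getLogger("droughtmort")


def imr(cases: int, noncases: int) -> float:
    """Infant mortality rate: deaths before age 1 per 1,000 live births.

    ``1000 * cases / (cases + noncases)``, reported to one decimal.
    """
    total = cases + noncases
    if total <= 0:
        raise ValidationError("zero live births: IMR undefined")
    return round(1000.0 * cases / total, 1)


def _weighted_imr(is_case, weights) -> float:
    w = np.asarray(weights, dtype=float)
    c = np.asarray(is_case, dtype=bool)
    if w.sum() <= 0:
        raise ValidationError("zero total weight")
    return round(1000.0 * w[c].sum() / w.sum(), 1)


@dataclass
class RunConfig:
    """All knobs of one end-to-end run; round-trips through YAML."""

    out_dir: str = "run_output"
    seed: int = 1
    years: int = 45
    grid: dict = field(default_factory=dict)            # GridSpec overrides
    scenario: Optional[dict] = None                      # DroughtScenario kwargs
    n_clusters: int = 120
    children_per_cluster: int = 25
    dgp: dict = field(default_factory=dict)              # DGPParams overrides
    spei: dict = field(default_factory=dict)             # SpeiConfig overrides
    model: dict = field(default_factory=dict)            # ModelSpec overrides
    run_subgroups: bool = True
    run_sensitivity: bool = True
    run_lag_grid: bool = True
    lag_months: tuple = tuple(range(1, 13))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "lag_months" in data:
            data["lag_months"] = tuple(data["lag_months"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Outputs of one run (tables plus provenance)."""

    main_results: pd.DataFrame
    descriptive: pd.DataFrame
    subgroups: Optional[pd.DataFrame]
    sensitivity: Optional[pd.DataFrame]
    lag_grid: Optional[pd.DataFrame]
    provenance: dict
    datasets: dict = field(default_factory=dict)


def build_cohort(config: RunConfig):
    """Stages 1-3: climate, SPEI, survey, wealth quintiles, person-months."""
    t0 = _time.time()
    grid = _synth.GridSpec(**config.grid)
    scenario = (_synth.DroughtScenario(**config.scenario)
                if config.scenario else None)
    climate = _synth.generate_climate(
        grid, config.years, scenario=scenario, seed=config.seed
    )
    spei_cfg = SpeiConfig(**config.spei)
    spei = spei_pipeline(climate, spei_cfg)
    log.info("climate+SPEI in %.1fs", _time.time() - t0)

    dgp_kwargs = dict(config.dgp)
    dgp_kwargs.setdefault("seed", config.seed + 1)
    dgp = _synth.DGPParams(**dgp_kwargs)
    clusters, children, assets = _synth.generate_survey(
        config.n_clusters, config.children_per_cluster, climate, spei, dgp
    )
    wq = _exposure.wealth_index(assets)
    children = children.merge(
        wq[["household_id", "wealth_quintile"]], on="household_id", how="left"
    )
    tables = {
        mode: _exposure.build_person_months(
            children, clusters, spei, severity_mode=mode, climate=climate
        )
        for mode in ("any", "stratified")
    }
    log.info("cohort built in %.1fs", _time.time() - t0)
    return {
        "climate": climate, "spei": spei, "clusters": clusters,
        "children": children, "assets": assets, "person_months": tables,
        "dgp": dgp,
    }


def main_results_table(tables: dict, model_spec: _hazard.ModelSpec) -> pd.DataFrame:
    """Any/mild/severe HRs for infant, neonatal, post-neonatal mortality."""
    from dataclasses import replace

    rows = []
    for outcome in ("infant", "neonatal", "postneonatal"):
        for mode in ("any", "stratified"):
            spec = replace(model_spec, severity_mode=mode, outcome=outcome)
            fit = _hazard.fit_td_cox(tables[mode], spec)
            for term in _hazard.drought_terms(spec):
                s = fit.term(term)
                rows.append({
                    "outcome": outcome,
                    "severity": term.replace("drought_", ""),
                    "hr": s["hr"], "hr_lower": s["hr_lower"],
                    "hr_upper": s["hr_upper"], "p": s["p"],
                    "n_events": fit.n_events, "re_sd": fit.re_sd,
                    "converged": fit.converged,
                })
    return pd.DataFrame(rows)


def descriptive_table(children: pd.DataFrame) -> pd.DataFrame:
    """Case/non-case counts and IMRs (unweighted and weighted) per stratum."""
    days = children["age_at_death_days"].to_numpy(float)
    is_case = np.isfinite(days) & (days < 365)
    w = children["sampling_weight"].to_numpy(float)

    def stratum_rows(name, values):
        out = []
        for lev in pd.unique(values):
            m = values == lev
            c, n = int(is_case[m].sum()), int((~is_case[m]).sum())
            out.append({
                "stratum": name, "level": str(lev), "cases": c, "noncases": n,
                "imr_unweighted": imr(c, n),
                "imr_weighted": _weighted_imr(is_case[m], w[m]),
            })
        return out

    rows = [{
        "stratum": "total", "level": "total",
        "cases": int(is_case.sum()), "noncases": int((~is_case).sum()),
        "imr_unweighted": imr(int(is_case.sum()), int((~is_case).sum())),
        "imr_weighted": _weighted_imr(is_case, w),
    }]
    rows += stratum_rows("sex", children["sex"].to_numpy())
    rows += stratum_rows("residence", children["residence"].to_numpy())
    rows += stratum_rows("mother_education", children["mother_education"].to_numpy())
    if "wealth_quintile" in children:
        wq = children["wealth_quintile"].astype("object").where(
            children["wealth_quintile"].notna(), "missing"
        ).to_numpy()
        rows += stratum_rows("wealth_quintile", wq)
    rows += stratum_rows("climate_zone", children["climate_zone"].to_numpy())
    return pd.DataFrame(rows)


def run_all(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute the full pipeline; partial outputs are retained on failure."""
    t0 = _time.time()
    stage = "synthesis"
    data = build_cohort(config)
    tables = data["person_months"]
    model_spec = _hazard.ModelSpec(**config.model)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    provenance["stages"][stage] = round(_time.time() - t0, 2)

    def timed(name, fn):
        s = _time.time()
        try:
            out = fn()
        except Exception as exc:  # stage failures reported with stage name
            log.error("stage %s failed: %s", name, exc)
            provenance["stages"][name] = f"FAILED: {exc}"
            return None
        provenance["stages"][name] = round(_time.time() - s, 2)
        return out

    main = timed("main_models", lambda: main_results_table(tables, model_spec))
    desc = timed("descriptive", lambda: descriptive_table(data["children"]))

    subgroups = None
    if config.run_subgroups:
        def _subgroups():
            rows = []
            for mod in ("sex", "residence", "education", "wealth", "period", "zone"):
                try:
                    res = _hazard.subgroup_interaction(
                        tables["any"], model_spec, mod
                    )
                except ValidationError as exc:
                    rows.append({"modifier": mod, "level": "", "hr": np.nan,
                                 "hr_lower": np.nan, "hr_upper": np.nan,
                                 "interaction_p": np.nan, "error": str(exc)})
                    continue
                for lev, r in res.levels.iterrows():
                    rows.append({
                        "modifier": mod, "level": lev, "hr": r["hr"],
                        "hr_lower": r["hr_lower"], "hr_upper": r["hr_upper"],
                        "interaction_p": res.interaction_p, "error": "",
                    })
            return pd.DataFrame(rows)
        subgroups = timed("subgroups", _subgroups)

    sensitivity = None
    if config.run_sensitivity:
        def _sens():
            res = _hazard.sensitivity_suite(tables["any"], model_spec)
            rows = []
            for label, fit in res.items():
                if isinstance(fit, Exception):
                    rows.append({"variant": label, "term": "", "hr": np.nan,
                                 "hr_lower": np.nan, "hr_upper": np.nan,
                                 "p": np.nan, "error": str(fit)})
                    continue
                for term in fit.summary.index:
                    if term.startswith("drought") or term.startswith("gest"):
                        s = fit.term(term)
                        rows.append({
                            "variant": label, "term": term, "hr": s["hr"],
                            "hr_lower": s["hr_lower"], "hr_upper": s["hr_upper"],
                            "p": s["p"], "error": "",
                        })
            return pd.DataFrame(rows)
        sensitivity = timed("sensitivity", _sens)

    lag = None
    if config.run_lag_grid:
        lag = timed("lag_grid", lambda: _monthly.lag_grid(
            data["children"], data["clusters"], data["spei"],
            model_spec, months=config.lag_months,
        ))

    bundle = ReportBundle(
        main_results=main, descriptive=desc, subgroups=subgroups,
        sensitivity=sensitivity, lag_grid=lag, provenance=provenance,
        datasets=data,
    )
    if write:
        write_bundle(bundle, config)
    return bundle


def write_bundle(bundle: ReportBundle, config: RunConfig) -> dict:
    """Write the report tables; returns a name -> sha256 checksum map."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}

    def put(name, df):
        if df is None:
            return
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    put("main_results.csv", bundle.main_results)
    put("descriptive_table.csv", bundle.descriptive)
    put("subgroup_results.csv", bundle.subgroups)
    put("sensitivity_results.csv", bundle.sensitivity)
    put("lag_grid.csv", bundle.lag_grid)
    prov = dict(bundle.provenance, checksums=checksums)
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    bundle.provenance = prov
    return checksums
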