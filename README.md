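# droughtmort

Long-term drought exposure and infant survival: a reusable, fully
synthetic-testable analysis pipeline.

## The problem

Epidemiological studies of drought and child health link geocoded
household-survey cohorts (DHS-style: clusters with GPS coordinates and
sampling weights; children with birth dates, survival outcomes and
socio-economic covariates) to gridded climate reanalysis, and ask
whether months spent under drought — from conception through the first
year of life — raise the risk of infant death.  The real inputs are
access-restricted (survey microdata) or bulky (decades of 0.1°
reanalysis), so this package pairs every analysis stage with a
synthetic-data generator whose ground truth is known, making the whole
chain testable end to end.

## What it computes

**Drought index.**  Monthly potential evapotranspiration (PET) by
FAO-56 Penman–Monteith (Hargreaves–Samani as a temperature-only
fallback), the climatic water balance `D = P − PET`, and the
standardized precipitation-evapotranspiration index at a 24-month
timescale: `X24[t] = Σ D[t−23..t]` is fitted per calendar month with a
three-parameter log-logistic distribution by unbiased
probability-weighted moments, then mapped through `Φ⁻¹(F(x))` so the
index has mean 0 and SD 1 over the calibration period.  Severity
classes: any drought `SPEI ≤ −0.5`, mild `−1.3 < SPEI ≤ −0.5`, severe
`SPEI ≤ −1.3`.

**Exposure.**  Each child's cluster is linked to its nearest grid cell;
the exposure window runs from conception (a fixed 9-month gestation)
to death or the 12th month after birth — 9 prenatal months plus up to
12 postnatal months, 21 lag months for survivors.  The window expands
into a person-month counting-process table with a time-varying drought
indicator.

**Models.**  A weighted extended Cox regression on the monthly time
axis (Efron ties) with child covariates, a categorical birth month, a
3-df natural cubic spline of birth year, and a Gaussian random
intercept (frailty) for the composite country–cluster id, fitted by
penalised partial likelihood; outcome splits for neonatal (days 0–27)
and post-neonatal (days 28–364) mortality; subgroup interactions; a
discrete-time complementary log-log model and other sensitivity
variants; and death-month-specific mixed-effects logistic models over
a (death month × exposure lag) grid.

## Worked example

```python
import droughtmort as dm

grid = dm.GridSpec(n_lat=4, n_lon=4)
climate = dm.generate_climate(grid, years=45, seed=3)
spei = dm.spei_pipeline(climate)

dgp = dm.DGPParams(seed=11)   # HR: mild 1.2, severe 1.5, cluster SD 0.25
clusters, children, assets = dm.generate_survey(60, 25, climate, spei, dgp)
children = children.merge(
    dm.wealth_index(assets)[["household_id", "wealth_quintile"]],
    on="household_id")
pm = dm.build_person_months(children, clusters, spei, "any")
fit = dm.fit_td_cox(pm, dm.ModelSpec())
print(fit.term("drought_any"))
```

prints (1,500 children, 83 deaths):

```
coef        0.340
se          0.233
z           1.455
p           0.146
hr          1.405
hr_lower    0.889
hr_upper    2.220
```

i.e. an any-drought hazard ratio of 1.41 (95% CI 0.89–2.22) against a
simulated truth of 1.2 (mild) / 1.5 (severe) — the wide interval is
what 83 events buy; the acceptance experiments below run the same
recovery at ~20,000 children per replicate, where the pooled estimate
tightens onto the truth.

The same pipeline is scriptable from the shell:

```bash
droughtmort run-all --out-dir run_output        # all stages + report tables
droughtmort synth --out climate.nc              # individual stages
droughtmort fit-main --config config.yaml
```

`run-all` writes `main_results.csv` (any/mild/severe × infant/neonatal/
post-neonatal hazard ratios — nine rows), `subgroup_results.csv`,
`sensitivity_results.csv`, `lag_grid.csv`, `descriptive_table.csv`
(stratum-wise infant mortality rates per 1,000 live births, weighted
and unweighted) and `provenance.json` (config hash, seeds, timings,
checksums).

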