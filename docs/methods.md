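# Methods

This note documents the models the package implements, the assumptions
behind the synthetic-data generator, and the numerical choices made
where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Drought index

### Potential evapotranspiration

The default PET is the FAO-56 Penman–Monteith reference
evapotranspiration, computed from maximum/minimum temperature, dew
point, wind speed, solar radiation, air pressure, latitude and
elevation — exactly the variable set a reanalysis-driven water balance
provides.  Choices within the FAO-56 chain:

- wind measured at 10 m is converted to 2 m by the log-profile factor
  `4.87 / ln(67.8 z − 5.42)`; the measurement height is a parameter;
- actual vapour pressure comes from the saturation curve at the dew
  point; the saturation deficit uses the mean of the curves at tmax
  and tmin;
- net longwave radiation bounds the relative shortwave ratio
  `Rs/Rso` to [0.3, 1] (the lower bound covers overcast months and
  polar-night cells where `Rso → 0`);
- soil heat flux is taken as zero on the monthly timescale;
- the monthly total is the daily reference value times the Gregorian
  (leap-aware) number of days in the month, evaluated at the mid-month
  day of year.

Hargreaves–Samani (`0.0023 · 0.408·Ra · (T̄ + 17.8) · √(Tmax − Tmin)`)
is available when humidity, wind or radiation are missing; with
`pet_method="none"` the index degrades to a precipitation-only (SPI)
mode.  PET is clipped at zero; with `Tmax = Tmin` the Hargreaves
estimate is exactly zero.

### SPEI

The climatic water balance `D = P − PET` is accumulated over `k`
months (default 24; the accumulation is inclusive of the current
month, so the first `k − 1` months are undefined).  For each of the 12
calendar months separately — which is what removes the local seasonal
cycle — a three-parameter log-logistic distribution

  F(x) = [1 + (α/(x − γ))^β]⁻¹,  x > γ

is fitted by unbiased (Hosking) probability-weighted moments.  The PWM
moment equations are written in the (1−F)-type moments
`w_r = E[X(1−F)^r]`; we estimate the F-type `b_r` with the unbiased
plotting weights and convert (`w0 = b0`, `w1 = b0 − b1`,
`w2 = b0 − 2b1 + b2`).  Validity requires `β > 1` (the mean must
exist); fits with `β ≤ 0` (or ≤ 1) raise a fit-failure error from the
scalar API.

**Left-skewed months.**  Accumulated balances are close to symmetric
(24-month sums of mildly skewed monthly values), so at calibration
sizes of a few decades the sample L-skewness of an individual calendar
month can be negative, and then *no* direct log-logistic fit exists.
The standardizer falls back to the reflected fit: the log-logistic is
fitted to `−X` and the CDF used is `1 − F_r(−x)`.  This keeps the
transform strictly increasing and the normalization exact, and reduces
to the direct fit whenever one exists.

Other choices: the calibration window defaults to the full record
(configurable); probabilities are floored/capped at `1/(2n)` before
the normal quantile so values at or beyond the fitted support map to a
bounded index; the quantile function is the full-accuracy
`scipy.stats.norm.ppf`, not the three-constant rational approximation
(the difference is orders of magnitude below the classification
tolerance).  Severity classes (any ≤ −0.5; mild (−1.3, −0.5]; severe
≤ −1.3) are assigned per month; undefined months get an explicit
missing code, never a default class.

## Synthetic data generator

The generator defines the study conditions for every simulation-based
check.

**Climate.**  0.1° cell-centre grid; monthly series per cell.
Precipitation is Gamma with shape 4 around a seasonal mean cycle of
100 ± 40 mm/month (plus a smooth ±8 mm spatial offset), so the
long-run per-calendar-month mean is known exactly.  Temperatures,
dew-point depression, wind (lognormal around 2.5 m/s), solar radiation
and barometric pressure (standard-atmosphere at the cell elevation)
follow seasonal cycles with noise.  A `DroughtScenario` lowers the
precipitation *mean* inside a region × period box by `balance_shift`
mm/month (floored at 1 mm), so the realised shift equals the requested
one by construction.  At these settings PET is ~120–150 mm/month and
the water balance is mostly negative — a semi-arid regime in which
roughly 30% of months classify as any-drought and ~10% as severe.

**Survey.**  Clusters are uniform over the grid with an urban flag
(27%), a country label (by longitude block), a provided climate-zone
label, and a lognormal design weight; interviews happen within the
last two years of the record minus a 12-month tail, so every child's
21-month window is covered by defined index values.  Children (default
25 per cluster, one reporting household each) are born uniformly in
the 60 months before the interview; sex, mother's education (4 levels)
and a latent household wealth score (cluster effect + child noise)
follow fixed marginals; ten binary asset indicators are Bernoulli in
the latent score with spread thresholds, which is what the wealth-index
PCA consumes.

**Mortality.**  Sequential monthly Bernoulli deaths over postnatal
months 0–11 with hazard `h0(a) · exp(lp)`;
`lp` contains the covariate log-HRs, a Gaussian cluster random
intercept (SD 0.25), the current month's realised drought-class effect
(defaults: mild log 1.2, severe log 1.5), optional purely gestational
effects (per-prenatal-lag or per-count), and optional
drought × modifier interactions.  The baseline hazards are calibrated
so the marginal IMR under the defaults is ≈60 per 1,000 live births
with ~57% of deaths neonatal, matching the descriptive scale of
large multi-country survey compilations.  The day of death is uniform
within the fatal month — days 0–27 for month 1 — so the 27-day
neonatal cut-off is exercisable; deaths occurring after the interview
are recorded as alive (the cross-sectional design's misclassification,
kept deliberately).

**What the generator does not emulate:** country borders and spatial
covariate structure, migration, multiple births, gestational-age
variation (gestation is fixed at 9 months), correlated asset batteries,
real climate teleconnections, or the DHS coordinate displacement
(available only as optional jitter for robustness tests).  Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline*, not substantive claims about real populations.

## Exposure construction

- Cluster→cell linkage is nearest cell centre; exact-midpoint ties go
  to the lower index (documented convention; with 0.1° floats a true
  tie is essentially unrepresentable).
- The death month is `floor(age_days / 30.44)` capped at 11 (0-based);
  neonatal means `age_days ≤ 27`.  Days 28–30 — impossible in
  generated data, possible in external data — belong to month 0 on
  this conversion but are *not* neonatal; the month-of-death analysis
  maps them to month 2 so its month 1 coincides exactly with the
  neonatal window.
- Person-month rows run on the months-since-conception axis (entry 0,
  events possible from month 9, mirroring the primary design and its
  acknowledged immortal-time caveat); survivors always contribute 21
  rows.  An option restarts the clock at birth.  With a uniform
  9-month gestation the two clocks give *identical* Cox partial
  likelihoods (prenatal rows carry no events and risk sets coincide
  after the shift) — the birth-start variant differs only once
  gestational-exposure covariates enter.
- Wealth quintiles cut the PC1 score at its 20/40/60/80 percentiles
  (score ties at a cut go down); missing quintiles become an explicit
  category by default, complete-case on request.
- The composite cluster id concatenates country and cluster.

## Models

**Extended Cox.**  Weighted partial likelihood on the monthly grid;
Efron tie handling by default (monthly event times are heavily tied;
Breslow is available and is the variant under which
half-weight-duplication invariance is exact).  The Gaussian cluster
random intercept is fitted by penalised partial likelihood — Newton
iterations on `(β, b)` with penalty `‖b‖²/2σ²`, exploiting the
diagonal-plus-low-rank structure of the cluster block — and `σ` is
chosen by maximising the Laplace-approximate integrated likelihood on
a bounded log-scale search (σ estimated on the boundary is reported as
~0).  Wald CIs and p-values come from the penalised information; a
grouped sandwich variance is available for the fixed-effects Breslow
model.  Covariates: sex, residence, mother's education, wealth
quintile, categorical birth month, and a natural cubic spline of birth
year with 3 df (knots at quantiles, linear beyond the boundary knots;
the basis is the classic reduced truncated-power construction).
Zero-variance design columns are dropped; a |coef| > 8 is flagged as
suspected separation.

**Discrete-time cloglog.**  The same design on postnatal child-month
rows with an age-month factor as the baseline hazard, fitted as a
binomial GLM(M) with complementary log-log link; the random intercept
uses penalised IRLS with a Schur-complement solve and the same Laplace
criterion for σ.  For rare events its coefficients approximate the Cox
log-HRs, which is the basis of the model-family agreement check.

**Subgroups.**  An any-drought × modifier interaction added to the
main model; level HRs combine main and interaction coefficients with
their covariance; the modifier's main effect is added explicitly where
the base covariates do not span it (period of birth — the continuous
birth-year spline does not span a step — and the 3-level climate zone,
which gets a joint 2-df Wald test).  The period split defaults to the
median birth year.  No multiple-testing adjustment anywhere, by
design.

**Month-specific lag models.**  For death month `m` (1 = days 0–27),
cases died in `m`, non-cases survived beyond `m`; children dead before
`m`, and children alive but younger than `m` months at the interview,
are excluded.  Exposures: a binary drought indicator at one lag
(−9..−1 prenatal, 1..m postnatal), the pregnancy drought-month count,
or the infancy count through `m`; a pooled post-neonatal analysis
(deaths at days 28–364 vs full-year survivors) uses the nine pregnancy
lags.  All are weighted mixed logistic fits with the main model's
covariates.  Note that at the default 24-month timescale adjacent
months share 23/24 of the accumulation window, so neighbouring lags
are nearly collinear; simulations that need single-lag resolution run
the pipeline at `k = 1`, where monthly classes decorrelate.

## Numerical choices and degenerate inputs

- Linear predictors are clipped at ±200 (Cox) / ±30 (GLM) before
  exponentiation; IRLS weights are floored at 1e-12.
- Newton/IRLS use step-halving; convergence is a relative
  objective-change tolerance of 1e-9 with a gradient-norm check.
- σ-search bounds are [0.01, 3.0] on the SD scale with `xatol` 0.02 on
  the log scale, warm-starting the inner solves.
- Zero events, zero-variance samples, empty modifier levels, windows
  not covered by defined index values, and clusters outside the grid
  all raise typed errors naming the offending unit.
- Event-free factor levels (e.g. a birth month with no deaths) drift
  to large negative coefficients; they are retained (their CIs are
  meaningless but other terms are unaffected) and surface in the
  separation flag.

## Problem sizes used by the shipped experiments

The recovery experiment uses 250 clusters × 80 children (~20,000
children, ~1,100 deaths) per replicate — 20 replicates in the test
suite, 10 in the acceptance script; null-calibration runs use 100
replicates of ~1,000–1,200 children; the model-family agreement check
uses ~10,000 children with baseline hazards scaled to <0.01/month.
These sizes resolve the target effects (per-replicate SE of the severe
log-HR ≈ 0.085) while keeping a full run on one CPU in minutes.

## Known limitations

- The frailty σ is a Laplace/profile estimate; its own uncertainty is
  not reported (as with the penalised-likelihood mixed Cox tools this
  mirrors).
- The robust (sandwich) variance is limited to the fixed-effects
  Breslow Cox.
- The wealth index uses a single PCA across the full asset table; no
  survey-wise harmonisation is attempted.
- The reflected log-logistic fallback is a pragmatic device for
  near-symmetric accumulations; a practitioner indexing real climate
  at short timescales (strong positive skew) will rarely trigger it.
- No multiple imputation; missing wealth is a category or dropped.
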