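# Methods

## The accounting model

National nutrient availability is built from item-level food supply.  For
nutrient *i*, country *c*, year *t*:

```
NUT_itc = Σ_j  supply_jtc · (1 − refuse_j) · density_ij / 100
```

where `supply_jtc` is the gross per-capita supply of food item *j*
(g/person/day), `refuse_j` the item's inedible fraction (constant across
countries and years), and `density_ij` the nutrient density per 100 g edible
portion.  Energy uses the Atwater metabolizable-energy factors — 4 kcal/g
protein, 4 kcal/g carbohydrate, 9 kcal/g fat, 7 kcal/g alcohol — applied to
the *aggregated* macronutrient masses, so the four macronutrient energy
shares close to 100% exactly (tested at 1e−9).

Digestible carbohydrate is never read from the composition table; it is
derived *by difference*:

```
carb = (energy − 4·protein − 9·fat − 7·alcohol) / 4 ,  floored at 0
```

which excludes indigestible fibre.  Real composition tables can make this
negative (stored energy is not an exact Atwater sum); we clamp at zero and
log the item id, since negative digestible carbohydrate has no meaning.
Stored energy (not a recomputed Atwater sum) is the minuend, so the
operation is exact on any source whose energy field is Atwater-consistent.

Availability is an upper bound on intake — pre-waste, household level — and
says nothing about within-country distribution.

Key unit conventions: per-capita conversion uses 365.25 days/year; a
location-year with no supply rows is *missing* (eligible for gap-filling),
never silently zero; every panel entry carries its unit and mixed-unit
arithmetic raises.

## Gap-filling (three-stage spatiotemporal GP)

Sparse panels are completed per nutrient in three stages:

1. **Covariate prior** — linear regression of the value on log
   lag-distributed income (LDI) with super-region intercepts, evaluated at
   every location-year.  LDI is a weighted mean of the current and previous
   9 years of income with linearly decaying weights (10, 9, …, 1)/55,
   renormalised over the available history at the start of a series.  The
   log enters because incomes are positive and right-skewed.  A location
   with no data receives its super-region's line.
2. **Residual smoothing** — each target cell averages all observed stage-1
   residuals with weight = temporal kernel
   `(1 − (|Δt|/(1+max|Δt|))^λ)³` times a spatial tier weight (ζ own
   location, ζ(1−ζ) same super-region, (1−ζ)² elsewhere), normalised to
   sum to 1.  Defaults λ = 0.5, ζ = 0.9.  A target with zero total weight
   (possible at ζ = 1 with no own-location data) keeps the stage-1 prior.
3. **Gaussian process** — per location over years, prior mean =
   stage 1 + 2, Matérn-3/2 covariance (length scale 10 years), observation
   nugget.  Space enters only through stages 1–2; per-location GPs are the
   standard factorisation of this estimator.

Hyperparameter defaults are data-driven: the **nugget** is estimated by the
lag-1 variogram of within-location residuals (half the mean squared
successive difference), which isolates year-to-year noise from smooth
signal; the **amplitude²** is the residual variance minus the nugget
(floored at 10% of the residual variance).  Both can be fixed explicitly.

Uncertainty intervals are the 2.5th/97.5th percentiles of seeded draws from
the *predictive* posterior (latent GP plus nugget), so a held-out
observation should fall inside the 95% band about 95% of the time; our
recovery experiment measures ~94% empirical coverage.  The draw streams are
keyed per (nutrient, location) off the root seed, making reruns
bit-identical.  Filled values are floored at 0 (availability cannot be
negative).

## SDI and aggregation

The socio-demographic index is the geometric mean of three components
min-max rescaled to [0, 1] over the pooled study period: LDI (ascending),
mean education years over age 15 (ascending), and total fertility rate
(descending — lowest fertility maps to 1).  Rescaling is plain min-max on
the raw component.  Quintiles of SDI at a reference year (default: final
year, held fixed across the series for trend reporting) define the five
development levels; level and global series are population-weighted means,
the only weighting consistent with per-person reporting.  Ties in quintile
assignment break lexicographically by location id.

## Trends and substitution

Net change is simply `value(end) − value(start)`.  Substitution is
summarised by cross-country Pearson correlations between macronutrient
energy shares at a fixed year (default: final year); p-values are the
two-sided t transform, unadjusted.  Zero-variance shares flag the pair as
undefined (NaN) rather than raising or returning 0.

## Availability → intake bridge

A national value is split by age group and sex with a positive multiplier
pattern renormalised so the population-weighted group mean equals the
national value.  The intake regression is

```
intake_cast = β · availability_cast + age_a + sex_s + α_super-region + ε
```

fitted as a mixed model with exchangeable super-region intercepts
(statsmodels MixedLM, REML), with a fixed-effects OLS fallback when the
mixed fit does not converge; the fit records which route was used.  Tree
ensembles (random forest, gradient boosting) plug into the same
fit/predict contract through a registry and are smoke-tested, not
seed-exactly asserted, since no canonical hyperparameters exist for them
here.  Out-of-sample evaluation holds out 20% of locations by default
(prediction to new places), or years, or random rows, and reports RMSE and
Pearson r; constant predictions flag r as undefined.

Share-based validation compares the percentage of energy from each
macronutrient between availability and survey intake.  Because shares are
ratios, a uniform retail/household waste factor cancels exactly — this is
why validation is done on shares, and why the generator's waste factor
(default 0.3, a plausible retail+household loss; no published figure
exists) only affects absolute-intake checks.

## The synthetic world

The generator emulates the statistical structure of supply-and-utilization
accounts without any external data:

* **Items** belong to archetypes (staples, produce, animal foods,
  oils/fats, alcoholic beverages) with gamma-distributed macronutrient and
  micronutrient densities; fat subtypes are a Dirichlet split strictly below
  total fat; stored energy is set *forward* as the Atwater sum, making
  carbohydrate-by-difference exactly invertible.
* **Locations** sit on a development continuum (base scores evenly spaced
  on (0, 1), randomly assigned) and close 30% of their remaining gap to 1
  over the study period — ordering is preserved in every year.  Total
  energy scales 1900 → 3300 kcal along the continuum.  The diet mix is a
  convex combination of a staple-heavy low-development profile and an
  animal/fat-tilted high-development profile; each macronutrient share
  along that path is a ratio of two linear functions of development and
  hence monotone, reproducing the nutrition transition (carbohydrate share
  falls, fat and protein shares rise).
* **Noise** on supply quantities is multiplicative log-normal (default SD
  0.05 — a free parameter, no published measurement-error figure exists).
* **Missingness** is Bernoulli per location-year, plus optional
  whole-location gaps emulating countries with no supply ledger.
* **Covariates** are deterministic monotone functions of development
  (income exponential with a common year shock, education linear, fertility
  exponential-decreasing), so monotonicity checks are exact.
  Super-regions partition locations round-robin by development rank —
  exchangeable spatial blocks without a real hierarchy.
* **Survey intake** is β · availability · pattern(a, s) · (1 − waste) plus
  additive age/sex/region effects (scaled to the nutrient's mean) and
  homoscedastic noise (default CV 10% of the mean signal), floored at 0.
  The recoverable slope is β(1 − waste), stored as ground truth.  Age
  groups default to 2–19, 20–34, 35–49, 50–64, 65+ with two sexes — survey
  group definitions are configuration, not science.

All randomness flows from one root seed through named `SeedSequence`
streams (development, composition, supply, covariates, intake), so each
generator and the whole world are individually reproducible.

What the generator does **not** emulate: real commodity taxonomies,
trade/stock/feed accounting, fortification, correlated measurement error
across items, non-stationary survey bias.  Passing recovery tests therefore
demonstrates internal consistency and statistical calibration of the
estimators, not fidelity to any real country's numbers.

## Problem sizes used in the standing experiments

* Gap-filling recovery: 150 locations × 34 years, 100 items, 20% masked,
  10 seeds, 1000 posterior draws.  Reported: held-out RMSE of the full
  smoother vs the covariate-only prior, and empirical 95% interval
  coverage.
* Slope recovery: one 60-location world, 50 replicate surveys, mixed-model
  fits on 5000 matched rows each.  Reported: CI coverage of the true slope
  and mean relative bias.
* Round-trip and closure checks: 1000 composition rows; a 30-location ×
  34-year complete panel.

## Known limitations

* The stage-1 prior is a single global slope on log LDI; strongly nonlinear
  covariate relationships would be absorbed by stages 2–3 rather than the
  prior.
* Per-location GPs cannot propagate uncertainty across locations; interval
  width in fully unobserved locations reflects the prior variance only.
* The intake model's additive effects assume a shared slope across age/sex
  groups; the generator matches this, real surveys need not.
* Reporting rounding (kcal to nearest 5, shares to 0.1) is applied only in
  the summary layer; files carry full precision.
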