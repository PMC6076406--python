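# nutledger

National nutrient availability accounting and analysis for country-year food
supply panels.

Food balance ledgers (supply-and-utilization accounts) record, per commodity,
country, and year, how much food is available for human consumption.
`nutledger` turns such item-level supply into per-capita availability of
energy, macronutrients, and micronutrients; completes sparse country-year
series; situates countries on a development continuum; quantifies
macronutrient substitution; and bridges availability to survey-measured
intake.  It is aimed at nutrition epidemiologists and global-health modellers
who work with supply-side dietary data.

## The model

**Accounting.**  Availability of nutrient *i* in country *c*, year *t* sums
item contributions after removing the inedible (refuse) fraction:

    NUT_itc = Σ_j supply_jtc · (1 − refuse_j) · density_ij / 100

Energy follows the Atwater factors (4 kcal/g protein and carbohydrate,
9 kcal/g fat, 7 kcal/g alcohol) applied to aggregated macronutrient masses,
and digestible carbohydrate is derived by difference,
`(energy − 4P − 9F − 7A)/4`, which excludes indigestible fibre.  The four
macronutrient energy shares therefore close to 100% exactly.

**Gap-filling.**  Sparse panels are completed by a three-stage
spatiotemporal Gaussian-process smoother: a linear prior on log
lag-distributed income with super-region intercepts; weighted residual
smoothing across geography and time; and a per-location Matérn-3/2 GP with
draw-based 95% uncertainty intervals.

**Development.**  The socio-demographic index (SDI) is the geometric mean of
min-max-rescaled lag-distributed income, education, and inverted total
fertility; SDI quintiles define five development levels, aggregated with
population weights.

**Intake bridge.**  `intake = β·availability + age + sex + α_super-region`,
fitted as a mixed-effects model (tree-ensemble regressors plug into the same
contract), validated by out-of-sample RMSE/correlation and by macronutrient
energy-share comparison with surveys — shares are invariant to any uniform
retail/household waste factor.

A fully synthetic world generator (items with Atwater-consistent
compositions, a development-linked nutrition transition, configurable
missingness, simulated surveys) provides ground truth for every stage; see
`docs/methods.md`.

## Worked example

```bash
cat > pipeline.yaml <<'YAML'
out_dir: demo_artifacts
seed: 42
generate:
  n_items: 40
  n_locations: 25
  year_start: 1980
  year_end: 2013
  n_super_regions: 4
  missing_fraction: 0.2
stgpr:
  n_draws: 500
nutrients: [energy_kcal, protein_kcal, carbohydrate_kcal, fat_kcal, alcohol_kcal, mufa_kcal]
YAML
nutledger run --config pipeline.yaml
nutledger summarise demo_artifacts
```

prints

```
Final-year (2013) availability by scope:
  global: 2840 kcal/person/day (alcohol 2.0%, carbohydrate 52.5%, fat 29.1%, protein 16.4%)
  high: 3155 kcal/person/day (alcohol 2.3%, carbohydrate 47.9%, fat 32.5%, protein 17.3%)
  low: 2455 kcal/person/day (alcohol 1.7%, carbohydrate 59.1%, fat 24.2%, protein 15.0%)
  lower-middle: 2620 kcal/person/day (alcohol 1.8%, carbohydrate 56.4%, fat 26.2%, protein 15.6%)
  middle: 2790 kcal/person/day (alcohol 2.0%, carbohydrate 53.7%, fat 28.2%, protein 16.1%)
  upper-middle: 2995 kcal/person/day (alcohol 2.1%, carbohydrate 50.4%, fat 30.6%, protein 16.8%)
Net change in energy availability over the study period:
  global: +195 kcal/person/day
  ...
```

Energies are rounded to the nearest 5 kcal and shares to one decimal — the
reporting convention; files under `demo_artifacts/` keep full precision.
High-development countries have more energy available, with larger fat and
protein shares and a smaller carbohydrate share — the nutrition transition
that the synthetic world builds in and the pipeline recovers.  The 20% of
location-years masked as unobserved were filled by the smoother before
aggregation.

The same stages are available individually (`nutledger generate / compute /
smooth / sdi / report / validate / predict`) and as library functions
(`nutledger.aggregate_availability`, `nutledger.fill_time_series`, ...).

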