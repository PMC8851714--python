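# Methods

## The problem and the model

The package targets long-format EHR tables: one row per clinic visit,
identified by patient id and visit date, with a mixed roster of binary,
categorical, continuous and date variables. Missingness is treated as an
explicit state throughout (`NaN`/`NaT` in the typed frame); an empty
string, a `0` or a `"no"` read from a file are observed values. Two
properties of clinical data drive the design:

* **Informative missingness.** Entry interfaces record dependent fields
  only when a gating field takes a particular value, so a blank
  downstream cell often logically means "no". This is deterministic
  domain knowledge, not a statistical estimate, and is executed first so
  the recovered variance is available to the statistical stages.
* **Patient-dominated variation.** Vitals vary far more between patients
  than within a patient's short visit window, so a per-patient line in
  time is a better local model than any cohort-level regression — and is
  embarrassingly parallel.

What the deterministic and per-patient stages cannot fill is handled by
multiple imputation by chained equations (MICE) with tree-based
conditional models, under the usual missing-at-random assumption, on a
*patient-level* collapse of the table (one randomly selected visit per
patient) because the chained models are time-invariant.

## Stage details and numerical choices

**Dependency fill.** Rules are data: `{target, fill, when:[{var, is}]}`
with antecedent states `yes` (observed yes), `no_or_filled` ("no" whether
observed or produced by an earlier rule) and `observed`. Rules must form
a DAG over variables; they execute in topological order, so declared
order is irrelevant and the pass is idempotent. Conditions are evaluated
against the current table state: because fills only ever write the
canonical fill value, `yes` antecedents cannot be created by fills, while
chained `no_or_filled` antecedents behave identically on first and
repeated application. An antecedent that is itself missing blocks the
rule — no speculative filling.

**Interpolation.** Eligibility: continuous kind and ≥ 10 distinct
observed values (configurable). The time axis is days since the
patient's first visit; affine reparametrizations do not change fitted
values, so the origin is cosmetic but fixed for reproducibility.
Duplicate-time observations enter the fit through their mean (the
least-squares-consistent choice). Edge gaps are filled by extrapolating
the same fitted line: interior-only interpolation cannot drive a
variable's missingness to zero for observed patients, which is the
stage's contract. Extrapolated values are not clamped by default; an
optional per-variable `[min, max]` clamp applies to filled cells only.
With one observation (or all observations at one time) the fill is the
observed mean; with none the series passes through untouched. After the
pass, a variable's remaining missing cells belong exactly to patients
with zero observations of it.

**CART.** Binary recursive partitioning, greedy over candidate
predictors; split score is SSE reduction (continuous target) or Gini
impurity decrease (categorical target); growth stops at `max_depth`
(default 5), `min_leaf_size` (default 5) or purity. Determinism: score
ties are broken by the first predictor in column order, then the smaller
threshold; leaf-class ties by the smaller class code. Categorical
predictors with more than two levels are ordered once per tree fit by
the mean (or positive-class rate) of the target and then treated as
ordinal — the classical reduction under which contiguous splits of the
ordered levels contain the optimal subset-vs-rest split for regression
and binary targets; for multi-class targets the same ordering by mean
class code is used as a deterministic approximation. Rows with missing
predictor values are routed, at prediction time, to the child that
received more training rows. The split kernels are numba-compiled; an
independent pure-Python exhaustive split search serves as the oracle in
the test suite.

**MICE.** Defaults: m = 5 copies and 5 sweeps per copy. Five copies is
the configuration the framework prescribes; five sweeps matches the
convention of widely used chained-equations implementations and, on the
desk-scale problems the package targets, the per-variable imputed-mean
trace (logged per copy and sweep as a convergence diagnostic, but not
used for early stopping) is flat well before that. Within a sweep,
variables are visited in order of increasing missingness fraction (ties:
column order). Each missing cell is redrawn as a uniform donor from the
observed target values in its terminal leaf, which keeps every imputed
value inside the variable's observed support — the donor-range invariant
the tests check exactly — and preserves conditional spread. Pooling
follows the random-selection scheme: per missing cell, one of the m
copies' final values is selected uniformly (per-copy selection is
available as a config alternative). Rubin's-rules variance pooling is
deliberately out of scope: the product is a single completed dataset for
downstream predictive modeling, not interval estimates. Variables with
zero observed values at patient level cannot be modeled; they are
excluded from the predictor matrix, left missing and reported. Date
variables never enter the engine. A single-row table is an error (no
donors).

**Unit-of-analysis shifts.** Collapse picks one uniformly random visit
per patient (a "least-missing row" mode exists but is off by default;
random selection avoids biasing toward heavily documented visits) and
records provenance row indices. Broadcast writes a patient's imputed
value into that patient's still-missing visit cells only; observed visit
cells always win. Date carry-forward is strictly forward within patient
(rows are date-sorted with file-order ties); leading gaps remain missing
and are visible in the final report.

## The synthetic generator

The generator emulates the registry structure the framework assumes,
with defaults chosen to match the motivating application's printed
shape: 500 patients (desk-scale; the mechanism is unchanged at larger
n), visit counts from a negative binomial matched to mean 32 / sd 23,
truncated to [1, 162] (overdispersed counts are the natural family
here); exponential inter-visit gaps (mean 45 days); 84 variables of
which ≈93% contain missing values and ≈42% are missing more than half;
per-variable missing rates of 10.1%/10.9%/11.0%/84.9% for weight,
systolic/diastolic pressure and CD4 count, with the remaining rates
spread uniformly on either side of 0.5 to hit the roster fractions.
Continuous variables follow patient-specific affine trajectories plus
Gaussian noise. ARV-chain variables are generated so the dependency
rules hold exactly in the complete table (a stop reason can be "yes"
only when the regimen changed), and their masking is informative — only
true-"no" cells can be blank — so the dependency stage can never
contradict ground truth. Insurance enrollment is a patient-level state
drawn from a logistic model on education (coef 1.0 per sd), mean illness
stage (0.8) and age (0.5 per sd), with the intercept calibrated
numerically so visit-level prevalence hits the configured 7%; half of
the enrolled patients switch on mid-follow-up, making the target time-
variant. The target is observed for ≈20% of visits.

What the generator does *not* emulate: clinic-level or spatial
correlation, realistic CD4 dynamics or pharmacokinetics, measurement
error models, or missingness that is not at random (an MNAR-style
mechanism is available via `mask_additional` for robustness experiments
but is not the default). Tests passing on this generator therefore show
that the machinery is correct under the stated structure, not that
imputed values on an arbitrary real registry are unbiased.

## Validation harness

A random forest of 200 bagged CARTs (per-split feature subsample
⌈√p⌉, depth ≤ 12, min leaf 5 — the framework prescribes no
hyperparameters, so these are conventional desk-scale choices) predicts
the binary enrollment target from fourteen features, trained on a random
80% of the rows where the target was *originally observed* and scored on
the rest. Imputed feature values participate; imputed target values are
never scored. F1 is reported for the positive (rare) class, defined 0
when precision + recall is 0. The default split is by row; a
patient-grouped split mode is provided for leakage-aware evaluation.

## Problem sizes and determinism

Default test and acceptance runs use 500 patients (~16,000 visits, 84
variables), 200 interpolation patients, 500-row MICE race tables over 20
replicate seeds — sizes at which the full pipeline completes in seconds
on one CPU while every property under test is already well resolved.
All randomness flows through `numpy.random.SeedSequence` children of a
single seed: generator, collapse, each MICE copy, pooling, forest
bootstraps and splits. Identical seeds give byte-identical output files;
report JSON deliberately excludes wall times for that reason.

## Known limitations

* The chained-equations stage is time-invariant by construction; panel
  or time-aware MICE is future work.
* Broadcast writes a single patient-level value into all of a patient's
  missing visit cells for a variable, flattening within-patient
  variation for MICE-filled variables.
* Backward date gaps (before a patient's first observed date) are never
  filled.
* Multi-class categorical splits use a mean-code level ordering rather
  than exact subset search.
* No outlier screening precedes the per-patient line fits; gross entry
  errors will tilt fills for that patient.
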