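# Methods

## The model

For a disease D and one level RF of a categorical determinant, the package
computes the posterior disease probability

P(D | RF) = P(RF | D) · P(D) / P(RF)

from three ingredients:

- **P(RF | D)** — the proportion of cases exhibiting the level, estimated as
  `count / n_cases` from the case series. Factors are either *exhaustive*
  (mutually exclusive levels covering every case: age band, gender,
  education; proportions sum to 1) or *non-exhaustive* (comorbidity flags a
  patient may carry several of).
- **P(RF)** — the proportion of the general population in the level, taken
  from an external reference table (census/UN statistics). Levels of an
  exhaustive factor need not sum to 1 in the reference: a table restricted
  to adults over 40 covers only part of the population pyramid, and the
  packaged example's age levels cover 30.92%.
- **P(D)** — the prior, an external constant of the model.

The model is strictly univariate per level: no multivariable adjustment, no
interactions, no correlation between determinants. That is the estimand's
definition here, not an approximation to a regression — each row answers
"what is the disease probability in the subpopulation defined by this one
level?"

Posteriors above 1 arise when the three inputs cannot co-exist (a prior too
large for the case/population proportions). They are returned as computed
and flagged infeasible, never clamped or raised as errors: an infeasible
posterior is the diagnostic that the inputs are inconsistent.

## Choice of the prior

Three provenances are supported, because practice needs all three:

- `user_supplied` — an explicit float in (0, 1);
- `observed` — the screened-cohort prevalence `n_cases / n_screened`;
- `auto` (default) — *calibrated* from a published posterior table by
  algebraic inversion: each published row yields
  P(D) = P(D|RF) · P(RF) / P(RF|D); the calibrated prior is the median of
  the per-row values and the maximum absolute deviation from that median is
  reported as a consistency measure. The median (rather than the mean) keeps
  one corrupted row from shifting the calibration.

On the packaged glaucoma tables all 14 rows invert to a common prior of
0.0560 (max deviation 1.0e-4), while the observed prevalence is 0.0213.
The package reports both and makes the 2.7× inconsistency inspectable; the
posterior is exactly linear in the prior, so every posterior in the
published table is inflated by the same factor relative to what the
observed prevalence would give.

## Confidence intervals and rendering

Per-level binomial intervals use `statsmodels`' `proportion_confint`. The
default method is Wald (normal approximation) with bounds clipped to
[0, 1], which is what printed epidemiological tables of this kind use;
Wilson and Clopper–Pearson are available behind the same interface for
small counts. Boundary counts (k = 0, k = n) are snapped to their exact
bounds (0 and 1) to remove floating-point noise.

Percent rendering rounds half-up on the percent scale via `decimal`
arithmetic (float half-even rounding would print 0.5% as "0.4%" in
half-way cases). Posterior "chance of disease" values render at two
decimals with trailing zeros trimmed (0.154 → "15.4"), matching the
published-table convention; CI bounds render at one decimal with an exact
upper bound of 1 printed as "100".

One published value is deliberately *not* reproduced: the whole-cohort
prevalence CI printed as 1.7–2.5% in the source tables is inconsistent with
the Wald interval used for every other row (which gives 1.8–2.4% for
200/9407). The pipeline reports the computed interval; the discrepancy is
asserted in the test suite rather than encoded as truth.

`daniel_sample_size` implements the single-proportion precision formula
n = ⌈z²p(1−p)/d²⌉ with optional loss-to-follow-up inflation. The absolute
precision d is a required input with no default: no principled universal
value exists, and published sample sizes are frequently not recoverable
from the stated inputs (the packaged study's is one such case).

## Bootstrap uncertainty

Published posterior tables of this kind carry no uncertainty statement, so
the package adds a parametric bootstrap: per replicate, exhaustive-factor
case counts are redrawn from a multinomial at the observed proportions and
comorbidity counts from binomials; posteriors are recomputed and percentile
intervals taken. Choices and their reasons:

- **Percentile intervals**, not BCa: the posterior is a smooth ratio of
  proportions and the percentile method is the simplest defensible choice;
  BCa's acceleration estimate adds machinery without changing conclusions
  at these sample sizes.
- **The prior is held fixed by default** — it is an external constant of the
  model, and resampling it would conflate prior uncertainty with sampling
  variation of the case series. When the prior *is* the observed prevalence,
  `resample_prior=True` additionally draws it from the screened-cohort
  binomial. For frequentist coverage of the full estimator (whose variance
  includes the prevalence term) this flag must be on; the coverage
  experiment below uses it.
- **Optional population perturbation** (Dirichlet around the reference
  proportions for exhaustive factors, Beta per comorbidity, concentration
  configurable) propagates uncertainty in the reference table itself, which
  is otherwise treated as exact.
- A single seeded `numpy` generator is threaded through all sampling; no
  global RNG state. Identical seed, identical output.

The interval's point estimate is always the non-resampled posterior, and
intervals are widened minimally if a percentile falls inside the point
(possible only through Monte Carlo discreteness).

## Synthetic cohorts and validation

`SyntheticConfig` specifies exhaustive factor distributions (summing to 1),
comorbidity marginals, a baseline risk and per-level multiplicative risk
ratios; individuals are sampled independently and disease status drawn with
probability `baseline × Π ratios`. The multiplicative link was chosen over a
logistic one because it keeps the generative truth closed-form:

P(D | level ℓ of factor f) = baseline · ratio(ℓ) · Π_{g≠f} E[ratio(g)] ·
Π_c E[ratio(c)]

(under independence), which is what recovery experiments compare against.
Configurations whose maximal reachable risk product exceeds 1 are rejected
at construction with the offending combination named.

`hail_like_config` encodes the study conditions the packaged example
represents: an adult (40+) outpatient cross-section with the UN-reference
age distribution renormalized to the covered bands, a 57.8/42.2 gender
split, 0.62% illiteracy, diabetes (16.2%) and hypertension (25%) flags,
age-risk ratios rising steeply to the 60s, and a baseline solved so the
marginal prevalence is 2% — the regime in which outpatient glaucoma
screening operates.

Validation performed by the test suite on these cohorts:

- **Parameter recovery**: with the prior set to the observed prevalence the
  pipeline's posterior for a level algebraically reduces to the empirical
  conditional frequency `cases-in-level / individuals-in-level`, and over
  100 replicates of n = 200,000 cohorts its bias against the closed-form
  truth is below 0.005 for every level.
- **Bootstrap calibration**: over 2000 independent n = 20,000 cohorts
  (~400 cases each), nominal 95% bootstrap intervals (with the prior
  resampled) cover the closed-form conditional risk of the 60–69 age band
  95.5% of the time. 2000 runs keep the Monte Carlo standard error of this
  estimate at ~0.5 percentage points.
- **Algebraic identities end-to-end**: forward/backward Bayes consistency to
  machine precision, population-weighted posteriors marginalizing to the
  prior for unit-coverage exhaustive factors, and exact linearity of the
  posterior in the prior.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: correlation between determinants (age and
comorbidity burden travel together in clinics), reference-population error
(P(RF) is treated as exact unless explicitly perturbed), diagnostic
misclassification, and continuous covariates (age is categorical; a cohort
mean age is not reproducible from banded counts).

## Numerical conventions

- Proportions are fractions in [0, 1] everywhere inside the package;
  percentages exist only at I/O and rendering boundaries.
- Level labels are Unicode-NFC normalized on read; en-dash range labels
  ("60–69 years") therefore match exactly across files.
- Ranking ties are broken lexicographically on the level label, making
  `rank_top_factors` deterministic. (The packaged example's published
  summary lists its seven levels in a non-sorted order; the package imposes
  descending posterior order and the test compares as a set.)
- Calibration requires ≥ 2 rows; zero population proportions, zero case
  proportions at inversion, and empty cohorts raise typed errors
  (`DomainError`, `ValidationError`) that the CLI maps to exit code 2
  (validation) vs 3 (I/O).

## Known limitations

- The model inherits every bias of its inputs: a reference population from
  a different year or region than the case series silently shifts all
  posteriors. The total-probability diagnostic catches only internal
  inconsistency (coverage and marginalization), not external validity.
- Case-series proportions for rare levels (counts of 2–8 in the packaged
  example) make the corresponding posteriors fragile; the bootstrap
  intervals make this visible but cannot repair it.
- The calibrated prior reproduces a published table's arithmetic; it is not
  evidence about the true disease prevalence, and the package deliberately
  reports it alongside the observed prevalence when both are available.
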