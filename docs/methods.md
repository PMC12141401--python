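# Methods

This note documents the statistical procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Cohort model and exclusions

One row per hospitalization of a patient aged ≥ 60. Two exclusions are
applied before analysis:

1. **Readmissions** — an admission with a discharge-to-readmission gap of
   at most 30 whole days is excluded (`readmission_gap_days ≤ 30`; a
   missing gap marks an index admission). The boundary convention — day 30
   excluded, day 31 retained, gap measured in whole days — is the
   implementer's; same-day discharge/readmit counts as gap 0.
2. **Insufficient laboratory data** — admissions with fewer than 70% of
   panel analytes measured, for which FI-lab is undefined.

The exclusion flow is tallied as readmission-only / labs-only / both /
included, and the four counts always sum to the raw count.

Laboratory results are the *first* result per analyte from the admission
day or the following day: duplicates are resolved by lowest sequence
number, ties by file order. Missing results are absent rows, never
sentinel values, and no imputation is performed anywhere in the pipeline;
models use complete cases on their own terms.

## Scores

**FI-lab.** `abnormal / measured` over the active reference panel
(default: 35 analytes — CBC, electrolytes, renal/liver/protein markers,
lipids, CRP, TSH, HbA1c — with textbook adult intervals, some
sex-specific). Two boundary conventions matter and are fixed here:

- a value exactly equal to a reference limit is **normal** (deviation
  means strictly outside the closed interval);
- eligibility is the exact rational comparison `measured·10 ≥ panel·7`,
  so 25/35 qualifies and 24/35 does not — no rounding of percentages.

The panel is configuration (YAML), not code: sites substitute their own
analyte lists and cut-offs without touching the package. The same holds
for the 40-item clinical deficit schema and the CCI code map.

**FI-lab banding and dichotomisation.** Bands are `< 0.25`, `0.25–0.4`
(inclusive at both ends), `> 0.4`; the binary variable is `FI-lab > 0.4`
(so 0.4 itself codes 0). The band is "high" exactly when the binary
variable is 1. The cutoff is a parameter (`0.345` is the Youden-scan
sensitivity value).

**FI-clinical.** `Σ deficit values / items assessed`, deficits graded
0 / 0.5 / 1, requiring ≥ 80% of the item set assessed (exact rational
comparison again: 32/40 qualifies, 31/40 does not).

**STRATIFY.** Sum of five mandatory binary items; the mental-status item
is the broadened criterion covering confusion, disorientation, or
agitation. The 6-item variant adds the binary FI-lab item. **CCI** uses
Quan's ICD-10 prefix coding with the original Charlson weights;
prefix matching is longest-prefix after stripping dots, and hierarchical
pairs (metastatic disease over malignancy, moderate/severe over mild
liver disease, complicated over uncomplicated diabetes) count once at the
higher weight.

## Logistic models

Six multivariate specifications, all containing age (years, untransformed)
and sex (male = 1, female reference; the direction is documented in the
output rather than assumed self-evident), fitted by maximum likelihood
(IRLS via statsmodels' binomial GLM, convergence tolerance 1e-10).
Confidence intervals are Wald: `exp(unit·(β ± 1.959964·SE))`; profile
likelihood is not used. Odds ratios are reported per point for score-type
predictors and per 0.1 unit for the frailty indices (OR = `exp(0.1·β)`).
Perfect separation or diverging coefficients are flagged as
non-convergence with a diagnostic instead of silently returning huge
estimates. Events-per-variable (events / non-intercept predictors) is
reported as a stability guardrail. Sensitivity covariates (polypharmacy,
CCI) append to the primary model; subgroup runs refit identically within
age (< 75 vs ≥ 75; 75 belongs to the older stratum) and sex strata,
skipping event-free strata with a warning.

## Discrimination and reclassification

**AUROC** is the Mann–Whitney pair statistic with half credit for ties,
computed via midranks; the trapezoidal integral of the ROC curve equals
it to numerical precision, which the tests assert on random instances.
Its standard error and the paired comparison come from the DeLong
structural-component (placement-value) covariance; the comparison p-value
is two-sided normal with no small-sample correction. Rank-identical score
vectors have zero-variance AUC difference and are reported as a
degenerate comparison with p = 1. The implementation was cross-checked
against R's pROC on a fixed fixture (agreement to 1e-12 on AUCs, variances
and p).

**NRI** is the category-free (continuous) version: net proportion of
events whose predicted risk rises plus net proportion of non-events whose
risk falls. Exact ties in predicted risk count for neither direction (the
natural convention; a tie is not a reclassification). The default CI is
the asymptotic (Pencina-style) variance; a percentile bootstrap CI is
available as an option. **IDI** is the change in discrimination slope
(mean risk in events minus mean risk in non-events, new minus old), with
the paired-difference standard error. NRI/IDI are suppressed (`n/a`) for
comparisons whose new model does not contain the reference score, since
"reclassification relative to the reference" is then undefined in the
intended sense — concretely, the FI-lab + FI-clinical model is compared
to the STRATIFY reference by AUROC only.

**Optimal cutpoint** maximizes the Youden index J = sensitivity +
specificity − 1 over midpoints of consecutive observed score values, a
subject being test-positive when its score strictly exceeds the cutoff;
ties in J break toward the lower cutoff.

## Bootstrap internal validation

Efron/Harrell enhanced bootstrap, resampling at admission level with
replacement (one row per admission, no clustering), default B = 1000 with
a mandatory seed:

- **optimism** = mean over resamples of (c on resample − c of the
  resample-fitted model on the original data); corrected c = apparent c −
  optimism, exactly;
- **calibration slope** = mean over resamples of the coefficient from
  refitting the outcome on the bootstrap model's linear predictor in the
  original data (averaged over resamples, not refit once);
- **calibration error**: the observed event probability is a lowess of
  the outcome on predicted probability (span 2/3 on the probability
  scale, configurable; one linear-interpolation pass with a 1%-of-range
  delta for speed); the optimism-corrected curve is the apparent curve
  minus the mean bootstrap-vs-original curve difference, evaluated at the
  observed predictions; the mean and 0.9 quantile of
  |corrected curve − prediction| are reported.

Non-converged resamples (e.g. single-class or separated) are skipped and
counted; a report with > 5% failures is flagged unstable. A degenerate
resampler that returns the original data yields optimism 0 and slope
exactly 1 (the original MLE solves the refit score equations), which the
tests verify. Reports are byte-identical given (B, seed).

## Synthetic cohort generator

The generator emulates the *schema and marginal structure* of an
admission cohort, not any real cohort's joint distribution:

- age truncated-normal (mean 73, SD 7.3, range 60–99), 63.5% male;
- each panel analyte independently out-of-range with probability 0.31
  (so mean FI-lab ≈ 0.31) and independently missing with probability 0.13
  (measured ratio ≈ 0.87); out-of-range values land uniformly on
  (limit, limit + 0.5·width) beyond the violated bound — magnitude is
  irrelevant because the FI-lab coding is binary per analyte;
- five STRATIFY items at prevalences 13.5 / 5.9 / 7.4 / 7.0 / 8.4%;
  forty deficit items with P(1) = 0.07, P(0.5) = 0.08 (mean FI-clinical
  ≈ 0.11); six medication flags at 20%; ICD-10 codes from a ten-condition
  admission mix;
- the fall outcome is Bernoulli from a logistic model on age, sex,
  STRATIFY and the **true** (pre-missingness) deficit fractions — the
  observed FI-lab then estimates that signal from the measured subset, as
  in real data. Default log-odds: 0.02/year age, 0.1 male, ln 1.65 per
  STRATIFY point, ln 1.28 per 0.1 FI-lab, ln 1.25 per 0.1 FI-clinical,
  matching adjusted associations reported for hospital fall cohorts. The
  intercept is solved by bisection so the expected marginal fall rate is
  2.9% (tolerance 1e-4).

Randomness flows from a single seed through named Philox substreams, one
per generated field, each drawn as a vector in row order — record *i*
therefore depends only on its index, and growing the cohort leaves
earlier records' covariates unchanged. (The outcome is the one exception:
its intercept is calibrated on the whole cohort, so it legitimately
depends on n.)

**What the generator does not emulate — and what that means for the
tests.** Deficits are independent by default. A shared logistic-normal
frailty factor (`frailty_sd`) is available and induces both wider FI-lab
spread and positive FI-lab/FI-clinical correlation, but it is off unless
requested: with independent analytes the between-patient SD of FI-lab is
capped near √(p(1−p)/35) ≈ 0.08, roughly half what real cohorts show, so
simulated AUROCs, per-0.1 ORs and NRI/IDI are systematically smaller than
published hospital values. Passing tests therefore demonstrate the
correctness of the estimators and the pipeline's accounting, not the
discrimination achievable on real data.

## Problem sizes and numerical choices

The test suite uses sizes chosen to give stable Monte-Carlo behaviour:
law-of-large-numbers checks at n = 50 000, marginal-rate calibration at
n = 200 000, parameter recovery over 200 replicates of n = 50 000,
DeLong type-I error over 2 000 replicates of n = 1 000, and validation
behaviour at n = 20 000 (B = 200) plus 100 overfit replicates (n = 400,
40 noise predictors, B = 50). The acceptance script runs the full study
at n = 6 200 with B = 200 validation resamples. Quantiles are type-7
(linear interpolation) throughout; Spearman correlations are
tie-corrected with t-approximation p-values; formatted tables round
percentages to one decimal, retaining full precision in the
machine-readable CSVs.

## Known limitations

- Exact analyte cut-off tables and deficit item definitions are
  site-specific; the shipped panel and item schema are sensible defaults,
  not a clinical standard.
- Wald CIs can misbehave at very low event counts; no Firth or other
  penalization is offered because the intended regime (EPV ≫ 10) does not
  need it.
- The NRI/IDI asymptotic variances ignore the estimation uncertainty of
  the underlying risk models (the conventional practice for these
  indices); the bootstrap CI option is provided for the NRI.
- Calibration-error summaries inherit lowess boundary bias at the extreme
  ends of the predicted-risk distribution.
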