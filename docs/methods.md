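# Methods

`frailtrans` implements a complete development-and-internal-validation
workflow for prognostic models of frailty transition in very old,
community-dwelling adults, together with a synthetic cohort generator that
makes every stage testable without access to individual-level cohort data.

## Frailty phenotype and transition taxonomy

Frailty is scored by the physical-phenotype count of five binary deficits
(shrinking, exhaustion, low physical activity, slowness, weakness): three or
more deficits is *frail*, one or two *prefrail*, none *robust*.  Items are
consumed as pre-scored ternary values; the operationalisation of raw
measurements (grip strength, gait speed, activity questionnaires) is
site-specific and left as an adapter point.

**Missing items.** A state is assigned only when it is invariant to every
completion of the missing items: frail requires three observed deficits
(already certain), robust requires five observed non-deficits, prefrail
requires at least one deficit and that even an all-deficit completion could
not reach three.  Every other pattern is *indeterminate*.  This reproduces
the practice of excluding participants with an unscorable baseline without
guessing their state, and is checked exhaustively in the test suite.

**Transitions.** Between baseline and follow-up, a decrease in severity is
*improvement*, an increase *worsening*, equality *no change*.  Death within
the follow-up window is worsening from any state and overrides recorded
follow-up items.  A surviving participant with an indeterminate follow-up
state has an *unknown* transition (lost to follow-up).  Baseline-indeterminate
participants are rejected with an exclusion signal.  No model is ever fit for
*no change*: its risk factors act in opposite directions through improvement
and worsening, so it has no single-direction risk model.

**Predictor derivation.** Dichotomisations follow the printed inequalities
exactly: eGFR strictly < 60 ml/min/1.73 m², ACR ≥ 30 mg/g, polypharmacy ≥ 5
medications, diabetes if HbA1c ≥ 6.5 % or any antidiabetic drug; BMI bands
<25 / 25–29.9 / ≥30 kg/m², hospitalisations 0 / 1–2 / ≥3 per two years.
Missing raw values propagate; negative measurements are rejected.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
calibrated to the published per-gender marginals of the cohort it stands in
for (637 women, 521 men, age ~84 truncated-normal with eligibility at 70,
baseline states 18/44/38 % women and 21/48/31 % men, covariate prevalences
among known values, per-gender missingness at the published unknown rates,
loss to follow-up ≈ 12–13 %).

- Covariates are drawn through a Gaussian copula over latent normals;
  the default correlation is the identity (independence) because only
  marginals are published.  A rank-correlation matrix can be supplied.
- Baseline items are materialised uniformly within the count range defined
  by the drawn state (prefrail: one or two deficits, uniform; frail: three
  to five), since states, not item identities, drive the analysis.
- The **empirical** transition mechanism draws a destination (robust,
  prefrail, frail, death) from per-gender 3×4 matrices.  The default
  entries are an approximate reconstruction from published cross-tabs and
  death shares; they reproduce the published aggregate transition counts
  but are calibrated defaults, not data.
- The **logistic** mechanism draws worsening from a logistic model on the
  candidate predictors with user-set coefficients (then death with a
  per-state conditional probability, fixed at 1 for frail participants),
  and improvement analogously among non-worsening, non-robust rows.  It is
  the truth source for parameter-recovery tests: the worsening indicator is
  exactly logistic in the configured design.
- Missingness is applied last, missing-at-random: per-column marginal rates,
  optionally tilted multiplicatively along one *observed* conditioning
  covariate with the marginal rate preserved in expectation.  MNAR is out of
  scope.

What the defaults do **not** emulate: covariate–transition dependence (the
empirical mechanism is covariate-independent, so selections on default
cohorts are null-model noise), state-dependent loss to follow-up (a single
per-gender rate is used although frail participants were lost more often),
item-level baseline missingness, and multi-wave follow-up.  Passing tests on
synthetic data therefore demonstrate correctness of the machinery and
recovery of known mechanisms, not clinical validity on real cohorts.

A deterministic 1158-row worked-example fixture reconstructs the published
origin×destination counts exactly and is used to verify the descriptive
pipeline against the printed aggregate numbers.

## Multiple imputation

Chained equations over the analysis table (18 candidate predictors, gender,
baseline state, follow-up state), default m = 10 imputations and 10 sweeps
per imputation (a common chained-equations default; the number of sweeps is
configurable).  Variables are visited in ascending missingness order after
an initial marginal-draw fill.  Conditional models on all other variables:

- two-level variables — logistic fit with a small ridge penalty
  (1e-4 per observation, which also serves as the separation fallback
  everywhere in the package) and an approximate multivariate-normal
  posterior draw of the coefficients before the Bernoulli draw;
- multi-level categoricals — multinomial-logistic fit on a bootstrap
  resample of the observed rows (the resample supplies between-imputation
  parameter variability), categorical draw from predicted probabilities;
- continuous — Bayesian normal-linear draw (scaled inverse-χ² draw of the
  residual variance, normal draw of the coefficients, posterior-predictive
  noise).  Predictive-mean matching is deliberately not the default: the
  analytic draw is simpler to verify.

The death flag is treated as fully observed and never imputed (the design
this emulates verified deaths against claims data); the follow-up state of a
deceased participant is the absorbing level `dead`, and the conditional
model for the follow-up state is fit among survivors only, so `dead` is
never drawn.  The transition outcome is recomputed from the imputed
follow-up state, keeping the death-overrides-items rule exact.  All M
datasets agree bitwise on originally observed cells; this is asserted in
tests, together with MCAR prevalence recovery and ≥ 90 % pooled-CI coverage
over 100 seeded replicates.

## Variable selection

Bootstrap-stability selection: from each imputed dataset, B = 200 resamples
(with replacement, at the analysis sample size, within the gender-specific
analysis subset); on each, automatic backward elimination on
AIC = 2k − 2 log L; a candidate is selected if retained in ≥ 50 % of the
M×B samples.  Categorical predictors enter and leave as whole dummy blocks.

- Improvement models are fit on baseline prefrail + frail participants only
  (a robust participant cannot improve); worsening models on all.  Baseline
  frailty state is an ordinary candidate with reference level *frail*.
- Ties on AIC improvement are broken by dropping the block with the smaller
  maximum absolute Wald z in the current fit, then by canonical candidate
  order — selection frequencies are invariant to candidate ordering.
- Resamples in which an outcome class vanishes are redrawn up to ten times,
  then skipped with the tally denominator adjusted.
- An events-per-parameter ratio below 10 raises a warning (not an error),
  echoing the practice of restricting candidates by the event count.

The logistic fitter is a Newton/IRLS solver with step-halving, written for
this inner loop (warm starts across elimination steps); it is cross-checked
against `statsmodels.Logit` and against an independently coded likelihood
maximiser in the tests.  Separation (non-convergence or |β| > 15) triggers
the ridge-stabilised refit and a flag.

## Pooling

Per-imputation fits of the selected terms are combined by Rubin's rules:
pooled estimate q̄ = mean(q_i); total variance T = W + (1 + 1/m) B with W
the mean within-imputation variance and B the between-imputation sample
variance; degrees of freedom by the Barnard–Rubin small-sample formula with
complete-data df = n − k.  Odds ratios and 95 % CIs are exp(q̄ ± t_df √T).
With B numerically zero (duplicated stacks) the df is infinite and the CI
uses the normal quantile; B below 1e-14·max(1, q̄²) is snapped to zero so
the zero-missingness identity (pooled fit ≡ single complete-data fit) holds
exactly.  Post-imputation event counts are reported as the rounded mean of
per-imputation outcome-positive counts.  Collinearity is screened with
variance inflation factors on the full candidate design of the first imputed
dataset (flag threshold 5; exact dependence reported as an infinite
sentinel).

## Internal validation

- **Discrimination.** The c-index is computed by the rank-sum identity
  (equivalent to pairwise enumeration with half-credit ties).  Optimism
  correction follows Harrell's loop per imputation: refit the *fixed
  selected term set* in each of B = 200 bootstrap resamples, optimism_b =
  AUC(boot model on boot sample) − AUC(boot model on original); corrected =
  apparent − mean optimism; the printed single c-index is the mean across
  imputations.  Selection is not re-run inside validation bootstraps — the
  workflow sequences selection before validation, and re-selection would be
  a different (more conservative) estimator; this is an explicit design
  choice.
- **AUC confidence interval.** The SE is the standard deviation of the
  c-index over 2000 outer bootstrap resamples of the (score, outcome) pairs
  of the first imputation's fitted scores (imputations agree on observed
  cells, so their score vectors are near-identical); the CI is the pooled
  corrected c-index ± 1.96 SE truncated to [0, 1].  Fewer than 50
  replications triggers an instability warning; fewer than 2 is an error.
- **Calibration.** Slope: coefficient of a logistic regression of the
  outcome on the linear predictor.  Intercept: offset recalibration
  (outcome on an intercept with the LP as offset).  Bias correction applies
  the same Harrell loop to both quantities per imputation (B = 200); the
  minima/maxima across imputations are reported as ranges.  The calibration
  curve uses decile bins of predicted probability per imputation — no
  smoother, so no bandwidth choice; duplicate bin edges collapse bins.

## Pipeline and reproducibility

`run_full` executes simulate/ingest → classify → describe → impute → select
→ fit → validate for the four gender×outcome models, asserts participant
conservation (improvement analysis n must equal gender n minus baseline
robust n), and writes deterministic JSON/TSV reports plus a manifest with
derived seeds, a configuration hash and the package version.  All
randomness flows from one integer seed through spawned generator streams;
reruns are byte-identical.  Percentages in printed-style tables round half
up to integer percent.

### Problem sizes used in the shipped checks

The test suite and the acceptance script run at sizes chosen to exercise
every code path at desk scale: worked-example fixtures at the published
n = 1158; generator calibration at n = 637 × 200 replicate seeds; stability
bookkeeping at n = 600 with five candidates and the full 10 × 200 = 2000
samples; parameter recovery at n = 5000 with m = 3 and B = 50; overfitting
direction at n = 200, ten noise predictors, 50 replicates.  The full
default configuration (18 candidates, m = 10, B = 200, 2000-rep AUC SE) is
the shipped default of `AnalysisConfig` and runs in tens of minutes on one
core.

## Known limitations

- The synthetic defaults encode published *marginals*; joint structure is
  user-supplied (copula correlations, logistic coefficients).
- The ridge fallback slightly shrinks coefficients in separated bootstrap
  resamples; AIC in those resamples uses the unpenalised log-likelihood at
  the stabilised estimate.
- Calibration intercepts from offset recalibration are near zero by
  construction on the development data; their corrected ranges mainly
  reflect bootstrap variability, while slopes carry the shrinkage signal.
- Time-to-event structure of death is out of scope: death is a competing
  absorbing destination inside a binary transition outcome, not a hazard.
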