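# Methods

## Study design

The package implements a population-based matched case–control analysis of
hip fracture in elderly claims data. Cases are patients aged ≥ 65 whose
*initial* confirmed femoral-fracture diagnosis (ICD-10 prefix S72) falls
inside the selection window (default 2015-01-01 to 2020-12-31); the
diagnosis date is the index date. A patient whose earliest qualifying
diagnosis precedes the window is excluded entirely, so every case is
incident within the window. Every other elderly patient is a control
candidate and receives one uniformly random index date in the window;
candidates must be fracture-free through their own index date
(`control_exclusion: through_index`, incidence-density style; an `ever`
switch excludes anyone with a qualifying diagnosis at any time).

Matching is 1:1, exact on sex and on 5-year age bands anchored at the
65-year eligibility floor: [65,70), [70,75), …, with the top band
absorbing ages 95 and above. The matching algorithm is greedy without
replacement in a seed-determined random case order; within a stratum this
is equivalent to pairing independent random permutations of its cases and
candidates, which is how it is computed. Unmatched cases are dropped and
logged, never fatal. Age-band anchoring at 65 guarantees that both pair
members fall on the same side of the age-75 cutoff that defines the
early-elderly (< 75) and late-elderly (≥ 75) strata, so the stratum label
is taken from the case's age at index.

## Exposure derivation

Prescriptions are collapsed into drug eras per (patient, raw drug code):
each prescription covers `[start, start + days_supplied − 1]` (inclusive
day-level convention) and two coverage intervals merge into one episode
when the uncovered gap between them (`next start − previous end − 1`
days) is at most the grace period of 7 days; overlaps always merge. The
7-day grace period reflects dispensing slack in claims streams; episodes
carry the drug's mapped category.

Per subject at their index date:

- **Concomitant-medication flags (60)** — a category is flagged when some
  episode started strictly before the index date and ended no earlier
  than 7 days before it (continued use, or discontinuation within a week
  of the event).
- **Medication count** — for each day of the window, the number of
  distinct raw drugs with an episode covering that day; the covariate is
  the maximum over the window. The default window is the pre-index week
  `[index − 7, index]` (`count_window: pre`): exposure should precede the
  outcome, and post-index prescriptions are likely fracture treatment. A
  `centered` switch widens the window to `[index − 7, index + 7]` for
  sensitivity analyses. Counting is per raw drug code; the 60 flags are
  per mapped category — a subject on three distinct drugs of one category
  contributes 3 to the count but one flag.
- **Comorbidity flags (16)** — an ICD-10 chapter is flagged when a
  *confirmed* diagnosis in it started strictly before the index date and
  has no end date registered by then (no end date, or an end after the
  index date). Unconfirmed (rule-out) diagnoses never count.

The 16 chapter ranges are the standard ICD-10 chapters (A00–B99
infectious, C00–D48 neoplasms, D50–D89 blood, E, F, G, H00–H59 eye,
H60–H95 ear, I, J, K, L, M, N, R, S00–T98 injury); the 60 medication
categories are ATC-style therapeutic groups. Because real vendor code
lists are proprietary, both maps ship as an editable YAML document with
synthetic code prefixes that the built-in generator emits; running on
other data means replacing the prefixes while keeping the category names.

Descriptive balance is reported as standardized differences: binary
variables use `(p₁ − p₂)/√((p₁(1−p₁) + p₂(1−p₂))/2)` from exact counts,
continuous ones `(m₁ − m₂)/√((s₁² + s₂²)/2)` (unpooled-average-variance
form), both rounded to three decimals for reporting. Variables matched by
design (age category, sex) are balanced exactly and reported with a blank
standardized difference. With zero pooled variance the difference is 0
for equal statistics and signed infinity otherwise.

## Conditional logistic lasso

For a 1:1 matched pair the conditional likelihood depends only on the
covariate difference `d = x_case − x_control`:
`P(the observed case is the case | pair) = σ(d·β)`, so over n pairs

    −log L(β) = Σ_i log(1 + exp(−d_i·β)),

an intercept-free logistic loss on difference rows with all responses 1
(the per-pair intercepts are eliminated by conditioning; no intercept
appears anywhere). The penalized problem adds `λ‖β‖₁`.

Numerics:

- Columns are scaled by the standard deviation of the pair differences
  before penalized fitting (comparable penalization of the count variable
  and the binary flags); coefficients are reported back on the original
  scale. Identically-zero difference columns (perfectly matched
  covariates) are flagged and reported as not estimable (NaN), never as
  OR 1. Constant non-zero columns keep unit scale — they are informative
  and typically signal separation.
- λ_max = max_j |½ Σ_i d_ij| is the sup-norm of the loss gradient at zero
  (KKT entry point); the path is geometric over `n_lambda` points down to
  `lambda_min_ratio · λ_max`, fitted with warm starts.
- Each outer iteration builds the iteratively reweighted least-squares
  quadratic model (weights `p(1−p)` floored at 1e−6) and solves it by
  cyclic coordinate descent with soft-thresholding, using active-set
  cycling with periodic full sweeps. A line search on the exact penalized
  objective guards against overshoot, so the objective is non-increasing
  across outer iterations. Convergence is declared on a maximum
  coefficient change below `tol` (default 1e−7, `max_iter` 10,000 outer
  cycles) or on an objective plateau (relative decrease < 1e−12), which
  terminates the quasi-separated small-sample regime where coefficients
  drift along a flat penalized objective.
- λ selection: 10-fold (pipeline default 5-fold at desk scale)
  cross-validation on out-of-fold conditional deviance, folds
  partitioning pairs — a pair is never split — and keyed to pair ids so
  row order does not matter under a fixed seed. The default rule is
  `lambda_min`; a one-standard-error rule is available.
- The unpenalized fit (used for the one-variable model and the
  count-category forest) is Newton–Raphson with step halving; standard
  errors come from the inverse observed information and 95% bounds are
  Wald. A coefficient magnitude above 15 on the log-odds scale is treated
  as quasi-separation and raised as an error advising penalization.

## Evaluation

Both pair members are scored with the linear predictor `x·β̂` and treated
as independent observations (design prevalence ½). AUC is the
Mann–Whitney statistic with ties counted half; its default 95% interval
is the asymptotic rank-covariance (DeLong-type) method, with a
subject-level stratified bootstrap as an alternative. The operating
cutoff maximizes the Youden index over observed score values, tied maxima
resolved toward the lower cutoff (higher sensitivity); a subject is a
predicted case when score ≥ cutoff, and sensitivity, specificity, PPV and
NPV are reported at that point.

The medication-count forest fits one unpenalized conditional logistic
model per stratum on indicator differences for count categories 1…14 and
≥ 15 with 0 as reference (reference OR fixed at 1, no interval). Sparse
top categories with one-sided discordance would separate the likelihood;
categories with fewer than five discordant pairs or with discordance in
only one direction are reported as not estimable instead.

The nested comparison fits four variable sets (count only; + 16
comorbidities; + 60 medications; all 77) in each stratum — the
one-variable model unpenalized, the rest by the CV-selected lasso — and
tabulates AUC with CI plus the Youden-point metrics. The stepwise
baseline runs forward–backward selection by AIC on the same
pair-difference likelihood, for a like-for-like comparison of selection
sparsity with the lasso. External validation freezes β̂ from the main
window and scores a cohort built with identical rules on a disjoint,
earlier calendar window.

## Synthetic data generator

The generator emulates the structure of an elderly administrative claims
population at desk scale. Defaults are fixed study conditions: ~71.4%
female; integer ages 65–100 from a discretized truncated normal with mean
82.7 and SD 7.6 (birth dates back-computed so the drawn age is the
completed age at the window start); 16 chapter prevalences set to the
published control-arm marginals where available and field-plausible
values otherwise; 60 medication activation probabilities anchored the
same way (expected concurrent count ≈ 5.3), with a sparse
chapter→medication link matrix (e.g. antidiabetics given endocrine
disease) on top of the baselines. The outcome is drawn from a logistic
risk model whose default has a per-medication log-OR of log 1.06, a
handful of non-null chapter and medication effects (anti-Parkinson's
drugs the largest, OR 1.9), and an intercept giving ~13% case prevalence;
optional per-stratum multipliers on the count effect can emulate an
early-/late-elderly contrast.

Event streams are built so that exposure derivation is genuinely
exercised: active diagnoses start before the window and are open-ended
(or end after it); active medication categories are emitted as 30-day
refill chains spanning the whole window, with small jitter gaps (≤ 3
days), an 8–30-day disruption in a configurable fraction of chains
(default 15%) that splits the era in two, and stale decoy chains and
decoy diagnoses (unconfirmed, or closed before the window) on inactive
categories that must *not* produce flags. Persistence across the window
means covariates are recoverable at any in-window index date — in
particular at the independently randomized control index dates — and the
latent truth table enables a round-trip test (≥ 99% of patient-variable
cells recovered; the deliberate era disruptions account for the
remainder). The latent truth is never visible to the analysis stages.

Each stage draws from its own pseudo-random stream derived from the
master seed by a fixed CRC32-hashed label, so enlarging one stage does
not perturb another and the pipeline is reproducible end to end.

What the generator does **not** emulate: realistic disease trajectories,
dosing and strength, correlated comorbidity clusters beyond the sparse
link matrix, calendar trends, or care-seeking behaviour. Passing tests
therefore demonstrate the correctness of the derivation and inference
machinery under the stated generating model, not clinical validity on
real claims.

A faster desk-scale simulator (`simulate_matched_pairs`) draws pair
differences directly from the conditional model with a known coefficient
vector; it backs the parameter-recovery (n = 20,000 pairs, mean absolute
bias < 0.05 at vanishing penalty) and selection-consistency (one true
log-OR of 1.0, 2,000 pairs, ≥ 95/100 replicates) checks at sizes where
full event-stream generation would be wasteful.

## Problem sizes and defaults

The packaged pipeline defaults (5,000 patients, 60-λ path, 5-fold CV) run
in well under a minute on one core; the test suite uses 200–5,000-patient
populations and completes in about a minute. The published study's scale
(~35 million insured, 34,717 pairs) is proprietary and out of scope; the
acceptance surface reproduces its printed descriptive statistics exactly
and validates the solver and metrics against independent oracles
(brute-force minimizers, exhaustive ROC/Youden enumeration, and reference
fits from survival::clogit and pROC frozen into the tests).

## Known limitations

- Greedy random matching is not optimal matching; with scarce strata a
  different order can match a different subset of cases (by design,
  mirroring "randomly selected" control assignment).
- The λ grid is finite; the reported λ is a grid point nearest the CV
  optimum.
- DeLong intervals assume independent subjects; the matched design's
  within-pair correlation is ignored, as is conventional when reporting
  pooled ROC metrics, and a pair-respecting bootstrap is the alternative.
- Ages are computed as floor(days/365.25); band boundaries can differ by
  a day from calendar-exact ages.
- The stepwise baseline uses plain AIC on the conditional likelihood; it
  is a comparison baseline, not a recommended selection procedure.
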