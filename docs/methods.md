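# Methods

This note documents the models, procedures and numerical choices behind
`sleresponse`: a pipeline for classifying 12-month disease-activity
response in systemic lupus erythematosus (SLE) from classic-BILAG visit
data and for ranking baseline predictors of response by stability
selection over repeated cross-validated penalized logistic fits.

## Outcome definitions

Disease activity is measured with the classic BILAG index: eight organ
domains (constitutional, mucocutaneous, neuropsychiatric,
musculoskeletal, cardiorespiratory, vasculitis, renal, haematological),
each graded A (severe) to E (never active). Grades A and B denote
active disease. Two responder states are assessed at the visit nearest
to 12 months after an index visit:

**Major Clinical Response (MCR)** — all of:

1. every domain graded C, D or E (no A or B anywhere);
2. daily oral prednisolone-equivalent dose ≤ 7.5 mg (boundary inclusive);
3. SLEDAI-2K ≤ 4 (boundary inclusive).

**Improvement** — all of:

1. no domain graded A at follow-up;
2. at most one domain graded B, and only in a domain already active
   (A/B) at index — a B in a previously quiet domain counts as a new
   active domain and fails;
3. banded steroid reduction: baseline ≥ 20 mg/day → follow-up ≤ 15;
   baseline in [10, 20) → follow-up ≤ 10; baseline < 10 → no increase.
   The source bands overlap at 20 mg ("≥ 20" and "10–20"); we resolve
   them as half-open intervals [20, ∞), [10, 20), [0, 10), so 20 mg
   falls in the ≥ 20 band (requirement ≤ 15);
4. no increase in SLEDAI-2K from index to follow-up.

A pair whose follow-up visit — or any field a definition needs
(follow-up BILAG, SLEDAI-2K, dose; for Improvement also the index
SLEDAI-2K and dose) — is missing is labelled *unclassifiable*. This is
a data state, never a disease state, and such pairs are dropped before
modelling rather than imputed. Pulse (IV) steroids play no role in
either definition: both name only the daily oral dose. A recorded dose
of 0 means "not on oral steroids"; an absent dose means "not recorded".

## Cohorts

Two analysis cohorts are drawn from a longitudinal registry-style
cohort:

* **Inception**: one index pair per patient whose first (enrolment)
  visit carries a complete BILAG assessment. Patients without a
  baseline assessment are excluded.
* **Active disease** (landmark cohort): for each patient, the first
  visit with ≥ 1 BILAG A or ≥ 2 BILAG B grades becomes the index;
  patients never reaching that level are excluded. Improvement is only
  assessed in this cohort — at enrolment many patients are not active
  enough for the definition to be meaningful, and the library enforces
  this as a contract.

The follow-up visit is the one whose elapsed time from the index lies
in a configurable window, default **(9, 15) months**, nearest to 12
months, with ties resolved to the earlier visit. Annual-visit registry
schedules jitter around 12 months and no canonical tolerance exists;
(9, 15) is symmetric, excludes adjacent annual visits, and is exposed
as a parameter. Only elapsed times matter anywhere in the pipeline:
shifting a patient's entire visit history by a constant changes
nothing.

## Predictor encoding

Baseline (index-visit) predictors are encoded with explicit reference
levels, chosen to match how such cohorts are conventionally reported:

| predictor | encoding | reference |
|---|---|---|
| age at diagnosis | years − 35 (continuous) | — |
| disease duration | years (continuous) | — |
| sex | male indicator | female |
| ethnicity | 4 dummies | Caucasian |
| location | 4 dummies | Canada |
| oral steroid dose | inception: medium [7.5, 30], high > 30; active: moderate (7.5, 30], high > 30 | low (< 7.5 resp. ≤ 7.5); absent dose = low |
| BILAG A/B domain count | inception: 1, ≥ 2; active: ≥ 2 | 0 resp. 1 |
| per-domain activity | 8 indicators of A-or-B | C/D/E |
| SLEDAI-2K | linear; optional quadratic after centring at the sample mean | — |
| SDI | 1, ≥ 2 and "not assessed" dummies | 0 |
| alcohol | > 0 & ≤ 4, > 4 units/week | 0 or not recorded |
| smoking | current, previous | never |
| SF-36 PCS / MCS | ≥ 40 indicators | < 40 |
| medications, serology, comorbidities | binary indicators | absent/negative |

Missing values are kept first-class. Alcohol merges "0 or not
recorded" into the reference level (the one merge the source data
convention evidences). SDI's heavy missingness gets its own dummy.
Every other missing value is filled — median for continuous, mode for
binary, ties toward the smaller value — with a companion `*_missing`
indicator, so the analysis row count is preserved instead of collapsing
to complete cases. Fill values and reference levels are recorded in the
matrix metadata. The quadratic SLEDAI term is computed after centring
at the sample mean to curb collinearity with the linear term; raw
encoding is selectable.

## Penalized logistic fits

For a design matrix X (standardized internally to zero mean, unit
variance per column) and binary outcome y, `fit_penalized_logistic`
minimizes the elastic-net-penalized average negative log-likelihood

    (1/n) Σᵢ log(1 + exp(−ηᵢ sᵢ)) + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

with unpenalized intercept, where α is the mixing parameter (α = 1 is
the lasso). Coefficients are reported on the original column scale;
"selected" means a coefficient that is exactly non-zero.

The solver is the standard IRLS outer loop with cyclic coordinate
descent on the penalized weighted least-squares subproblem, warm-
started along a descending log-spaced λ path from λ_max (the smallest
λ with an all-zero solution) down to λ_max · r with r = 10⁻³ over 20
grid points by default. Soft thresholding makes zeros exact, and the
full-shrinkage limit is exact: at λ ≥ λ_max every coefficient is 0 and
the intercept equals logit(mean(y)). At λ = 0 the fit converges to the
unpenalized maximum-likelihood solution (verified against an
independent ML fit to 10⁻⁶ relative error in the test suite, with the
interior of the path cross-checked against an independent saga solver).

Numerical choices: probabilities are clipped to [10⁻⁹, 1 − 10⁻⁹] and
IRLS weights floored at 10⁻⁹; constant columns are pinned at zero; CD
sweeps iterate the active set between full KKT sweeps; a multi-λ path
stops early once the fit explains 99.9% of the null deviance or the
deviance improvement between consecutive λ stalls below 10⁻⁵ of the
null deviance (the remaining tail is a quasi-separated regime whose
optimum diverges), carrying the last solution forward; single-λ
requests are always solved at their λ.

λ (and, for the elastic net, α over the grid {0.1, 0.3, 0.5, 0.7, 0.9,
1.0}) is tuned by stratified inner cross-validation minimizing mean
binomial deviance (the "min" rule; a one-standard-error rule is
available as `lambda_rule="1se"`). The "min" rule is the default as the
least-assumption reading of tuning "by cross-validation". Inner
standardization statistics come from each training subsample only — no
leakage into held-out folds.

## Stability selection

The model-building procedure repeats an outcome-stratified K-fold split
R times (reference conditions: R = 300, K = 10, i.e. 3000 models). For
each of the R·K training sets, λ is tuned by inner CV, a penalized
logistic model is fitted, its non-zero set logged, and probabilities
predicted for the held-out fold. Per-sample out-of-fold probabilities
are averaged over the R replications and summarized by ROC AUC,
computed as the Mann–Whitney concordance P(score_case > score_control)
+ ½ P(tie) from midranks. A predictor's **selection frequency** is the
exact rational (models with non-zero coefficient) / (R·K); predictors
with frequency strictly above ½ are taken forward to univariate
logistic odds ratios (Wald 95% intervals, exp(β̂ ± 1.96·SE); complete
or quasi-complete separation is flagged with an unbounded interval
rather than raised). A random forest (500 trees, √p features per
split, out-of-fold prediction under the same fold scheme, permutation
importances) over the chosen set serves as a check for interactions
and non-linearity. Folds are stratified by outcome by default — with a
~15–28% outcome at K = 10, unstratified splits risk single-class folds
— with an unstratified flag available.

Everything derives from a single seed: fold draws, inner-CV seeds, and
forest randomness, so identical configuration reproduces bit-identical
results.

### A caution on selection at prediction-optimal λ

The recovery simulations in the test suite exhibit a known property of
this procedure: when the signal is strong, deviance-optimal λ is small,
and a null predictor whose chance correlation with the outcome exceeds
the entry threshold (~ λ) in the *dataset* is then selected in nearly
every one of the R·K models — repeated splitting averages over split
randomness, not over sampling randomness. At n = 2000 with 15 nulls,
a few nulls typically exceed the 50% frequency threshold alongside all
planted effects. Selection frequencies should therefore be read as a
ranking with high sensitivity, not as a false-positive-controlled set;
the null-calibration simulation (no signal anywhere) shows no such
inflation because the tuned λ then stays near λ_max.

## Synthetic cohort generator

Real registry patient-level data are not public, so the pipeline is
exercised end-to-end on synthetic cohorts:

* **Baselines** are sampled independently per field from configured
  marginals emulating published registry baseline tables: 89% female;
  ethnicity/location mixes; per-domain BILAG A-or-B probabilities
  (e.g. renal 0.52, haematological 0.44); SLEDAI-2K from a discretized
  gamma (shape 1.8, scale 4.5, matching a median ≈ 7, IQR ≈ 4–12);
  dose as a 69% on-steroids mixture with a log-normal positive part
  (patients not on oral steroids carry no recorded dose); 66%
  antimalarial use; per-agent immunosuppressant indicators; per-field
  missingness rates for education, serology, SF-36, comorbidities.
* **Outcomes** are planted: the linear predictor is a configurable
  coefficient map over encoded baseline columns — by default the
  natural logs of published univariate odds ratios (illustrative, not
  an estimate of any real generating process) — with the intercept
  solved by root-finding so the mean response probability equals the
  target prevalence (default 0.28). Labels are Bernoulli draws with
  recorded uniforms, so ground truth reproduces exactly.
* **Follow-ups** (~12 months, uniform ±1.5-month jitter) realize the
  intended MCR label by construction: achieved → all domains C/D, dose
  ≤ 7.5, SLEDAI ≤ 4; not achieved → a uniformly drawn non-empty subset
  of {residual A/B, dose > 7.5, SLEDAI > 4} violated. 7% of patients
  (configurable) get no follow-up. Improvement labels are computed,
  never planted — jointly planting both outcomes is over-constrained,
  so the MCR label takes precedence in construction.
* `theoretical_auc` estimates, by Monte Carlo, the AUC of the *true*
  linear predictor against labels it generates — the ceiling any
  fitted model can approach. `sample_planted_design` provides the
  analogous generic design (independent standard-normal columns,
  calibrated intercept) for calibration and recovery studies.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: correlation among baseline predictors
(e.g. dose with immunosuppressant use; a joint distribution is not
recoverable from marginal tables), multi-visit disease trajectories,
centre effects, informative (outcome-dependent) missingness, and any
misalignment between the planted linear model and real disease
biology. Recovery results are statements about the procedure, not
about SLE.

## Problem sizes used in the test and acceptance studies

Simulation studies are run at sizes chosen to make their statistical
assertions sharp while keeping the suite practical: null calibration
at n = 500, 20 noise predictors, R = 30, K = 5 over 20 seeds;
parameter recovery at n = 2000, 5 planted effects (|log-OR| ln 2 to
ln 3, mixed signs) among 15 nulls, R = 30, K = 10 over 10 seeds, with
a 200,000-draw Monte-Carlo AUC ceiling; generator fidelity at
n = 10,000; the end-to-end acceptance study at n = 1500 with R = 20
(inception) and R = 10 (active-disease) replications. Inner CV uses 5
folds and a 20-point λ path in these studies. Binomial tolerances are
3 standard deviations throughout.

## Known limitations

* Selection frequencies at prediction-optimal λ overselect (see the
  caution above); a false-positive-controlled variant (fixed-λ
  stability selection with complementary pairs) is out of scope.
* The univariate odds ratios are unadjusted by design; they show
  direction and strength of association for chosen predictors, not
  independent effects.
* The Improvement definition inherits the printed band overlap at
  20 mg; the half-open resolution is a convention, documented above.
* The generator's independence assumption tends to make selection
  *easier* than in collinear real data; an optional correlation
  structure is a natural extension.
* Only single-landmark analyses are supported: no sustained-response
  definitions across multiple visits, no time-varying covariates
  between index and follow-up.
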