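# Methods

## Model and fitting

All fitting is Cox proportional hazards with the **Breslow** treatment of
tied event times: every event at time *t* shares the same risk-set
denominator Σ_{j: T_j ≥ t} exp(η_j). This matches the plain risk-set sum
in the partial-likelihood objective the pipeline optimizes; Efron and
exact tie corrections are out of scope. The log partial likelihood is
kept on the *sum* scale (no 1/n normalization), so the lasso penalty λ
and `lambda_max` (the smallest penalty with an all-zero solution,
computed from the null-model gradient) live on that scale too.

Unpenalized fits use Newton–Raphson with step halving, convergence when
the relative log-likelihood change falls below 1e-9 (max 100 iterations),
and Wald p-values from the observed information at the optimum.
Covariates that are numerically constant are assigned β = 0 and p = 1
instead of erroring mid-pipeline; a singular information matrix raises an
error advising a ridge stabilizer (`ridge_eps`), which adds ε/2·‖β‖² to
the objective and ε·I to the information.

Penalized fits standardize columns to zero mean and unit variance
internally and report coefficients back on the original scale with exact
zeros preserved. The path solver is scikit-survival's Coxnet coordinate
descent (glmnet parameterization; our sum-scale λ maps to its α = λ/n,
verified against the KKT conditions of our own objective); a short
warm-start path from `lambda_max` down to the target penalty is used for
stability at a single λ.

## Choosing the penalty: prediction vs selection

Two tuning rules are implemented, because they answer different
questions:

- **Cross-validation** (`select_lambda_cv`, `lambda_rule="cv"`):
  Verweij–van Houwelingen cross-validated partial likelihood — each
  fold's held-out contribution is ℓ(full data) − ℓ(training fold), both
  evaluated at the training-fold coefficients; the λ maximizing the sum
  is returned. Folds (default 5) are event-stratified and seeded. This
  targets out-of-sample prediction and, like all CV-minimum lasso rules,
  keeps many small noise coefficients: at the default simulation scale it
  selects 30–50 genes when 5 are truly active.

- **Extended BIC** (`select_lambda_ebic`, `lambda_rule="ebic"`, the
  pipeline default for stages 1 and 3): every distinct support S on the
  100-point log-spaced path (`lambda_min_ratio` 0.01) is refit without
  penalty — the lasso selects, the MLE estimates — and scored with
  −2ℓ(S) + |S|·log d + 2γ·log C(P, |S|), where d is the event count (the
  effective sample size of a partial likelihood) and γ = 0.5. The
  combinatorial term uses the **ambient** gene count P even at stage 3:
  Θ was searched out of all p genes, so the complexity prior must count
  that search. Supports larger than d/3 are skipped as ill-posed. This
  rule targets recovery of the true support, which is the pipeline's
  goal; it is why the selection stages default to it while purely
  predictive fits (the stage-4 penalized fallback and CoxSis's
  dense fallback) keep CV.

## The four stages

Stage 2 re-estimates the C₀ coefficients *jointly* with each candidate's
(the screen maximizes over both), warm-started from the C₀-only fit; the
screening threshold defaults to 1/p with p the post-filter gene count.
Per-candidate fit failures (e.g. a gene collinear with C₀) are logged and
the gene excluded, not fatal. Note what this screen can and cannot do:
it recovers genes whose marginal association is masked by correlation
with C₀ members, but a gene whose only role is a pure multiplicative
interaction with a C₀ gene induces almost no main-effect signal in the
conditional fit (the hazard is nearly invariant under jointly flipping
the pair), so such genes are found only if they also carry a main effect.

Stage 4 builds each unordered pair once — *x_{i₁}x_{i₂}* equals
*x_{i₂}x_{i₁}*, and ordered duplication would make β unidentifiable —
naming pairs `A_B` with A < B lexicographically. Products are formed
from standardized main-effect columns (training-time means/SDs are
recorded in the result so risk scores on new samples rebuild the same
columns); under the penalized fallback the product columns are
re-standardized. The fallback triggers when main + interaction
parameters reach the event count, where the written MLE is ill-posed,
and is flagged in the result.

## Synthetic data

The survival generator emulates the statistical shape of a multi-study
tumor microarray cohort (hundreds of samples by ~10⁴ post-filter genes)
at desk scale: n = 200 samples, p = 1000 genes. Gene values are standard
normal with equicorrelation ρ = 0.3 in blocks of 10 (a crude model of
co-expression modules). The linear predictor holds five main effects of
|β| = 0.8 (alternating sign, one per block) and two interactions of
|β| = 0.6 between main-effect genes; interactions are formed on the
standardized (unit-variance) gene values so effect sizes are comparable.
Event times come from an exponential baseline with rate 0.06 per month
(median ≈ 11.6 months, a realistic aggressive-tumor scale); a Weibull
baseline is available. Censoring is independent exponential whose rate
is root-found so that the expected censoring fraction, given the drawn
event times, equals the target (default 30%); the achieved rate is
recorded and a warning is issued if it misses by more than 0.05.

What the generator does **not** emulate: probe-level measurement noise,
batch effects, heavy-tailed or skewed expression marginals, non-block
correlation, non-proportional hazards, and informative censoring.
Passing tests therefore show correct behavior under a clean Gaussian
proportional-hazards world, not robustness to real microarray artifacts.

The RPPA generator draws protein baselines log-normally (median 1000
a.u., log-SD 1 across proteins) and multiplies replicate noise that is
log-normal with coefficient of variation 0.1 (m = 2 replicates, matching
a typical duplicated array run); shifted proteins multiply the
experimental baseline. Null tables give the t-test its nominal type-I
rate; the generator does not model antibody cross-reactivity or spatial
slide artifacts.

## Differential proteins, chi-square

Fold change is the ratio of replicate sums exactly as defined (equal to
the ratio of means at equal m), not the mean of per-replicate ratios;
the boundary FC = 1 is judged DOWN. The t-test defaults to
equal-variance Student (Welch switchable); with both within-group
variances zero, p is 1 for equal means and 0 otherwise. No
multiple-testing correction is applied by default — candidates use a raw
p < 0.05 — and a Benjamini–Hochberg option exists but is off.

The 2×2 chi-square is the uncorrected Pearson statistic
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on 1 df — the uncorrected form is the
one consistent with the reference staining table's printed p-value
(0.036485093 for counts 18, 11, 2, 7) — with Fisher's exact test
available separately for small cells.

## Time-dependent ROC

At horizon t*, cases are samples with an observed event by t* and
controls are samples observed beyond t*. The default estimator is
cumulative/dynamic with IPCW: cases are weighted 1/Ĝ(Tᵢ⁻), where Ĝ is
the Kaplan–Meier estimate of the censoring survival function (the common
control weight 1/Ĝ(t*) cancels); `discard_ambiguous` instead drops
samples censored before t*. Tied scores are averaged over orderings,
which makes the trapezoidal area under the threshold-swept ROC equal the
weighted concordance probability. Algorithm comparison uses repeated
event-stratified 70/30 train/test splits with t* fixed at the median
observed follow-up of the full dataset; this protocol is the package's
own construction.

## Problem sizes and determinism

Simulation-backed tests and the acceptance script use 20 replicates of
the default n = 200 × p = 1000 conditions (a few minutes on one CPU);
unit tests use instances small enough for brute-force oracles (grid or
golden-section maximization of the same partial likelihood, hand-worked
risk-set sums). Every stochastic component takes an explicit seed and is
bit-reproducible; pipeline stages derive per-stage seeds from the run
seed by fixed offsets.

## Known limitations

- Breslow ties only; heavy tie structures (coarsely rounded times) would
  favor Efron's correction.
- The conditional screen is main-effects-only by construction (see
  above); interaction discovery happens inside C at stage 4 and cannot
  add genes beyond C.
- Stage-4 inference (Wald p-values of interaction terms) is
  post-selection and should be read descriptively, not as calibrated
  significance.
- The EBIC tuning default trades a little recall for much higher
  precision; with very weak signals a user wanting maximal sensitivity
  should switch the selection stages to `lambda_rule="cv"`.
- IPCW weights assume censoring independent of covariates; covariate-
  dependent censoring would need a censoring model.
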