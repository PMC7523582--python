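# Methods

## Model and assumptions

The package analyses a point-treatment study with a continuous outcome, a
single dichotomous confounder L, and a binary treatment A:

* L ~ Bernoulli(p), 0 < p < 1 (the degenerate prevalences are excluded:
  a confounder present or absent in everyone cannot confound);
* A | L = l ~ Bernoulli(p_l), with positivity 0 < p_l < 1;
* Y = beta0 + beta·A + lambda·L + sigma·eps, eps ~ N(0, 1).

The analyst observes the surrogate L\* instead of L, with sensitivity
se = P(L\*=1 | L=1) and specificity sp = P(L\*=0 | L=0). Misclassification
is **nondifferential**: L\* is independent of (A, Y) given L. Standard
causal assumptions hold (consistency, no interference, conditional
exchangeability given L, positivity), and the treatment effect is assumed
not to vary across confounder strata, so the conditional and marginal
effects coincide under the linear model — nothing here speaks to
noncollapsibility in nonlinear models.

Two assignment settings are distinguished. If treatment is initiated on
the surrogate itself (the `setting1` generator mode), conditioning on L\*
blocks the backdoor path and neither estimator is biased — the package
verifies this by simulation. The substantive case is `setting2`
(default): treatment depends on the true L while only L\* is available,
and adjustment for L\* leaves residual confounding.

## Bias expressions and their oracles

Everything asymptotic is driven by the exact eight-cell joint law
P(L=l, A=a, L\*=s) = P(L=l)·P(A=a|L=l)·P(L\*=s|L=l) (`confbias.joint`).

* **MSM-IPW.** Weighting by 1/P(A=a | L\*) makes treatment independent of
  L\* in the weighted population, so the weighted regression of Y on
  (1, A) converges to the L\*-standardized contrast
  Σ_s P(L\*=s)[E(Y|A=1,L\*=s) − E(Y|A=0,L\*=s)]. Under the linear outcome
  model its deviation from beta is
  lambda · Σ_s P(L\*=s)[P(L=1|A=1,L\*=s) − P(L=1|A=0,L\*=s)].
* **Conditional model.** The main-effects regression of Y on (1, A, L\*)
  is misspecified: the implied true regression contains an A×L\*
  interaction (E[L | A, L\*] depends on both arguments). The A-coefficient
  converges to beta + lambda·alpha_A with alpha_A the A-coefficient of
  the population least-squares projection of L onto (1, A, L\*), solved
  from the 3×3 normal equations.

Each expression is implemented twice, by deliberately disjoint routes:
a scalar algebraic form (`bias_msm`, `bias_conditional`, the latter via
Cramer's rule on closed-form moments) and a brute-force oracle that only
marginalizes/Bayes-inverts the joint table and solves the normal
equations numerically. The test suite holds the two routes to 1e-10 over
1,000 seeded random parameter draws (probabilities in (0.05, 0.95),
accuracies in (0.5, 1], lambda in [−5, 5]); all exact identities
(normalization, marginals, nondifferentiality, null-bias conditions)
are asserted to 1e-12.

Structural facts verified as properties rather than assumed: bias is null
iff classification is perfect, lambda = 0, or p0 = p1; the two methods'
biases always share a sign; bias is linear in lambda; for fixed
specificity, |bias| is minimal at sensitivity 1 and maximal where
sensitivity equals 1 − specificity. The diagnostic `conditional_bias_terms`
exposes the alpha coefficients and the conditional/MSM bias ratio
(`curly_factor`, NaN when the MSM bias is numerically null, threshold
1e-12); equality of biases is decided numerically, not from symbolic
conditions. One parameter set in the packaged scenarios
(p = 0.45, p0 = 0.50, p1 = 0.75) gives biases equal at 2-decimal
precision (0.1490 vs 0.1486) though not identically — the classification
tolerance is an explicit argument for exactly this reason.

## Estimators

* `fit_conditional`: OLS of Y on (1, A, L\*); classical model-based SE.
* `fit_msm_ipw`: propensities estimated as the empirical treated fraction
  per L\* stratum (saturated; algebraically identical to a logistic fit
  with a binary regressor — asserted against statsmodels in the tests),
  unstabilized weights 1/P̂(A=A_i | L\*_i), weighted least squares of Y on
  (1, A), and an HC0 sandwich SE treating the weights as fixed. Ignoring
  the weight-estimation step makes the SE conservative — this is the
  commonly used procedure whose properties the simulation study measures,
  so no bootstrap or linearization refinement is offered.

Both report normal-based 95% CIs (z = 1.96). Degenerate inputs fail
loudly: fewer than 4 rows, a missing treatment arm or surrogate stratum,
a collinear design, or an empty (A, L\*) cell (in-sample positivity).
With the saturated propensity the weights sum exactly to n within each
treatment arm, which the tests exploit.

## Simulation engine

`run_simulation` executes generate → fit(conditional) → fit(MSM-IPW)
over R replicates. Per-replicate RNG streams are seeded as
`default_rng([seed, rep_index])`, so replicates are order-independent and
the whole summary is bit-for-bit reproducible. Replicates where an
estimator fails (empty (A, L\*) cell — realistically only at small n) are
excluded and counted; the run aborts when more than 1% fail, so reported
measures are never silently built on a trimmed sample.

Performance measures and their Monte Carlo SEs follow standard
simulation-study practice: bias (MCSE empSE/√R), empirical SE
(empSE/√(2(R−1))), MSE (SD of squared errors/√R), coverage
(√(c(1−c)/R)), mean model SE (SD of SEs/√R). Coverage counts the same
±1.96·SE intervals the estimators emit.

Defaults mirror the study conditions the package reproduces: five
scenario files ship in `confbias/scenarios` (beta = 1, lambda = 2,
sigma = 1, beta0 = 0 throughout; accuracy (0.90, 0.95) except the
error-free scenario), with R = 5,000 replicates at n = 1,000 for the
full-scale runs in `scripts/acceptance.py`. The outcome intercept and
residual SD are not part of the published parameter tables; beta0 = 0 and
sigma = 1 are adopted as defaults, and sigma = 1 is corroborated by the
reproduced empirical SE of ≈0.07 at n = 1,000 in the error-free scenario.
The published table's scenario rows 2 and 3 are keyed here to explicit
parameter values rather than labels, because the two independent bias
oracles show the printed biases for those rows correspond to
(p = 0.8, p0 = 0.50, p1 = 0.75) → 0.14/0.16 and
(p = 0.8, p0 = 0.25, p1 = 0.75) → 0.29/0.32 respectively.

## Quantitative bias analysis

Priors over (se, sp): uniform, symmetric triangular, or trapezoidal with
modes at one third and two thirds of the support; the two accuracies are
drawn independently from the same marginal (no correlation structure is
modeled). Sampling uses scipy's uniform/triang/trapezoid distributions;
the trapezoid's lower mode is its exact first quartile, which the tests
assert. A degenerate (point-mass) support is allowed for the uniform
kind, which is how "known accuracy" analyses are expressed.

For each draw, the bias-formula inputs are re-estimated from the data:

* `naive`: read p, (p0, p1) and lambda off the surrogate directly
  (lambda as the L\*-coefficient of OLS Y ~ A + L\*);
* `matrix` (default): invert the misclassification matrix — prevalence
  from P(L\*=1) = se·p + (1−sp)(1−p); the true treated-by-confounder
  cells from the analogous 2×2 system; lambda as the coefficient of the
  Bayes posterior P(L=1 | A, L\*) (implied by the corrected parameters)
  in a regression of Y on A and that posterior. Requires se + sp > 1;
  any corrected probability falling outside (0, 1) raises an
  identifiability error naming the offending parameter (the draw is
  inconsistent with the data). Failed draws are skipped and counted; the
  run aborts beyond 5% failures.

Both closed-form biases are evaluated per draw; summaries are mean,
median and IQR (type-7 linear-interpolation quantiles), plus
bias-adjusted estimate distributions (fitted estimate minus bias draw).
With the prior degenerate at the true accuracy, the matrix correction
concentrates the bias draws on the closed-form bias as n grows — the
package's parameter-recovery check.

## What the synthetic generator does and does not emulate

The generator reproduces the stated data-generating law exactly:
Bernoulli confounder, Bernoulli treatment given (true or surrogate)
confounder, Gaussian outcome linear in treatment and confounder,
nondifferential misclassification. It does **not** emulate features of
real observational data — multiple or continuous confounders,
differential or outcome-dependent misclassification, treatment effect
modification, non-Gaussian or heteroskedastic outcomes, missingness.
Passing tests therefore certify the estimators and bias algebra under
the stated model, not robustness beyond it; the QBA on real data (e.g.
the blood-pressure application this methodology is known for) inherits
all of those simplifications.

## Numerical choices

* Probabilities and biases in double precision; closed-form identities
  asserted at 1e-12, route-equivalence at 1e-10.
* Cramer's rule / linear solves guard against singular designs at
  determinant 1e-14 (population) and rank checks at 1e-10 (sample).
* 95% intervals use z = 1.96 everywhere, never t — matching the coverage
  behaviour being studied.
* CSV output at 6 significant digits; JSON at full precision.
* Simulation problem sizes: full-scale runs use 5,000 replicates of
  n = 1,000 (a few seconds each with the closed-form fits); in-suite
  property checks use 200–500 replicates, which keeps Monte Carlo SEs
  around 0.004 — small enough for 3-MCSE comparisons against theory.

## Known limitations

Single binary confounder only; no differential misclassification; no
time-varying treatments or censoring; unstabilized weights only; no
bias-correction estimators (the package quantifies bias, it does not
remove it); the conditional-model bias is for the main-effects fit — the
interaction-adjusted variant is out of scope, though the joint-table
oracle machinery would extend to it.
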