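# Methods

`jmspm` implements two complementary likelihoods for jointly modeling a
sparsely measured longitudinal biomarker (one or two visits per subject)
and mortality in an older-adult family cohort, a synthetic cohort generator
that emulates such a study, preprocessing transforms, and a familial
bootstrap. This note records the models, the numerical choices, and the
limits of what the synthetic validation shows.

## Joint models (current value and shared random effects)

Longitudinal submodel (both variants): a linear mixed model on the
inverse-normal-transformed biomarker with random intercept and slope,

    y_i(t) = x_i(t)'beta + b0_i + b1_i t + eps_i(t),
    b_i ~ N(0, D),  eps ~ N(0, sigma^2),

with t = time since the baseline visit (years) and fixed covariates
(intercept, sex, baseline age per decade centered at 70, one binary
covariate). The survival clock is the same: s_i = event/censoring age minus
baseline age.

Hazard submodels:

* current value: `h_i(t) = h0(t) exp{gamma'w_i + alpha m_i(t)}` with
  m_i(t) the error-free biomarker level; `HR = exp(alpha)` per unit of the
  transformed biomarker.
* shared random effects: `alpha0 b0_i` ("int") or
  `alpha0 b0_i + alpha1 b1_i t` ("intslope", always separate alphas).
  Reported hazard ratios are per SD of the estimated random effects:
  `exp(alpha * SD)`.

`h0` is piecewise constant on six intervals delimited by event-time
sextiles (configurable; fewer segments when event times tie). The marginal
likelihood integrates the two random effects by pseudo-adaptive
Gauss-Hermite quadrature: nodes are centered and scaled per subject by the
empirical-Bayes means and conditional covariances of a first-stage LME fit
(statsmodels MixedLM, ML). Nine nodes per dimension is the default; the
test suite checks the 9-vs-15-node difference is < 1e-3 on reference data.
Because every association structure here makes the log-hazard linear in t,
the within-segment hazard integral has the closed form
`exp(c0) (exp(c1*hi) - exp(c1*lo)) / c1` (series expansion for small c1);
a dense-grid Gauss-Legendre oracle in the tests confirms the assembled
likelihood to 1e-4. Optimization is L-BFGS-B on the packed parameters
(variance parameters on the log scale, D as a log-Cholesky factor), started
from the stage-1 LME plus a biomarker-free piecewise-exponential Poisson
GLM. Standard errors come from a finite-difference Hessian; confidence
intervals are Wald (the conventional choice for these fits).

Residual diagnostics: standardized marginal residuals are
`(y_i - X_i beta)` whitened by the subject's marginal covariance
`Z D Z' + sigma^2 I` (about 95% should fall in (-1.96, 1.96) under a
correct model), and Cox-Snell residuals are posterior expected cumulative
hazards at the event/censoring time, computed with the same quadrature.

### Identifiability with at most two visits

With two random effects and at most two measurements per subject, the
residual variance sigma^2 is identified only through variation in the
second-visit timing (the marginal variance is quadratic in t while sigma^2
is constant). With a tight visit window (SD ~1 y) the ML estimate of
sigma^2 can collapse to the boundary; the generator's default visit-2
offset SD is therefore 2.0 y, and the joint-model validation fixtures use
2.5 y. This mirrors a real limitation of two-visit designs rather than an
implementation artifact. Similarly, the random-slope variance is weakly
identified; "intslope" fits flag `alpha1` as weakly identified when the
stage-1 slope variance falls below 1e-4 (slope SD < 0.01/y).

## Stochastic process model

The biomarker follows a mean-reverting linear SDE with a hazard quadratic
in the deviation from an age-dependent optimum:

    dY = a(t,c) (Y - f1(t,c)) dt + b(t,c) dW,
    mu(t,c,Y) = mu0(t,c) + Q(t,c) (Y - f0(t,c))^2,

with all components linear in (t - 50) plus a sex shift, b age-constant,
`ln mu0` Gompertz with a covariate term (sex plus the binary covariate;
age is the time variable so baseline age is not a covariate), and
`Y(t0) ~ N(f1(t0,c), sigma0^2)`. Interpretation: a < 0 is adaptive
capacity (resilience), Q the vulnerability to deviations from the optimum
(robustness), and `AL(t,c) = |f0 - f1|` the allostatic-load measure.

Likelihood: the discrete-time conditional-Gaussian recursion. Between
observations the conditional mean m and variance gamma evolve by

    dm     = [a (m - f1) - 2 gamma Q (m - f0)] dt
    dgamma = [2 a gamma + b^2 - 2 Q gamma^2] dt

on an Euler grid (default step 0.1 y, left-point hazard accumulation,
gamma floored at 0), the survival factor is `exp(-int mu0 + Q[(m-f0)^2 +
gamma] dt)` with `ln(mu0 + Q[(m-f0)^2 + gamma])` added at death, and each
measurement contributes a Gaussian density after which the recursion
restarts from (y, 0) — observations are treated as exact because the SDE
carries no measurement-error term and the transformed values enter
directly. For linear drift and quadratic log-weights the Gaussian closure
is exact in continuous time; the tests verify the implementation against a
brute-force path-simulation oracle (survival-weighted Euler paths with the
final-step transition density evaluated exactly) to within 3 Monte-Carlo
SEs, and against closed-form Ornstein-Uhlenbeck and Gompertz limits.

Fitting: L-BFGS-B with finite-difference gradients on rescaled
coordinates (each parameter divided by a characteristic scale, FD step
1e-6 in scaled units), sign constraints as bounds (aY <= -1e-6, sigmas >=
1e-3), and deterministic data-driven starts (least squares of y on age and
sex for f1; residual SD for the sigmas; a Gompertz-only survival prefit
for mu0; `aQ = 1e-3 / residual variance`). Two numerical choices matter:

* Q(t,c) >= 0 is enforced during fitting by a smooth quadratic penalty at
  the corners of the observed age window, in addition to the 1e-12 floor
  inside the likelihood kernel. A floor alone turns linear Q into a hinge
  that the optimizer can exploit as an age-threshold switch.
* bY (the age trend of the feedback coefficient) is left unconstrained in
  the fit although the canonical parameterization declares bY >= 0: a
  bound at zero would put the AnoT null on the parameter boundary and turn
  its LRT null distribution into a chi-square mixture; leaving it free
  keeps all twelve tests on the standard chi-square scale.

Because small samples produce long flat valleys, fits restart L-BFGS from
the incumbent until the objective stabilizes, and cold starts also try a
staged path (hazard-curvature age/sex terms pinned at zero first, then
released), keeping the better optimum. The hypothesis suite warm-starts
every restricted fit from the unrestricted solution and re-polishes the
unrestricted fit if a restricted fit ever exceeds it, so the nesting
inequality holds on every cohort the suite is run on.

The 12 null hypotheses remove age trends (…noT), sex differences (…noC),
or whole components: Qzero {aQ=bQ=betaQ=0, df 3}, QnoT {bQ=0}, QnoC
{betaQ=0}, AnoT {bY=0}, AnoC {betaY=0}, BnoC {betaW=0}, F1noT {bf1=0},
F1noC {betaf1=0}, F0noT {bf0=0}, F0noC {betaf0=0}, ALzero {f0 ≡ f1 via
equality ties, df 3}, ALnoT {bf1=bf0=0, df 2}. p-values are upper-tail
chi-square of the (zero-clipped) LR statistic.

## Synthetic cohort generator

`generate_cohort` emulates a two-visit family longevity study: 555
families (size 1 + Poisson(5.24), ~6.2 subjects), 55.1% female, baseline
age truncated normal 70.3 ± 15.2 on [25, 104], visit 2 at +7.5 ± 2.0 y
(>= 1 y) attended with probability 0.54 by surviving subjects, 18-y
administrative censoring, one extra binary covariate ("smoker", p=0.432).
Trajectories and deaths come from Euler-Maruyama simulation of the SPM
itself (step 0.05 y, finer than the likelihood grid; death within a step
placed at the step's end). The default truth has f1 declining with age and
higher in females, f0 rising with age, Q increasing with age and slightly
smaller in males, near-constant feedback a ≈ -0.25/y, and a Gompertz level
calibrated once so ~36% of subjects die within follow-up; under these
conditions the implied current-value association is clearly negative
(higher biomarker, lower mortality), matching the qualitative pattern the
models are designed to detect. Families share no random effect by default
(the fitted models assume independence); an optional family-level
log-normal frailty on mu0 exists solely to exercise the familial
bootstrap.

What the generator does **not** emulate: raw LC/MS intensities, batch
effects, informative dropout beyond death, covariate-dependent visit
attendance, or real family-level dependence. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions and
calibrated null behavior — not robustness to the violations real cohort
data may exhibit.

## Preprocessing

Half-minimum imputation replaces exact zeros by half the smallest positive
intensity. The inverse-normal transformation maps average ranks through
`Phi^{-1}((r - 3/8) / (n + 1/4))` (Blom offset, configurable), computed on
the pooled analytic sample (both visits together).

## Familial bootstrap

Each replicate draws families with replacement until the original family
count is reached (subject counts vary), relabels subjects, and refits the
statistic; the summary is the median and min-max range. Failed replicates
are dropped and recorded; more than 10% failures marks the summary invalid.
Resampling is unstratified.

## Simulation sizes and tolerances

Validation runs at desk scale, chosen as the smallest sizes at which each
check is informative: path-simulation oracle with 1.2e5 paths at step 0.01
on three subjects; SPM recovery over 5 replicates of ~1,000-subject
cohorts (coverage of truth by ±2 numerical SEs for >= 80% of
parameter-replicate pairs; at ~600 subjects the quadratic-hazard block is
occasionally absorbed by the baseline — its MLE genuinely sits near Q = 0
for some realizations — so recovery is assessed at the larger size);
joint-model recovery over 8 replicates of 350 subjects (mean alpha within
±0.05 of truth, Wald CI coverage within the binomial band); LRT type-I
error over 20 null replicates of ~220-subject cohorts with truth-started
fits (a variance-reduction device for the simulation only), rejection
counts within the exact binomial 95% band at nominal 0.05. The acceptance
script reruns the full pipeline on a ~950-subject cohort, with the
familial bootstrap run at 12 replicates on a ~380-subject cohort (the
reference analysis style uses 100 replicates; the median/min-max summary
is already informative at this scale, though the range is wider than a
full-size bootstrap would give). Parameter covariance matrices come from a
finite-difference Hessian in rescaled coordinates with eigenvalues floored
at 1e-6 of the largest, so unidentified directions report large bounded
variances rather than spurious zeros.

## Known limitations

Single biomarker only (no multivariate JM/SPM); linear age shapes for the
SPM components; no frailty inside either likelihood (the bootstrap is the
cluster-uncertainty device); Wald intervals rather than profile
likelihood; piecewise-constant baseline rather than splines; the SPM
treats measurements as error-free, so heavy measurement noise would bias
its component estimates.
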