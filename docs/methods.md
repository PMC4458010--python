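# Methods

## Model and estimation

The analysis model is a logistic GLMM with a single cluster-level random
intercept (compound symmetry):

```
y_ij | b_i ~ Bernoulli(mu_ij),  logit(mu_ij) = alpha + beta x_i + b_i,
b_i ~ N(0, tau^2),
```

with cluster-constant covariates (intercept and arm indicator). Fitting is
by the classical pseudo-likelihood scheme: linearize around the current
`(beta, b)` to form the working response `z = eta + (y - mu)/(mu(1-mu))`
and weights `w = mu(1-mu)`, fit the working linear mixed model
`z = X beta + Z b + e` with `Var(b) = tau^2 I_K`, `Var(e) = phi W^{-1}` by
REML, update `b` by BLUP, and iterate to a fixed point. This is the
estimation scheme whose degrees-of-freedom corrections
(Satterthwaite, Kenward-Roger) operate on the working linear mixed model;
adaptive-quadrature or Laplace maximum likelihood is deliberately out of
scope. ML on the working model is available via `FitOptions(reml=False)`.

All per-cluster linear algebra uses the Sherman-Morrison rank-one identity
for `V_i = tau^2 J + phi W_i^{-1}` (O(n_i) per cluster, never a dense
inverse), and because the fixed effects are cluster-constant every p-by-p
cross-product reduces to per-cluster scalars. This is what makes
5000-replicate Monte-Carlo grids affordable on one CPU.

### The sign of tau^2

The between-cluster component is treated as a **compound-symmetry
covariance**, not a variance: the REML optimizer may take `tau^2`
negative, down to the positive-definiteness limit
`tau^2/phi > -1/max_i(sum_j w_ij)` of the working covariance. This matters
scientifically, not just numerically. If `tau^2` is clamped at zero, then
whenever the between-cluster mean square happens to fall below the
within-cluster one (about half the time under a near-zero true ICC) the
clamped fit over-states `Var(beta-hat)`, and *every* DDF method becomes
conservative — in 5000-replicate runs at K = 10, nbar = 50, cv = 0.5,
ICC = 0.01 the Between-Within test rejects at 0.032 instead of 0.05. With
the unbounded compound-symmetry fit the same scenario gives the behaviour
the methods literature reports: Residual liberal (0.089), Between-Within
nominal (0.052), Satterthwaite (0.037) and Kenward-Roger (0.031)
conservative. The unbounded fit is therefore the default;
`FitOptions(allow_negative_tau2=False)` restores the clamped variant
(flagging `tau2_boundary` when pinned at zero).

Fits whose optimum is pinned at the positive-definiteness limit itself are
flagged `cs_boundary` and reported as non-converged: the working
covariance is numerically singular there, the Wald statistic explodes
(such replicates reject a null about half the time), and the Monte-Carlo
driver excludes them from a method's denominator along with other
convergence failures. Their frequency is reported; it stays below ~5-6%
in the scenario grids studied here.

### Degrees-of-freedom machinery

For the rank-one arm contrast `L = [0, 1]`:

- **Residual** `N - rank(X)`, **Containment** `N - K`, **Between-Within**
  `K - rank(X)` are closed-form design quantities.
- **Satterthwaite**: `d = 2 (L C L')^2 / Var[L C L']` with
  `C = (X'V^{-1}X)^{-1}`. The delta-method variance is `g' A g`, where `g`
  is the analytic gradient of `L C L'` in `theta = (tau^2, phi)` (via
  `dC/dtheta = C (X'V^{-1} dV V^{-1} X) C`, with `dV/dtau^2 = ZZ'` and
  `dV/dphi = W^{-1}`), and `A` is the inverse REML information of `theta`.
  Expected (Fisher) information is the default; observed information is
  available (`reml_information(..., expected=False)`) and is what the
  finite-difference tests check against. `d` is not capped but is flagged
  when it exceeds `N`; a non-positive delta variance (singular information
  at a boundary) fails that method for that replicate only.
- **Kenward-Roger**: the fixed-effects covariance is inflated with the
  two-term second-order correction for covariance structures linear in
  theta, `C_adj = C + 2C [ sum_jk A_jk (N_jk - H_j C H_k) ] C` (the
  second-derivative term vanishes since `d^2V/dtheta^2 = 0`). At r = 1 the
  DDF equals the Satterthwaite value — computed from the *unadjusted*
  covariance, the only reading consistent with reporting identical DDF but
  different standard errors for the two methods — and the statistic's
  residual scale is 1. The adjusted contrast variance is floored at the
  unadjusted one (flagged if the floor binds), so the K-R standard error
  is never reported smaller than the model-based one.

Multi-row contrasts raise `NotImplementedError`: the intervention-effect
test has one numerator degree of freedom, and the spectral multi-df
Satterthwaite machinery is a non-goal.

## Synthetic data generator

The simulator emulates the standard beta-binomial CRT benchmark:

- per-arm marginal event proportion `mu` and ICC `rho` define Beta shapes
  `a = mu(1-rho)/rho`, `b = (1-mu)(1-rho)/rho`; each cluster draws
  `p_i ~ Beta(a, b)` and its subjects are Bernoulli(`p_i`);
- cluster sizes are `max(1, round(Normal(nbar, (nbar*cv)^2)))`. The clamp
  at 1 slightly raises the realized mean and shrinks the realized SD when
  `cv` approaches 1 (at `nbar = 50, cv = 0.5` a draw below 1 is already a
  2-sigma event); this is accepted and not re-normalized, matching the
  generator being emulated;
- the intervention arm's marginal proportion applies the odds ratio on the
  **marginal** scale (`mu1 = 1/3` for `mu0 = 0.25`, OR 1.5), because the
  beta-binomial generator controls marginal moments only. The conditional
  (cluster-specific) odds ratio of the analysis model is slightly larger
  than the marginal one at positive `tau^2`; power figures produced by the
  driver are therefore powers against the marginal alternative.
- defaults: `mu_control = 0.25`; grid axes K in {10, 20, 30}, nbar in
  {20, 50, 100}, cv in {0, 0.25, 0.5, 0.75, 1}, ICC in
  {0.001, 0.01, 0.05, 0.1}; 5000 replicates for type I error and 1000 for
  power.

Arm assignment is deterministic (first K/2 clusters control): randomizing
labels has no distributional effect. Every replicate's stream is spawned
from the master seed by a counter-based scheme
(`SeedSequence(entropy=seed, spawn_key=(rep,))`), so runs are reproducible
replicate-by-replicate and invariant to the degree of parallelism.

What the generator does **not** emulate: covariates beyond the arm
indicator, unequal allocation, informative cluster sizes, non-logit links,
longitudinal structure, or missing data. Passing simulation checks
therefore say nothing about those features of real trials.

The generator's implied latent heterogeneity can be audited two ways:
`latent_logit_variance(mu, rho)` gives the exact `Var(logit p)` under the
Beta law (trigamma identity `psi1(a) + psi1(b)`), and
`empirical_random_effect_variance` fits the intercept-only GLMM to one
large one-arm sample. The two agree to within the PQL linearization bias
(a few percent at cluster size 100). Note the exact values — 0.055 at
ICC 0.01, 0.307 at ICC 0.05 (mu 0.25) — are the package's quadrature-based
diagnostic; they are not calibrated to any external table.

## Numerical choices

- Outer PQL loop: convergence when the max relative change in
  `(beta, tau^2, phi)` falls below 1e-8; at most 200 sweeps; beta
  initialized from plain logistic regression (own IRLS), `b = 0`,
  `tau^2 = 0.1`, `phi = 1`.
- Inner REML step: L-BFGS-B on `(gamma = tau^2/phi, phi)` with analytic
  gradients, warm-started from the previous sweep; bounds as described
  above.
- Working weights floored at 1e-10 (flagged); fitted probabilities within
  1e-10 of 0/1 flag quasi-separation and fail the fit.
- phi is estimated by default (it absorbs over/under-dispersion of the
  working residuals); `fix_phi=True` holds it at 1, and then the
  variance-component covariance `A` is 1x1.
- Singular REML information (flat profile at a boundary) falls back to the
  pseudo-inverse and flags the fit.
- Ties/degenerate inputs: all-identical outcomes or a single arm raise
  validation errors before any fitting.

## Monte-Carlo driver

Rejection uses the upper F tail at two-sided alpha = 0.05 (`p < alpha`).
Rates are computed over converged fits; replicates where a specific method
fails (e.g. non-positive delta variance) leave that method's denominator
only. A scenario is flagged unreliable when more than 5% of replicates
fail. Classification against the nominal band
`alpha ± 1.96 sqrt(alpha(1-alpha)/n)` (rounded to 3 decimals) is
conservative / nominal / liberal; the interval attached to each observed
rate is the 95% Wilson interval, which stays non-degenerate at 0
rejections.

## Problem sizes used by the test suite and acceptance script

The full 180-scenario grid at 5000 replicates is supported
(`crtwald run` or `run_grid(benchmark_grid(), ...)`) but not exercised
wholesale by the test suite; the suite instead runs the individual
scenario-level checks at full 5000-replicate size for the type I error
claims, 500 replicates for the power ordering, and 200 replicates for
parameter recovery — sizes chosen so the whole suite completes in minutes
while each check retains the Monte-Carlo resolution its assertion needs.

## Known limitations

- PQL linearization carries the well-known O(1/n_i) downward bias in
  `tau^2` for binary outcomes: about -4% at cluster size 50 and
  `tau^2 = 0.44`, which is visible against the 3-MCSE bar of the 200-rep
  recovery experiment (the fixed-effect `beta` recovers within its bar).
  Holding `phi = 1` makes this bias slightly worse, not better.
- The variance-component covariance `A` uses expected information by
  default; observed information can differ noticeably in very small K.
- Only the logit link, a single random intercept, and two-arm designs are
  supported; the Containment rule `N - K` hard-codes the random-intercept
  containment structure.
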