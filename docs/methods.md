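# Methods

This note documents the statistical models implemented by `htebayes`,
the numerical choices behind the sampler and diagnostics, what the
synthetic-data generators do and do not emulate, and the design
decisions taken where more than one reasonable convention exists.

## Sampling model and data reduction

All Bayesian models act on per-subgroup summary statistics
`(theta_hat_g, s_g)`, one pair per cell of the full cross-classification
of the declared categorical covariates, under the large-sample
approximation

    theta_hat_g | theta_g ~ Normal(theta_g, s_g^2).

The plug-in of `s_g` ignores uncertainty in the standard error itself;
this is the usual convention for summary-level hierarchical modeling and
is adequate unless subgroups are very small. Subgroup ordering is fixed
and lexicographic (covariates in declaration order, levels in declared
order, last covariate varying fastest); every downstream vector indexes
subgroups by this order. The first declared level of each covariate is
its reference level.

When subject-level data are supplied, the reduction to
`(theta_hat_g, s_g)` is:

- **continuous** — difference of arm means with the pooled two-sample
  standard error (requires at least three subjects so the pooled
  variance is defined);
- **binary** — log-odds ratio with `sqrt(1/a + 1/b + 1/c + 1/d)`. A
  zero cell raises an error rather than applying a continuity
  correction: silent corrections change the estimate, and users can
  pre-aggregate or re-specify subgroups deliberately;
- **survival** — log-hazard ratio and standard error from a
  treatment-only proportional-hazards fit within the subgroup (see
  below). Supplied event times are used as-is; no administrative
  truncation is applied.

Rows with a missing covariate value are dropped with a logged count.

## The proportional-hazards core

`survival_core` maximizes the Breslow-tie partial likelihood by
Newton–Raphson with step halving (the step is halved, up to 30 times,
whenever the log-likelihood would decrease — cheap insurance on tiny
data sets). Conventions and tolerances:

- risk set at an event time `t` is every subject with observed time
  `>= t` (right-continuous), so a censoring recorded at an event time
  stays in that risk set;
- Breslow rather than Efron ties: simpler, and exactly reproducible by
  a desk-scale grid search over the directly evaluated tied likelihood,
  which is how the implementation is tested;
- convergence when the largest absolute score component is below 1e-8,
  with a cap of 50 iterations;
- a coefficient exceeding |beta| > 15 is treated as a monotone
  (separated) likelihood and raises a named error;
- a singular information matrix at the start (no covariate variation
  within any risk set) raises an estimability error — the likelihood is
  flat and no finite maximizer exists.

The covariance is the inverse observed information at the optimum.
Efron ties, stratification, time-varying covariates and robust
variances are out of scope.

## Frequentist comparators

The univariate interaction test fits one covariate at a time:
treatment, the K−1 level indicators, and the K−1 treatment-by-level
products; the unstructured test includes every covariate's main effects
and every treatment-by-level product at once (df = sum_j (K(j)−1)).
Both return the joint Wald test of the interaction block — a single
fit per test, matching how such models are usually reported
(coefficients and standard errors). For small samples the Wald test can
differ from a likelihood-ratio test; no correction is applied.
Continuous outcomes use least squares, binary outcomes logistic
regression (both via statsmodels), survival outcomes the
proportional-hazards core. Bonferroni (`min(1, m p)`) is the only
multiplicity adjustment provided.

## Priors

The half-normal convention is a documented pitfall: `Half-Normal(b^2)`
means the law of `b |Z|`, i.e. `b` is a *scale*. The package's APIs and
configs always take the scale; the conventional defaults
`sigma_tau^2 = 1000` and `sigma_omega^2 = 100` therefore appear as
`tau_scale = sqrt(1000) ~ 31.6` and `omega` scale 10. The quantile
multipliers 0.674 / 1.150 / 2.576 (at p = 0.5 / 0.75 / 0.99) are the
desk reference for judging whether a chosen scale is plausible on the
outcome's effect scale — e.g. on a log-odds or log-hazard scale a
half-normal with scale 1 already puts 99% of its mass below 2.58, a
weakly informative choice, while scale 100 is effectively flat.

The approximate Jeffreys prior on `omega^2` is
`p(omega^2) proportional to omega^(-2)` for `omega^2 >= eps` and flat at
`1/eps` below (default `eps = 0.005`; the density is continuous at the
junction). As written it is improper on the right tail, so inside the
sampler (and the log posterior) it is truncated at `omega <= 100`
(`omega^2 <= 10^4`), far above any plausible effect-scale value. Where
a published sensitivity analysis says "Half-Normal(0.1)" it can mean
scale 0.1 or variance 0.1; the sensitivity grid takes explicit
`PriorSpec` objects so the user states which is meant rather than the
package guessing.

## The seven model structures

Parameter layouts (G subgroups, p1/p2/p3 design columns per interaction
order):

| model | free parameters |
|---|---|
| pooled | tau |
| stratified | theta_1..theta_G |
| basic_shrinkage | theta_1..theta_G, tau, omega |
| basic_regression | tau, beta (p1) |
| dixon_simon | tau, beta (p1), omega |
| regression_plus_shrinkage | tau, beta (p1), phi_1..phi_G, omega |
| extended_dixon_simon | tau, beta (p1), gamma (p2), delta (p3), omega_1..omega_3 |

Design matrices use dummy (reference-level) coding, never sum-to-zero:
`beta_jk` is the change in treatment effect relative to the reference
level, and in the regression models `tau` is the effect in the
all-reference subgroup rather than an average. Higher-order designs are
products of first-order indicator columns from distinct covariates.
The extended model is restricted to interactions of order ≤ 3; with
more than three covariates orders 1–3 are used and higher interactions
are simply not modeled.

Two conventions here were genuinely open and are package choices:

- the seven-model roster is completed by the two non-hierarchical
  endpoints (complete pooling and full stratification) that the
  shrinkage model interpolates between;
- `basic_regression` places independent `Normal(0, sigma_tau^2)` priors
  on each coefficient (no shared variance), and
  `regression_plus_shrinkage` adds an exchangeable subgroup offset
  `phi_g ~ Normal(0, omega^2)` on top of that regression; the
  stratified model reuses `sigma_tau^2` for its independent effects.
  These structures are stated prominently because the literature leaves
  their details to software documentation.

## Posterior computation

Every model here is conditionally linear-Gaussian given its variance
components, so the sampler is Gibbs with exact conditional draws for
all location parameters and univariate slice sampling (stepping-out
plus shrinkage) for each `log(omega)`, with the Jacobian of the log
transform included. Sampling `omega` on the log scale avoids boundary
sticking near zero — precisely the regime a skeptical or concentrated
prior puts mass on.

One structural choice matters for correctness in practice: for the
models with exchangeable latent effects (`basic_shrinkage` and the
`phi` offsets of `regression_plus_shrinkage`) the sampler is *partially
collapsed*. The latent effects are integrated out analytically — the
marginal likelihood is `theta_hat_g ~ Normal(tau, s_g^2 + omega^2)`
(resp. `Normal((A c)_g, s_g^2 + omega^2)`) — and each sweep updates
`omega` by slice sampling on that marginal, then `tau` (or the
coefficient vector) from its marginal normal conditional, then draws
the latent effects exactly from

    theta_g | tau, omega, y ~ Normal(tau + r_g (theta_hat_g - tau), v_g),
    r_g = omega^2/(omega^2 + s_g^2),  v_g = (1/s_g^2 + 1/omega^2)^(-1).

A naive centered Gibbs sweep (theta, then tau given theta, then omega
given theta − tau) is a valid sampler but freezes in the funnel as
omega → 0: theta glues itself to tau and tau moves O(omega/sqrt(G)) per
sweep, so a strongly concentrated omega prior leaves the chain
arbitrarily far from its stationary distribution for any practical run
length. The collapsed scheme removes that coupling exactly (the
marginalization is closed-form in this normal-normal model) and costs
one extra O(G) pass per sweep. The coefficient-block variances of the
Dixon–Simon models keep plain slice updates given their coefficients:
there is no latent-effect funnel in that direction, and the blocks are
low-dimensional.

Remaining sampler conventions:

- defaults 4 chains × 5000 iterations, 2500 burn-in, no thinning —
  ample at desk scale (G up to ~50) because all location updates are
  exact conditional draws;
- initialization is deterministic given the data: theta at theta_hat,
  tau at the precision-weighted mean, omega at the sd of theta_hat
  (floored at 1e-3), coefficients at 0;
- one master seed spawns per-chain `SeedSequence` substreams, so runs
  are bit-reproducible for any chain count;
- split-R-hat (rank-normalized, via ArviZ) is computed per parameter; a
  single chain is split in halves first. Any value above 1.1 flags the
  result non-converged — the flag is returned (and surfaced as a
  nonzero CLI exit code), never raised, so diagnostics are always
  available;
- `run_mcmc(..., fixed={"tau": t, "omega": w})` clamps hyperparameters
  of the shrinkage-family models; with both clamped the theta draws are
  iid from the closed-form conditional, which is how the sampler is
  validated against `conditional_theta_posterior` in the tests;
- Monte-Carlo standard errors use batch means with `floor(sqrt(n))`
  batch size on the pooled draws (chain boundaries are ignored, a
  negligible effect at the default draw counts).

`shrinkage_factors` reports `E[r(omega, s_g) | y]` for the models with a
single `omega` (basic_shrinkage, dixon_simon, regression_plus_shrinkage).
For the extended Dixon–Simon model no single `r` describes the pooling
(three variance components act on different coefficient blocks), so the
operation raises an unsupported-model error rather than reporting
something misleading. The familiar posterior-mean identity
`E(theta_g|y) ~= tau_hat + E(r|y)(theta_hat_g − tau_hat)` neglects the
posterior correlation between `r` and `tau`; empirically the
discrepancy on desk-scale fixtures stays within
`0.02 (|theta_hat_g| + s_g)`, which is the tolerance the test suite
asserts.

## Diagnostics

**DIC.** Deviance is `D(theta) = sum_g ((theta_hat_g − theta_g)/s_g)^2`;
`D_bar` averages it over draws, `p_D = D_bar − D(theta_bar)`, and
`DIC = D_bar + p_D = 2 D_bar − D(theta_bar)` — the identities hold by
construction and are asserted to 1e-10. Because the deviance is
quadratic in theta, Jensen's inequality makes `p_D` nonnegative up to
Monte-Carlo error. The comparison table annotates differences below 3
as not meaningful, following the usual rule of thumb that DIC
differences only start to matter around 3–5.

**Posterior predictive checks.** Replicates are
`theta_hat_g^rep ~ Normal(theta_g^draw, s_g^2)` with one distinct
posterior draw per replicate (sampled without replacement, so `n_rep`
cannot exceed the draw count; default 1000). Statistics are median, sd,
min and max across the G-vector, applied on the `theta_hat` scale — the
scale the models actually see. The tail probability convention is
`P(T(y^rep) >= T(y) | y)` with ties counted in; values outside
(0.05, 0.95) are flagged. These p-values are known to be conservative
(they concentrate near 0.5 when the fitted model is correct), so the
flags are a screening device, not calibrated tests; Meng-style
calibrated versions are a possible extension.

**Sensitivity grids.** Each cell refits the same model structure under
a different `omega` prior with the same master seed, so differences
across cells reflect the priors rather than Monte-Carlo noise. The grid
reports per-subgroup posterior means side by side and the maximum
absolute change across cells; non-converged cells are flagged but
returned.

## Synthetic data generators

`simulate_summary_data` draws directly from the two-stage generative
model (`theta_g ~ Normal(tau, omega^2)`,
`theta_hat_g ~ Normal(theta_g, s_g^2)`) with a user-supplied standard
error profile. It is the exact data-generating process assumed by the
shrinkage model, which is what makes it suitable for calibration
studies (coverage, predictive self-consistency): those tests verify the
inference machinery, not robustness to model misspecification.

`simulate_subject_data` generates subject-level records: normal
outcomes with a mean shift, Bernoulli outcomes with a logistic arm
probability around a baseline of 0.5, or exponential event times with
the specified log-hazard ratio (baseline hazard 1). Censoring is
generated by flipping an independent coin with the stated probability
per subject and, when censored, drawing the observed time uniformly on
(0, event time] — this realizes exactly the requested marginal
censoring rate and keeps censoring independent of arm and covariates.

What these generators do **not** emulate: correlated covariates and
unbalanced subgroup sizes arising from a joint covariate distribution,
non-proportional hazards, overdispersion, measurement error in
covariates, or informative censoring. A test passing on these fixtures
shows the estimator and sampler are correct under the stated model; it
does not certify behavior on real trial data that violate it.

Calibration tests in the suite use fixed problem sizes chosen to keep
the whole suite fast while leaving clear signal margins: G = 12 or 50
subgroups, 100 replicate fits for coverage and predictive
self-consistency, 1000 null replications for test size, and 20k–50k
posterior draws where Monte-Carlo error must be small relative to the
asserted tolerance.

## Known limitations

- Summary-level likelihood only: the Bayesian models never see subject
  records, so small-sample non-normality of `theta_hat_g` propagates
  into the posterior unexamined.
- Continuous effect modifiers are out of scope; covariates must be
  categorical (discretization is the user's responsibility).
- No model averaging, spike-and-slab selection, WAIC/LOO, or Bayes
  factors; DIC is the only comparison criterion.
- The Wald interaction tests can be anticonservative in very small
  samples (no likelihood-ratio or permutation alternative is provided).
- The Jeffreys-prior truncation point `eps` genuinely matters when the
  heterogeneity is near zero; the sensitivity grid is the tool for
  examining that dependence, and no default conclusion is drawn from a
  single `eps`.
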