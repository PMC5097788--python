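# htebayes

Bayesian subgroup analysis of **heterogeneity of treatment effect (HTE)**.

Clinical trials report an average treatment effect, but efficacy often
varies across patient subgroups defined by baseline covariates (sex, age
band, disease severity, ...). Fully stratified per-subgroup estimates are
noisy; classical interaction tests lose power under multiplicity
adjustment and say nothing about effect magnitude. `htebayes` implements
the Bayesian alternative: a suite of hierarchical models that place all
subgroup effects in one joint model so that every subgroup "borrows
strength" from the rest, yielding stabilized estimates and direct
probability statements such as *P(subgroup g benefits | data)*.

The package is aimed at biostatisticians analyzing trial data at the
subgroup level, and at methodologists who need a transparent, fully
scriptable reference implementation of these models with reproducible
MCMC.

## The models

All models share the normal sampling approximation for per-subgroup
summary statistics (mean difference, log-odds ratio or log-hazard ratio
with its standard error):

    theta_hat_g | theta_g ~ Normal(theta_g, s_g^2),    g = 1..G

and differ in the structure placed on the true effects `theta_g`:

| model | structure |
|---|---|
| `pooled` | theta_g = tau (complete pooling) |
| `stratified` | independent theta_g, diffuse priors (no pooling) |
| `basic_shrinkage` | theta_g ~ N(tau, omega^2), tau ~ N(0, sigma_tau^2), omega ~ Half-Normal(sigma_omega^2) |
| `basic_regression` | theta_g = tau + X_g beta, diffuse independent betas |
| `regression_plus_shrinkage` | theta_g = tau + X_g beta + phi_g, phi_g ~ N(0, omega^2) |
| `dixon_simon` | theta_g = tau + X_g beta, beta_jk ~ N(0, omega^2), omega ~ Half-Normal |
| `extended_dixon_simon` | adds 2- and 3-way covariate interactions with per-order variances omega_1..omega_3 |

`X` is the dummy (reference-level) coding of the crossed covariates.
Under the shrinkage model the posterior mean obeys

    E(theta_g | y) ~= tau_hat + E[r(omega, s_g) | y] (theta_hat_g - tau_hat),
    r(omega, s_g) = omega^2 / (omega^2 + s_g^2),

so noisier subgroups (larger `s_g`) are pulled harder toward the overall
effect — the partial-pooling behavior the package is built around.

Around the Bayesian core the package provides: per-subgroup summary
computation from subject-level data (two-sample, log-odds, or a built-in
Cox partial-likelihood fit with Breslow ties), univariate and
unstructured Wald interaction tests with Bonferroni adjustment as
frequentist comparators, DIC model comparison, posterior predictive
checks (median / sd / min / max), prior-sensitivity grids over the
`omega` prior (half-normal scales and an approximate Jeffreys prior),
forest tables, and a CLI.

## Worked example

```python
import numpy as np
import htebayes as hb

frame = hb.build_subgroup_frame([
    hb.CovariateSpec("gender", ["female", "male"]),
    hb.CovariateSpec("age", ["le65", "gt65"]),
    hb.CovariateSpec("ejection_fraction", ["high", "medium", "low"]),
])                                    # 2 x 2 x 3 = 12 subgroups

# synthetic trial summaries with known truth: overall log-hazard ratio
# -0.3, between-subgroup sd 0.25, standard errors 0.1-0.4
truth, data = hb.simulate_summary_data(
    tau=-0.3, omega=0.25, se_profile=np.linspace(0.1, 0.4, 12),
    frame=frame, seed=1)

spec = hb.make_model("basic_shrinkage", frame)
draws = hb.run_mcmc(spec, data, seed=1)      # 4 chains x 5000, split-Rhat checked
summary = hb.summarize_posterior(draws, thresholds=[0.0])
print(summary.params.loc[["tau", "omega"], ["mean", "sd", "q2.5", "q97.5"]].round(3))
```

prints

```
        mean     sd   q2.5  q97.5
tau   -0.249  0.069 -0.382 -0.111
omega  0.097  0.078  0.004  0.291
```

i.e. the estimated overall effect is −0.249 (credible interval −0.38 to
−0.11, covering the generating value −0.3) with modest estimated
heterogeneity. The subgroup table gives shrunken per-subgroup estimates
and direct benefit probabilities (`p_below_0` is P(theta_g < 0 | y),
"benefit" on a log-hazard scale):

```
                     mean   q2.5  q97.5  p_below_0
female/le65/high   -0.266 -0.420 -0.120      1.000
female/le65/medium -0.207 -0.366 -0.002      0.976
...
```

The shrinkage fractions show the differential pooling — the most precise
subgroup (s = 0.10) keeps 40% of its deviation from the overall mean,
the noisiest (s = 0.40) only 8%:

```python
r = hb.shrinkage_factors(draws, data)        # r[0]=0.403, r[-1]=0.075
```

and DIC comparison across models annotates small differences as not
meaningful:

```
               model  d_bar  p_d   dic  delta_dic                      assessment
     basic_shrinkage   9.74 3.21 12.95       0.00                            best
extended_dixon_simon   8.94 5.84 14.78       1.83 difference < 3 (not meaningful)
```

The same pipeline is available from the shell via a YAML run config:

```sh
htebayes simulate -c run.yaml -o out/
htebayes fit      -c run.yaml -o out/   # draws_*.csv, summary_*.csv, provenance.json
htebayes compare  -c run.yaml -o out/   # DIC table
htebayes ppc      -c run.yaml -o out/
htebayes report   -c run.yaml -o out/ --plot forest.png
```

Every command writes a provenance block (config hash, seed, versions);
re-running `fit` with the same config and seed reproduces the draw CSVs
byte for byte.

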