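"""Model comparison and model checking: DIC, posterior predictive
checks, and prior-sensitivity grids.

Under the normal sampling model for the subgroup estimates, the deviance
is D(theta) = sum_g ((theta_hat_g - theta_g)/s_g)^2.  DIC combines the
posterior expected deviance D-bar with the effective number of
parameters p_D = D-bar - D(posterior mean); differences in DIC smaller
than about 3 are conventionally not considered meaningful.

Posterior predictive checks draw replicate estimate vectors
theta_hat^rep ~ Normal(theta^post, s_g^2) and compare summary statistics
T (median, sd, min, max across subgroups) of the replicates against the
observed T(y); the reported tail probability is P(T(y^rep) >= T(y) | y),
with ties counted in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError, InvalidStateError
from .hte_models import ModelSpec, make_model
from .mcmc_engine import PosteriorDraws, PosteriorSummary, run_mcmc, summarize_posterior
from .priors import ModelPriors, PriorSpec
from .subgroup_data import SubgroupSummary

#: DIC differences below this are conventionally "not meaningful"
DIC_MEANINGFUL_DIFFERENCE = 3.0

_STAT_FNS = {
    "median": lambda x: np.median(x, axis=-1),
    "sd": lambda x: np.std(x, axis=-1, ddof=1),
    "min": lambda x: np.min(x, axis=-1),
    "max": lambda x: np.max(x, axis=-1),
}
DEFAULT_STATISTICS = ("median", "sd", "min", "max")


def deviance(theta, data: SubgroupSummary):
    """D(theta) = sum_g ((theta_hat_g - theta_g)/s_g)^2; vectorized over draws."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != data.n_subgroups:
        raise InvalidSpecError(
            f"theta has length {theta.shape[-1]}, expected G={data.n_subgroups}")
    z = (data.theta_hat - theta) / data.se
    out = np.sum(z**2, axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DicResult:
    """DIC triple: D_bar + p_D = 2 D_bar - D(posterior mean) by construction."""

    d_bar: float
    d_at_mean: float
    p_d: float
    dic: float

    @property
    def effective_parameters(self) -> float:
        return self.p_d


def dic(draws: PosteriorDraws, data: SubgroupSummary) -> DicResult:
    """Deviance information criterion from posterior draws of theta."""
    theta = draws.theta()
    if theta.shape[0] == 0:
        raise InvalidStateError("no draws available for DIC")
    d_bar = float(deviance(theta, data).mean())
    d_at_mean = float(deviance(theta.mean(axis=0), data))
    p_d = d_bar - d_at_mean
    return DicResult(d_bar=d_bar, d_at_mean=d_at_mean, p_d=p_d, dic=d_bar + p_d)


def dic_table(results: dict[str, DicResult]) -> pd.DataFrame:
    """Side-by-side DIC comparison, best model first.

    ``delta_dic`` is the difference from the best model; differences
    below 3 are annotated as not meaningful.
    """
    if not results:
        raise InvalidSpecError("no DIC results to tabulate")
    df = pd.DataFrame(
        {"model": list(results), "d_bar": [r.d_bar for r in results.values()],
         "p_d": [r.p_d for r in results.values()],
         "dic": [r.dic for r in results.values()]}).sort_values("dic")
    df["delta_dic"] = df["dic"] - df["dic"].iloc[0]
    df["assessment"] = np.where(
        df["delta_dic"] < DIC_MEANINGFUL_DIFFERENCE,
        f"difference < {DIC_MEANINGFUL_DIFFERENCE:g} (not meaningful)",
        "meaningfully worse")
    df.loc[df.index[0], "assessment"] = "best"
    return df.reset_index(drop=True)


def posterior_predictive_draws(draws: PosteriorDraws, data: SubgroupSummary,
                               n_rep: int = 1000, seed: int = 0) -> np.ndarray:
    """Replicate estimate vectors: theta^post draw plus Normal(0, s_g^2) noise.

    Each of the n_rep rows uses a distinct posterior draw (sampled
    without replacement), so n_rep may not exceed the number of draws.
    """
    theta = draws.theta()
    n = theta.shape[0]
    if n_rep > n:
        raise InvalidSpecError(f"n_rep={n_rep} exceeds the {n} available draws")
    if n_rep < 1:
        raise InvalidSpecError("n_rep must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_rep, replace=False))
    noise = rng.standard_normal((n_rep, data.n_subgroups)) * data.se
    return theta[idx] + noise


@dataclass
class PpcResult:
    """Posterior predictive check: one row per test statistic."""

    table: pd.DataFrame
    n_rep: int

    @property
    def p_values(self) -> dict[str, float]:
        return dict(zip(self.table["statistic"], self.table["p_value"]))

    @property
    def discrepant(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "statistic"].tolist()


def ppc_statistics(replicates, observed: SubgroupSummary,
                   statistics=DEFAULT_STATISTICS) -> PpcResult:
    """Compare T(y^rep) with T(y) for each statistic T.

    p_value = P(T(y^rep) >= T(y) | y) with ties counted; statistics with
    p outside (0.05, 0.95) are flagged as discrepant.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[1] != observed.n_subgroups:
        raise InvalidSpecError("replicates must be an (n_rep x G) table")
    if reps.shape[0] < 100:
        raise InvalidSpecError("at least 100 replicates are required")
    rows = []
    for name in statistics:
        fn = _STAT_FNS.get(name)
        if fn is None:
            raise InvalidSpecError(
                f"unknown statistic {name!r}; expected one of {sorted(_STAT_FNS)}")
        t_rep = fn(reps)
        t_obs = float(fn(observed.theta_hat))
        p = float(np.mean(t_rep >= t_obs))
        rows.append({"statistic": name, "observed": t_obs,
                     "rep_mean": float(t_rep.mean()), "rep_sd": float(t_rep.std(ddof=1)),
                     "p_value": p, "flagged": bool(p < 0.05 or p > 0.95)})
    return PpcResult(table=pd.DataFrame(rows), n_rep=reps.shape[0])


@dataclass
class SensitivityGrid:
    """Refits of one model structure under a grid of omega priors."""

    model_name: str
    cells: list[tuple[str, PosteriorSummary, bool]]
    max_abs_change: float

    def table(self) -> pd.DataFrame:
        """Per-subgroup posterior means side by side, one column per cell."""
        out = {}
        for label, summary, _ in self.cells:
            out[label] = summary.subgroups["mean"]
        return pd.DataFrame(out)

    @property
    def any_nonconverged(self) -> bool:
        return any(not ok for _, _, ok in self.cells)


def sensitivity_grid(spec: ModelSpec, data: SubgroupSummary, prior_grid,
                     n_iter: int = 5000, n_burn: int = 2500, chains: int = 4,
                     seed: int = 0, thresholds=()) -> SensitivityGrid:
    """Refit the model for each omega prior in the grid.

    ``prior_grid`` is a sequence of PriorSpec (for omega) or (label,
    ModelPriors) pairs.  Every cell reuses the same master seed, so
    differences across cells reflect the priors rather than Monte-Carlo
    noise.  Non-converged cells are flagged but the grid is returned.
    """
    grid = list(prior_grid)
    if len(grid) < 2:
        raise InvalidSpecError("a sensitivity grid needs at least 2 cells")
    cells = []
    means = []
    for item in grid:
        if isinstance(item, PriorSpec):
            priors = ModelPriors(tau_scale=spec.priors.tau_scale, omega=item,
                                 coef_scale=spec.priors.coef_scale)
            label = item.label()
        else:
            label, priors = item
        cell_spec = make_model(spec.name, spec.frame, priors)
        draws = run_mcmc(cell_spec, data, n_iter=n_iter, n_burn=n_burn,
                         chains=chains, seed=seed)
        summary = summarize_posterior(draws, thresholds)
        cells.append((label, summary, draws.converged))
        means.append(summary.subgroups["mean"].to_numpy())
    means = np.asarray(means)
    max_change = float(np.max(np.abs(means[:, None, :] - means[None, :, :])))
    return SensitivityGrid(model_name=spec.name, cells=cells,
                           max_abs_change=max_change)
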