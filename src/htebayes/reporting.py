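"""Forest-table assembly and posterior probability statements.

The canonical report is a table, one row per subgroup: the frequentist
estimate theta_hat_g with its 95% normal-approximation confidence
interval, next to the posterior mean and 95% credible interval of every
fitted model, plus each model's overall reference line (the posterior
mean of tau where the model has one, otherwise the precision-weighted
mean of the raw estimates).  Plot rendering is optional; the CSV table
is the artifact that tests and downstream tooling rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidSpecError
from .mcmc_engine import PosteriorDraws, PosteriorSummary
from .subgroup_data import SubgroupSummary

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class ForestTable:
    """Per-subgroup frequentist and Bayesian estimates with intervals."""

    table: pd.DataFrame
    reference: dict[str, float]
    model_names: tuple[str, ...]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def forest_data(summaries, data: SubgroupSummary) -> ForestTable:
    """Assemble the forest table from one or more posterior summaries.

    ``summaries`` is a sequence of PosteriorSummary (or a dict mapping a
    display name to one); all must be fitted to the same subgroups as
    ``data``.
    """
    if isinstance(summaries, dict):
        items = list(summaries.items())
    else:
        items = [(s.model_name, s) for s in summaries]
    if not items:
        raise InvalidSpecError("at least one posterior summary is required")

    labels = data.frame.labels()
    table = data.frame.to_dataframe()
    table.insert(0, "subgroup", labels)
    table["theta_hat"] = data.theta_hat
    table["ci_low"] = data.theta_hat - Z95 * data.se
    table["ci_high"] = data.theta_hat + Z95 * data.se

    reference = {}
    for name, summary in items:
        sub = summary.subgroups
        if list(sub.index) != labels:
            raise InvalidSpecError(
                f"summary {name!r} was fitted to different subgroups")
        ci = summary.credible_interval(0.95)
        table[f"{name}_mean"] = ci["mean"].to_numpy()
        table[f"{name}_low"] = ci["q2.5"].to_numpy()
        table[f"{name}_high"] = ci["q97.5"].to_numpy()
        reference[name] = (summary.tau_mean if summary.tau_mean is not None
                           else data.precision_weighted_mean())
    return ForestTable(table=table, reference=reference,
                       model_names=tuple(n for n, _ in items))


def benefit_probabilities(draws: PosteriorDraws, threshold: float,
                          direction: str = "less") -> pd.DataFrame:
    """P(benefit) per subgroup plus the qualitative-interaction probability.

    ``direction='less'`` defines benefit as theta_g < threshold (the
    convention for log-hazard and log-odds ratios where negative favors
    treatment); ``'greater'`` reverses it.  The qualitative-interaction
    column is P(sign(theta_g) != sign(tau) | y), computed by draw
    counting; models without tau use the precision-weighted mean of the
    theta draws as the per-draw overall effect.
    """
    if direction not in ("less", "greater"):
        raise InvalidSpecError("direction must be 'less' or 'greater'")
    theta = draws.theta()
    if direction == "less":
        p_benefit = (theta < threshold).mean(axis=0)
    else:
        p_benefit = (theta > threshold).mean(axis=0)
    spec = draws.spec
    if "tau" in spec.layout:
        tau = draws.pooled()[:, spec.layout["tau"]][:, 0]
    else:
        tau = theta.mean(axis=1)
    p_qual = (np.sign(theta) != np.sign(tau)[:, None]).mean(axis=0)
    return pd.DataFrame({
        "subgroup": spec.frame.labels(),
        "p_benefit": p_benefit,
        "p_qualitative_interaction": p_qual,
    })


def forest_plot(forest: ForestTable, path, title: str = "") -> None:
    """Optional matplotlib rendering of the forest table (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = forest.table
    G = len(df)
    n_models = len(forest.model_names)
    fig, ax = plt.subplots(figsize=(8, 0.45 * G * (n_models + 1) + 1.5))
    y = np.arange(G)[::-1] * (n_models + 1)
    ax.errorbar(df["theta_hat"], y, xerr=[df["theta_hat"] - df["ci_low"],
                                          df["ci_high"] - df["theta_hat"]],
                fmt="o", color="black", label="frequentist")
    for i, name in enumerate(forest.model_names, start=1):
        ax.errorbar(df[f"{name}_mean"], y - i,
                    xerr=[df[f"{name}_mean"] - df[f"{name}_low"],
                          df[f"{name}_high"] - df[f"{name}_mean"]],
                    fmt="s", label=name)
        ax.axvline(forest.reference[name], linestyle="--", linewidth=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(df["subgroup"])
    ax.set_xlabel("treatment effect")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
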