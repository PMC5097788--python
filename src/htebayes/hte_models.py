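"""The seven Bayesian model structures for subgroup treatment effects.

Every model consumes the same data -- per-subgroup estimates theta_hat_g
with standard errors s_g, modeled as theta_hat_g | theta_g ~
Normal(theta_g, s_g^2) -- and differs only in how the true effects
theta_g are structured:

==========================  ====================================================
pooled                      theta_g = tau for every g (complete pooling)
stratified                  theta_g independent, diffuse priors (no pooling)
basic_shrinkage             theta_g ~ Normal(tau, omega^2), omega ~ Half-Normal
basic_regression            theta_g = tau + X beta, diffuse independent betas
regression_plus_shrinkage   theta_g = tau + X beta + phi_g, phi_g ~ N(0, omega^2)
dixon_simon                 theta_g = tau + X beta, beta_jk ~ N(0, omega^2)
extended_dixon_simon        adds 2- and 3-way interaction coefficients with
                            per-order variances omega_1, omega_2, omega_3
==========================  ====================================================

X is the dummy (reference-level) coding of the crossed covariates, so a
first-order coefficient beta_jk is the change in treatment effect when
covariate j moves from its reference level to level k+1, and tau is the
effect in the all-reference subgroup (for the regression models) or the
overall effect (for the shrinkage model).  Interactions above order 3
are not modeled; with more than three covariates the extended model uses
orders 1-3 only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidSpecError
from .priors import (HALF_NORMAL, OMEGA_CAP, ModelPriors,
                     half_normal_logpdf, jeffreys_approx_logdensity)
from .subgroup_data import SubgroupFrame, SubgroupSummary

MODEL_NAMES = ("pooled", "stratified", "basic_shrinkage", "basic_regression",
               "regression_plus_shrinkage", "dixon_simon", "extended_dixon_simon")

_LOG_2PI = math.log(2.0 * math.pi)


def _order1_columns(frame: SubgroupFrame):
    cols, names = [], []
    sub = frame.to_dataframe()
    for cov in frame.covariates:
        vals = sub[cov.name].astype(str)
        for level in cov.levels[1:]:
            cols.append((vals == level).to_numpy(dtype=float))
            names.append(f"{cov.name}:{level}")
    return cols, names


def _design(frame: SubgroupFrame, order: int):
    """Design matrix and column names for one interaction order."""
    if order not in (1, 2, 3):
        raise InvalidSpecError("order must be 1, 2 or 3")
    J = len(frame.covariates)
    if order > J:
        raise InvalidSpecError(f"order {order} exceeds the {J} covariate(s)")
    cols1, names1 = _order1_columns(frame)
    if order == 1:
        return np.column_stack(cols1), names1
    # group order-1 columns by their covariate
    by_cov, pos = [], 0
    for cov in frame.covariates:
        k = cov.n_levels - 1
        by_cov.append(list(range(pos, pos + k)))
        pos += k
    cols, names = [], []
    for combo in itertools.combinations(range(J), order):
        for idxs in itertools.product(*(by_cov[j] for j in combo)):
            col = cols1[idxs[0]].copy()
            for i in idxs[1:]:
                col = col * cols1[i]
            cols.append(col)
            names.append("*".join(names1[i] for i in idxs))
    return np.column_stack(cols), names


def design_matrix(frame: SubgroupFrame, order: int) -> np.ndarray:
    """Indicator products of the given interaction order, rows in frame order.

    Order 1 has sum_j (K(j)-1) columns X_gjk (subgroup g holds level k+1
    of covariate j); order 2 all products of order-1 columns from
    distinct covariates; order 3 triple products.
    """
    return _design(frame, order)[0]


@dataclass
class ModelSpec:
    """A declarative model: parameter layout, designs, priors, log posterior."""

    name: str
    frame: SubgroupFrame
    priors: ModelPriors
    layout: dict[str, slice]
    param_names: list[str]
    designs: dict[int, np.ndarray] = field(default_factory=dict)
    design_names: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_subgroups(self) -> int:
        return self.frame.n_subgroups

    @property
    def omega_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.layout if n.startswith("omega"))

    def effect_map(self, params) -> np.ndarray:
        """Map a parameter vector (or draw matrix) to the G-vector theta."""
        p = np.asarray(params, dtype=float)
        if p.shape[-1] != self.n_params:
            raise InvalidSpecError(
                f"parameter vector has length {p.shape[-1]}, expected {self.n_params}")
        G = self.n_subgroups
        if self.name in ("stratified", "basic_shrinkage"):
            return p[..., self.layout["theta"]]
        if self.name == "pooled":
            return np.repeat(p[..., self.layout["tau"]], G, axis=-1)
        theta = np.repeat(p[..., self.layout["tau"]], G, axis=-1)
        blocks = {1: "beta", 2: "gamma", 3: "delta"}
        for order, key in blocks.items():
            if key in self.layout:
                theta = theta + p[..., self.layout[key]] @ self.designs[order].T
        if "phi" in self.layout:
            theta = theta + p[..., self.layout["phi"]]
        return theta

    # -- log posterior --------------------------------------------------

    def _omega_values(self, params):
        return {n: float(np.asarray(params)[self.layout[n]][0])
                for n in self.omega_names}

    def log_likelihood(self, params, data: SubgroupSummary) -> float:
        """sum_g log Normal(theta_hat_g | theta_g(params), s_g^2)."""
        theta = self.effect_map(np.asarray(params, dtype=float))
        z = (data.theta_hat - theta) / data.se
        return float(-0.5 * np.sum(z**2) - np.sum(np.log(data.se))
                     - 0.5 * theta.shape[-1] * _LOG_2PI)

    def _omega_log_prior(self, omega: float) -> float:
        spec = self.priors.omega
        if spec.family == HALF_NORMAL:
            return float(half_normal_logpdf(omega, spec.scale))
        # Jeffreys prior is stated on omega^2; include the Jacobian 2*omega
        # and the propriety truncation at omega <= OMEGA_CAP
        if omega > OMEGA_CAP:
            return -math.inf
        return float(jeffreys_approx_logdensity(omega**2, spec.eps)
                     + math.log(2.0 * omega))

    def log_prior(self, params) -> float:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.n_params,):
            raise InvalidSpecError(
                f"parameter vector has shape {p.shape}, expected ({self.n_params},)")
        omegas = self._omega_values(p)
        if any(not w > 0 for w in omegas.values()):
            return -math.inf

        def normal_lp(x, scale):
            x = np.atleast_1d(x)
            return float(-0.5 * np.sum((x / scale) ** 2)
                         - x.size * (math.log(scale) + 0.5 * _LOG_2PI))

        pr = self.priors
        lp = 0.0
        if "tau" in self.layout:
            lp += normal_lp(p[self.layout["tau"]], pr.tau_scale)
        if self.name == "stratified":
            lp += normal_lp(p[self.layout["theta"]], pr.tau_scale)
        elif self.name == "basic_shrinkage":
            tau = p[self.layout["tau"]][0]
            omega = omegas["omega"]
            lp += normal_lp(p[self.layout["theta"]] - tau, omega)
            lp += self._omega_log_prior(omega)
        elif self.name == "basic_regression":
            lp += normal_lp(p[self.layout["beta"]], pr.effective_coef_scale)
        elif self.name == "dixon_simon":
            lp += normal_lp(p[self.layout["beta"]], omegas["omega"])
            lp += self._omega_log_prior(omegas["omega"])
        elif self.name == "regression_plus_shrinkage":
            lp += normal_lp(p[self.layout["beta"]], pr.effective_coef_scale)
            lp += normal_lp(p[self.layout["phi"]], omegas["omega"])
            lp += self._omega_log_prior(omegas["omega"])
        elif self.name == "extended_dixon_simon":
            for key, om in (("beta", "omega1"), ("gamma", "omega2"),
                            ("delta", "omega3")):
                if key in self.layout:
                    lp += normal_lp(p[self.layout[key]], omegas[om])
                    lp += self._omega_log_prior(omegas[om])
        return lp

    def log_posterior(self, params, data: SubgroupSummary) -> float:
        """Joint log density (up to a constant) of data and priors at params."""
        if data.frame.n_subgroups != self.n_subgroups:
            raise InvalidSpecError("data frame does not match model frame")
        lp = self.log_prior(params)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.log_likelihood(params, data)


def make_model(name: str, frame: SubgroupFrame,
               priors: ModelPriors | None = None) -> ModelSpec:
    """Build one of the seven model structures on the given frame."""
    if name not in MODEL_NAMES:
        raise InvalidSpecError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    priors = priors or ModelPriors()
    G = frame.n_subgroups
    labels = frame.labels()
    layout: dict[str, slice] = {}
    names: list[str] = []
    designs: dict[int, np.ndarray] = {}
    dnames: dict[int, list[str]] = {}

    def add(key, count, param_labels):
        start = len(names)
        layout[key] = slice(start, start + count)
        names.extend(param_labels)

    if name == "pooled":
        add("tau", 1, ["tau"])
    elif name == "stratified":
        add("theta", G, [f"theta[{l}]" for l in labels])
    elif name == "basic_shrinkage":
        add("theta", G, [f"theta[{l}]" for l in labels])
        add("tau", 1, ["tau"])
        add("omega", 1, ["omega"])
    else:
        add("tau", 1, ["tau"])
        M1, n1 = _design(frame, 1)
        designs[1], dnames[1] = M1, n1
        add("beta", len(n1), [f"beta[{c}]" for c in n1])
        if name == "extended_dixon_simon":
            J = len(frame.covariates)
            for order, key in ((2, "gamma"), (3, "delta")):
                if J >= order:
                    M, nn = _design(frame, order)
                    designs[order], dnames[order] = M, nn
                    add(key, len(nn), [f"{key}[{c}]" for c in nn])
        if name == "regression_plus_shrinkage":
            add("phi", G, [f"phi[{l}]" for l in labels])
        if name in ("dixon_simon", "regression_plus_shrinkage"):
            add("omega", 1, ["omega"])
        elif name == "extended_dixon_simon":
            add("omega1", 1, ["omega1"])
            if "gamma" in layout:
                add("omega2", 1, ["omega2"])
            if "delta" in layout:
                add("omega3", 1, ["omega3"])
    return ModelSpec(name=name, frame=frame, priors=priors, layout=layout,
                     param_names=names, designs=designs, design_names=dnames)
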