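"""Minimal Cox proportional-hazards regression by partial likelihood.

Supplies per-subgroup log-hazard ratios (and their standard errors) for
the subgroup summary step, and Wald block tests for the frequentist
interaction tests.  Ties are handled with the Breslow approximation: all
events at a tied time share the same risk-set denominator.  The risk set
at an event time t is every subject with observed time >= t, so a
censoring at an event time keeps the censored subject in that risk set.

Newton-Raphson maximization with step halving; convergence when the
largest absolute score component drops below 1e-8 (or 50 iterations).  A
coefficient wandering beyond |beta| > 15 is taken as evidence of a
monotone partial likelihood and raises a NonConvergenceError.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EstimabilityError, NonConvergenceError, NumericalError

MAX_ABS_COEF = 15.0
SCORE_TOL = 1e-8
MAX_ITER = 50


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit.

    ``coefficients`` are log-hazard ratios; ``covariance`` is the inverse
    observed information at the optimum; ``loglik`` is the Breslow
    partial log-likelihood at the returned coefficients.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    n_iter: int
    names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass(frozen=True)
class TestResult:
    """A Wald test: chi-square statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    p: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def _prepare(times, events, design):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = times.shape[0]
    if events.shape[0] != n or X.shape[0] != n:
        raise EstimabilityError("times, events and design must have equal length")
    if np.any(times <= 0):
        raise EstimabilityError("event/censoring times must be strictly positive")
    if not np.all(np.isin(events, (0, 1))):
        raise EstimabilityError("event indicators must be 0 or 1")
    events = events.astype(bool)
    if events.sum() < 1:
        raise EstimabilityError("no events observed; hazard ratio is not estimable")
    # descending time: risk set of an event is a prefix of the sorted arrays
    order = np.argsort(-times, kind="stable")
    times, events, X = times[order], events[order], X[order]
    # last index of each tie group == end of the risk set for that time
    boundary = np.flatnonzero(np.diff(times) != 0)
    risk_end = np.empty(n, dtype=int)
    start = 0
    for b in list(boundary) + [n - 1]:
        risk_end[start:b + 1] = b
        start = b + 1
    return times, events, X, risk_end


def _loglik_score_info(beta, events, X, risk_end):
    eta = X @ beta
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * X, axis=0)
    S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    idx = risk_end[events]
    s0 = S0[idx]
    xbar = S1[idx] / s0[:, None]
    ll = float(eta[events].sum() - np.log(s0).sum())
    score = X[events].sum(axis=0) - xbar.sum(axis=0)
    info = (S2[idx] / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, score, info


def cox_fit(times, events, design, names=None) -> CoxFit:
    """Maximize the Breslow-tie partial likelihood by Newton iterations.

    Parameters
    ----------
    times, events
        Observed times (> 0) and event indicators (1 = event, 0 = censored).
    design
        Covariate matrix (n x p) or a single covariate vector.
    names
        Optional covariate labels used in error messages.
    """
    times, ev, X, risk_end = _prepare(times, events, design)
    p = X.shape[1]
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise EstimabilityError("names length must match design columns")
    # full column rank required for an identifiable fit
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise EstimabilityError(
            "design is rank deficient (a covariate is constant or aliased)")

    beta = np.zeros(p)
    ll, score, info = _loglik_score_info(beta, ev, X, risk_end)
    # no covariate variation within any risk set -> flat likelihood
    if np.linalg.matrix_rank(info) < p:
        raise EstimabilityError(
            "covariates show no variation within the event risk sets")
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guarded above
            raise NumericalError("singular information matrix") from exc
        # step halving keeps the likelihood non-decreasing on tiny data
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, score_new, info_new = _loglik_score_info(cand, ev, X, risk_end)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            j = int(np.argmax(np.abs(beta)))
            raise NonConvergenceError(
                f"monotone partial likelihood: coefficient for {names[j]!r} diverged")
    else:
        converged = np.max(np.abs(score)) < SCORE_TOL
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("information matrix not invertible at optimum") from exc
    return CoxFit(coefficients=beta, covariance=cov, loglik=ll,
                  n_events=int(ev.sum()), converged=converged,
                  n_iter=n_iter, names=names)


def breslow_loglik(beta, times, events, design) -> float:
    """Direct evaluation of the Breslow partial log-likelihood.

    Exposed so desk-scale instances can be checked against brute-force
    grid maximization.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, ev, X, risk_end = _prepare(times, events, design)
    ll, _, _ = _loglik_score_info(beta, ev, X, risk_end)
    return ll


def wald_block_test(fit: CoxFit, block, label: str = "") -> TestResult:
    """Joint Wald test that a block of coefficients is zero.

    statistic = beta_block' (Cov_block)^{-1} beta_block, compared to a
    chi-square with df = |block|.
    """
    block = np.asarray(block, dtype=int)
    p = fit.coefficients.shape[0]
    if block.size == 0 or np.any(block < 0) or np.any(block >= p):
        raise NumericalError("block indices outside the coefficient vector")
    b = fit.coefficients[block]
    C = fit.covariance[np.ix_(block, block)]
    try:
        sol = np.linalg.solve(C, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular covariance block in Wald test") from exc
    if not np.all(np.isfinite(sol)):
        raise NumericalError("singular covariance block in Wald test")
    statistic = float(b @ sol)
    df = int(block.size)
    return TestResult(statistic=statistic, df=df,
                      p=float(stats.chi2.sf(statistic, df)), label=label)
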