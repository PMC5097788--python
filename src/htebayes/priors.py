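"""Prior distributions for the heterogeneity models.

The between-subgroup standard deviation ``omega`` carries a half-normal
prior by default.  Following the meta-analysis convention, writing
``Half-Normal(b^2)`` means the distribution of ``b * |Z|`` for a standard
normal ``Z`` -- i.e. ``b`` is a *scale*, so the common default
``sigma_omega^2 = 100`` corresponds to scale ``sigma_omega = 10``.  Every
function here takes the scale explicitly to avoid that pitfall.

An approximate Jeffreys prior on ``omega^2`` is also provided:
``p(omega^2) proportional to omega^{-2}`` for ``omega^2 >= eps`` and flat
(``1/eps``) below, which keeps the density bounded near zero.  As printed
the prior is improper on the right tail; inside the sampler it is
truncated at ``omega^2 <= 10^4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidSpecError, ValidationError

NORMAL = "normal"
HALF_NORMAL = "half_normal"
JEFFREYS_APPROX = "jeffreys_approx"

_FAMILIES = (NORMAL, HALF_NORMAL, JEFFREYS_APPROX)

#: upper truncation for omega when the (improper) Jeffreys prior is used
OMEGA_CAP = 100.0


@dataclass(frozen=True)
class PriorSpec:
    """One prior choice: a family plus its scale (or truncation) parameter.

    ``scale`` is the standard deviation of the underlying normal for the
    ``normal`` and ``half_normal`` families; ``eps`` is the flattening
    point of the approximate Jeffreys prior on omega^2.
    """

    family: str
    scale: float | None = None
    eps: float = 0.005

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidSpecError(f"unknown prior family {self.family!r}; "
                                   f"expected one of {_FAMILIES}")
        if self.family in (NORMAL, HALF_NORMAL):
            if self.scale is None or not self.scale > 0:
                raise InvalidSpecError(
                    f"{self.family} prior requires a positive scale, got {self.scale!r}")
        if not self.eps > 0:
            raise InvalidSpecError(f"eps must be positive, got {self.eps!r}")

    def label(self) -> str:
        if self.family == JEFFREYS_APPROX:
            return f"jeffreys(eps={self.eps:g})"
        return f"{self.family}(scale={self.scale:g})"


@dataclass(frozen=True)
class ModelPriors:
    """Hyperparameter bundle shared by the seven model structures.

    ``tau_scale`` is sigma_tau (default sqrt(1000), i.e. the conventional
    sigma_tau^2 = 1000); ``omega`` is the prior for every between-group /
    between-coefficient standard deviation (default Half-Normal with scale
    10, i.e. sigma_omega^2 = 100); ``coef_scale`` is the fixed prior scale
    for unshrunken regression coefficients (defaults to ``tau_scale``).
    """

    tau_scale: float = math.sqrt(1000.0)
    omega: PriorSpec = PriorSpec(HALF_NORMAL, scale=10.0)
    coef_scale: float | None = None

    def __post_init__(self) -> None:
        if not self.tau_scale > 0:
            raise InvalidSpecError("tau_scale must be positive")
        if self.coef_scale is not None and not self.coef_scale > 0:
            raise InvalidSpecError("coef_scale must be positive")
        if self.omega.family == NORMAL:
            raise InvalidSpecError("omega prior must be half_normal or jeffreys_approx")

    @property
    def effective_coef_scale(self) -> float:
        return self.tau_scale if self.coef_scale is None else self.coef_scale


def half_normal_quantile(p, sigma):
    """Quantile of ``sigma * |Z|``: ``sigma * Phi^{-1}((1 + p) / 2)``.

    The multipliers at p = 0.5, 0.75, 0.99 are 0.674, 1.150 and 2.576,
    which is the standard desk reference for judging a half-normal scale.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValidationError("p must lie in [0, 1)")
    if np.any(np.asarray(sigma) < 0):
        raise ValidationError("sigma must be nonnegative")
    out = np.asarray(sigma, dtype=float) * stats.norm.ppf((1.0 + p) / 2.0)
    return out if out.ndim else float(out)


def half_normal_cdf(y, sigma):
    """P(sigma * |Z| <= y) = 2 Phi(y / sigma) - 1 for y >= 0."""
    y = np.asarray(y, dtype=float)
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    out = np.where(y < 0, 0.0, 2.0 * stats.norm.cdf(y / sigma) - 1.0)
    return out if out.ndim else float(out)


def half_normal_logpdf(y, sigma):
    """Log density ``2 phi(y/sigma)/sigma`` on y >= 0; -inf off support."""
    y = np.asarray(y, dtype=float)
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    with np.errstate(divide="ignore"):
        out = np.where(y < 0, -np.inf,
                       math.log(2.0) + stats.norm.logpdf(y / sigma) - math.log(sigma))
    return out if out.ndim else float(out)


def half_normal_sample(sigma, size=None, seed=None):
    """Draw ``|sigma * Z|`` variates; ``seed`` may be an int or a Generator."""
    if not sigma >= 0:
        raise ValidationError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.abs(sigma * rng.standard_normal(size))


def jeffreys_approx_logdensity(omega_sq, eps=0.005):
    """Unnormalized log density of the flattened Jeffreys prior on omega^2.

    ``-log(omega^2)`` for omega^2 >= eps, ``log(1/eps)`` below; the two
    branches agree at omega^2 = eps, so the density is continuous.
    """
    omega_sq = np.asarray(omega_sq, dtype=float)
    if not eps > 0:
        raise ValidationError("eps must be positive")
    if np.any(omega_sq <= 0):
        raise ValidationError("omega^2 must be positive")
    out = np.where(omega_sq >= eps, -np.log(omega_sq), -math.log(eps))
    return out if out.ndim else float(out)
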