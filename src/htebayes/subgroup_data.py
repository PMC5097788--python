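"""Subgroup definition, per-subgroup summary statistics, and fixtures.

A subgroup analysis starts from mutually exclusive subgroups formed by
fully crossing categorical baseline covariates.  Every downstream model
consumes one row per subgroup: a treatment-effect estimate theta_hat_g
(mean difference, log-odds ratio, or log-hazard ratio) and its standard
error s_g.  This module builds the crossed frame, computes (theta_hat_g,
s_g) from subject-level data, reads/writes the delimited summary format,
and generates synthetic data with known truth for testing and
calibration studies.

Subgroup ordering is lexicographic: covariates in declaration order,
levels in declared order within each covariate (the last covariate
varies fastest).  The first declared level of each covariate is its
reference level.  All downstream vectors index subgroups by this order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (EstimabilityError, FormatError, InvalidSpecError,
                         ValidationError)
from .survival_core import cox_fit

logger = logging.getLogger(__name__)

EFFECT_SCALES = ("mean_diff", "log_or", "log_hr")
OUTCOME_KINDS = ("continuous", "binary", "survival")
#: effect scale implied by each subject-level outcome kind
SCALE_FOR_OUTCOME = {"continuous": "mean_diff", "binary": "log_or",
                     "survival": "log_hr"}
_RESERVED_COLUMNS = {"theta_hat", "se", "n_trt", "n_ctl",
                     "outcome", "time", "event", "treatment"}


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical baseline covariate; the first level is the reference."""

    name: str
    levels: tuple[str, ...]

    def __init__(self, name: str, levels) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "levels", tuple(str(l) for l in levels))
        if len(set(self.levels)) != len(self.levels):
            raise InvalidSpecError(
                f"covariate {self.name!r} has duplicate level labels")
        if self.name in _RESERVED_COLUMNS:
            raise InvalidSpecError(
                f"covariate name {self.name!r} clashes with a reserved column")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass(frozen=True)
class SubgroupFrame:
    """The full cross-classification of the declared covariates."""

    covariates: tuple[CovariateSpec, ...]
    subgroups: tuple[tuple[str, ...], ...]

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroups)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def labels(self, sep: str = "/") -> list[str]:
        return [sep.join(combo) for combo in self.subgroups]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.subgroups), columns=list(self.covariate_names))

    def index_of(self, combo) -> int:
        try:
            return self.subgroups.index(tuple(str(c) for c in combo))
        except ValueError as exc:
            raise InvalidSpecError(f"unknown subgroup {tuple(combo)!r}") from exc


def build_subgroup_frame(covariates) -> SubgroupFrame:
    """Cross the covariates into G = prod_j K(j) ordered subgroups."""
    covariates = tuple(covariates)
    if not covariates:
        raise InvalidSpecError("at least one covariate is required")
    names = [c.name for c in covariates]
    if len(set(names)) != len(names):
        raise InvalidSpecError(f"duplicate covariate names: {sorted(names)}")
    for cov in covariates:
        if cov.n_levels < 2:
            raise InvalidSpecError(
                f"covariate {cov.name!r} needs at least 2 levels, has {cov.n_levels}")
    subgroups = tuple(itertools.product(*(c.levels for c in covariates)))
    return SubgroupFrame(covariates=covariates, subgroups=subgroups)


@dataclass
class SubgroupSummary:
    """Per-subgroup effect estimates -- the sole data input to the models."""

    frame: SubgroupFrame
    theta_hat: np.ndarray
    se: np.ndarray
    effect_scale: str = "mean_diff"
    n_trt: np.ndarray | None = None
    n_ctl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        G = self.frame.n_subgroups
        if self.theta_hat.shape != (G,) or self.se.shape != (G,):
            raise ValidationError(
                f"theta_hat and se must have length G={G}; got "
                f"{self.theta_hat.shape} and {self.se.shape}")
        if not np.all(np.isfinite(self.theta_hat)):
            raise ValidationError("theta_hat contains non-finite values")
        bad = np.flatnonzero(~(self.se > 0) | ~np.isfinite(self.se))
        if bad.size:
            raise ValidationError(
                f"standard errors must be positive; offending rows {bad.tolist()}")
        if self.effect_scale not in EFFECT_SCALES:
            raise ValidationError(f"effect_scale must be one of {EFFECT_SCALES}")
        for attr in ("n_trt", "n_ctl"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape != (G,) or np.any(v < 0):
                    raise ValidationError(f"{attr} must be G nonnegative integers")
                setattr(self, attr, v)

    @property
    def n_subgroups(self) -> int:
        return self.frame.n_subgroups

    def to_dataframe(self) -> pd.DataFrame:
        df = self.frame.to_dataframe()
        df["theta_hat"] = self.theta_hat
        df["se"] = self.se
        if self.n_trt is not None:
            df["n_trt"] = self.n_trt
        if self.n_ctl is not None:
            df["n_ctl"] = self.n_ctl
        return df

    def precision_weighted_mean(self) -> float:
        """Fixed-effect pooled estimate sum(theta/s^2)/sum(1/s^2)."""
        w = 1.0 / self.se**2
        return float(np.sum(w * self.theta_hat) / np.sum(w))


@dataclass
class SubjectTable:
    """Subject-level records: outcome, 0/1 treatment arm, covariate levels."""

    table: pd.DataFrame
    outcome_kind: str
    covariates: tuple[CovariateSpec, ...]

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        if self.outcome_kind not in OUTCOME_KINDS:
            raise ValidationError(f"outcome_kind must be one of {OUTCOME_KINDS}")
        df = self.table
        required = (["time", "event"] if self.outcome_kind == "survival"
                    else ["outcome"])
        for col in required + ["treatment"]:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if self.outcome_kind != "survival" and "event" in df.columns:
            raise ValidationError("event indicator only valid for survival outcomes")
        if not df["treatment"].isin([0, 1]).all():
            raise ValidationError("treatment must be coded 0/1")
        if self.outcome_kind == "survival":
            if not df["event"].isin([0, 1]).all():
                raise ValidationError("event must be coded 0/1")
            if not (df["time"] > 0).all():
                raise ValidationError("times must be strictly positive")
        if self.outcome_kind == "binary" and not df["outcome"].isin([0, 1]).all():
            raise ValidationError("binary outcomes must be coded 0/1")
        for cov in self.covariates:
            if cov.name not in df.columns:
                raise FormatError(f"missing covariate column {cov.name!r}")
            observed = df[cov.name].dropna().astype(str)
            unknown = set(observed) - set(cov.levels)
            if unknown:
                raise ValidationError(
                    f"covariate {cov.name!r} has undeclared levels {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.table)


def _continuous_summary(sub: pd.DataFrame, label: str):
    trt = sub.loc[sub["treatment"] == 1, "outcome"].to_numpy(dtype=float)
    ctl = sub.loc[sub["treatment"] == 0, "outcome"].to_numpy(dtype=float)
    n1, n0 = trt.size, ctl.size
    if n1 + n0 < 3:
        raise EstimabilityError(
            f"subgroup {label}: pooled variance needs at least 3 subjects")
    sp2 = ((n1 - 1) * trt.var(ddof=1) + (n0 - 1) * ctl.var(ddof=1)) / (n1 + n0 - 2)
    if sp2 <= 0:
        raise EstimabilityError(f"subgroup {label}: zero pooled variance")
    theta = trt.mean() - ctl.mean()
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0)))
    return float(theta), se


def _binary_summary(sub: pd.DataFrame, label: str):
    trt = sub.loc[sub["treatment"] == 1, "outcome"]
    ctl = sub.loc[sub["treatment"] == 0, "outcome"]
    a, b = int((trt == 1).sum()), int((trt == 0).sum())
    c, d = int((ctl == 1).sum()), int((ctl == 0).sum())
    if min(a, b, c, d) == 0:
        raise EstimabilityError(
            f"subgroup {label}: zero cell in the 2x2 table "
            f"(a,b,c,d)=({a},{b},{c},{d}); no continuity correction is applied")
    theta = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d))
    return theta, se


def _survival_summary(sub: pd.DataFrame, label: str):
    events = sub["event"].to_numpy()
    if events.sum() < 1:
        raise EstimabilityError(f"subgroup {label}: no events observed")
    try:
        fit = cox_fit(sub["time"].to_numpy(), events,
                      sub["treatment"].to_numpy(dtype=float), names=("treatment",))
    except EstimabilityError as exc:
        raise EstimabilityError(f"subgroup {label}: {exc}") from exc
    return float(fit.coefficients[0]), float(fit.se[0])


def compute_subgroup_summaries(data: SubjectTable, frame: SubgroupFrame
                               ) -> SubgroupSummary:
    """Reduce subject-level data to (theta_hat_g, s_g) in frame order.

    Continuous outcomes give a difference of arm means with the pooled
    two-sample standard error; binary outcomes a log-odds ratio with the
    usual sqrt of summed reciprocal cell counts; survival outcomes the
    log-hazard ratio from a treatment-only proportional-hazards fit
    within the subgroup.  Rows with a missing covariate value are dropped
    (with a logged count).
    """
    names = list(frame.covariate_names)
    df = data.table
    missing = df[names].isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d subject(s) with missing covariate values",
                       int(missing.sum()))
        df = df.loc[~missing]
    df = df.copy()
    for name in names:
        df[name] = df[name].astype(str)
    grouped = {(k if isinstance(k, tuple) else (k,)): v
               for k, v in df.groupby(names, sort=False)}

    theta = np.empty(frame.n_subgroups)
    se = np.empty(frame.n_subgroups)
    n_trt = np.zeros(frame.n_subgroups, dtype=int)
    n_ctl = np.zeros(frame.n_subgroups, dtype=int)
    reducer = {"continuous": _continuous_summary, "binary": _binary_summary,
               "survival": _survival_summary}[data.outcome_kind]
    for g, combo in enumerate(frame.subgroups):
        sub = grouped.get(combo)
        label = "/".join(combo)
        if sub is None or len(sub) == 0:
            raise EstimabilityError(f"subgroup {label}: no subjects")
        n_trt[g] = int((sub["treatment"] == 1).sum())
        n_ctl[g] = int((sub["treatment"] == 0).sum())
        if n_trt[g] == 0 or n_ctl[g] == 0:
            raise EstimabilityError(f"subgroup {label}: empty treatment arm")
        theta[g], se[g] = reducer(sub, label)
    return SubgroupSummary(frame=frame, theta_hat=theta, se=se,
                           effect_scale=SCALE_FOR_OUTCOME[data.outcome_kind],
                           n_trt=n_trt, n_ctl=n_ctl)


def simulate_summary_data(tau, omega, se_profile, frame: SubgroupFrame,
                          seed, effect_scale: str = "log_hr"):
    """Draw true effects and noisy estimates from the two-stage model.

    theta_g ~ Normal(tau, omega^2), theta_hat_g ~ Normal(theta_g, s_g^2)
    with s_g taken from ``se_profile``.  Returns ``(true_theta, summary)``.
    """
    if not omega >= 0:
        raise InvalidSpecError("omega must be nonnegative")
    se = np.asarray(se_profile, dtype=float)
    G = frame.n_subgroups
    if se.shape != (G,):
        raise InvalidSpecError(
            f"se_profile length {se.shape} does not match G={G}")
    if np.any(se <= 0):
        raise InvalidSpecError("se_profile entries must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_theta = tau + omega * rng.standard_normal(G)
    theta_hat = true_theta + se * rng.standard_normal(G)
    summary = SubgroupSummary(frame=frame, theta_hat=theta_hat, se=se.copy(),
                              effect_scale=effect_scale)
    return true_theta, summary


def simulate_subject_data(frame: SubgroupFrame, effects, outcome_kind: str,
                          n_per_arm, seed, censoring_rate: float = 0.0,
                          baseline_hazard: float = 1.0, control_mean: float = 0.0,
                          outcome_sd: float = 1.0, control_prob: float = 0.5
                          ) -> SubjectTable:
    """Generate subject-level records with a known per-subgroup effect.

    survival: exponential event times with log-hazard ratio = effect_g
    between arms and independent uniform censoring at ``censoring_rate``;
    binary: logistic arm probabilities with log-odds ratio = effect_g
    around ``control_prob``; continuous: normal outcomes with mean shift
    = effect_g.
    """
    if outcome_kind not in OUTCOME_KINDS:
        raise InvalidSpecError(f"outcome_kind must be one of {OUTCOME_KINDS}")
    effects = np.asarray(effects, dtype=float)
    G = frame.n_subgroups
    if effects.shape != (G,):
        raise InvalidSpecError(f"effects length {effects.shape} does not match G={G}")
    if not 0.0 <= censoring_rate < 1.0:
        raise InvalidSpecError("censoring_rate must lie in [0, 1)")
    n_per_arm = np.broadcast_to(np.asarray(n_per_arm, dtype=int), (G,))
    if np.any(n_per_arm < 1):
        raise InvalidSpecError("n_per_arm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    for g, combo in enumerate(frame.subgroups):
        n = int(n_per_arm[g])
        for arm in (0, 1):
            base = dict(zip(frame.covariate_names, combo))
            base["treatment"] = arm
            if outcome_kind == "continuous":
                mu = control_mean + (effects[g] if arm else 0.0)
                y = mu + outcome_sd * rng.standard_normal(n)
                for v in y:
                    rows.append({**base, "outcome": float(v)})
            elif outcome_kind == "binary":
                logit = np.log(control_prob / (1 - control_prob))
                p = 1.0 / (1.0 + np.exp(-(logit + (effects[g] if arm else 0.0))))
                y = rng.random(n) < p
                for v in y:
                    rows.append({**base, "outcome": int(v)})
            else:
                hazard = baseline_hazard * (np.exp(effects[g]) if arm else 1.0)
                t = rng.exponential(1.0 / hazard, size=n)
                censored = rng.random(n) < censoring_rate
                # uniform censoring time on (0, t]; (1 - U) avoids exact zero
                obs = np.where(censored, t * (1.0 - rng.random(n)), t)
                for tv, cv in zip(obs, censored):
                    rows.append({**base, "time": float(tv), "event": int(not cv)})
    table = pd.DataFrame(rows)
    return SubjectTable(table=table, outcome_kind=outcome_kind,
                        covariates=frame.covariates)


def write_summary_table(summary: SubgroupSummary, path) -> None:
    """Write the delimited summary format: covariate levels, theta_hat, se."""
    summary.to_dataframe().to_csv(path, index=False)


def read_summary_table(path, covariates=None, effect_scale: str = "log_hr"
                       ) -> SubgroupSummary:
    """Read a delimited summary table back into a SubgroupSummary.

    With ``covariates=None`` the covariates are inferred from the
    non-reserved columns, levels in order of first appearance (the first
    observed level becomes the reference).  The file must contain every
    level combination exactly once.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("theta_hat", "se"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if covariates is None:
        names = [c for c in df.columns if c not in _RESERVED_COLUMNS]
        if not names:
            raise FormatError("no covariate columns found")
        covariates = [CovariateSpec(n, pd.unique(df[n].astype(str)).tolist())
                      for n in names]
    frame = build_subgroup_frame(covariates)
    if len(df) != frame.n_subgroups:
        raise FormatError(
            f"expected {frame.n_subgroups} rows (full cross), found {len(df)}")
    bad = df.index[~(df["se"] > 0)].tolist()
    if bad:
        raise ValidationError(f"non-positive se in row(s) {bad}")
    # reorder rows into frame order
    keys = [tuple(str(df.loc[i, c.name]) for c in frame.covariates)
            for i in df.index]
    if len(set(keys)) != len(keys):
        raise FormatError("duplicate subgroup rows in summary table")
    order = []
    for combo in frame.subgroups:
        try:
            order.append(df.index[keys.index(combo)])
        except ValueError as exc:
            raise FormatError(f"missing subgroup row {'/'.join(combo)}") from exc
    df = df.loc[order]
    kwargs = {}
    for col, attr in (("n_trt", "n_trt"), ("n_ctl", "n_ctl")):
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=int)
    return SubgroupSummary(frame=frame, theta_hat=df["theta_hat"].to_numpy(float),
                           se=df["se"].to_numpy(float), effect_scale=effect_scale,
                           **kwargs)
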