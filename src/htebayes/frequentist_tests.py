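"""Frequentist treatment-covariate interaction tests.

Comparators for the Bayesian suite: a univariate (one-covariate-at-a-
time) interaction test, the unstructured interaction test with every
covariate and every treatment-by-covariate interaction in one model, and
Bonferroni multiplicity adjustment.  All tests are Wald block tests of
the interaction coefficients from a single fit -- least squares for
continuous outcomes, logistic regression for binary outcomes, and the
proportional-hazards core for time-to-event outcomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import EstimabilityError, NumericalError, ValidationError
from .subgroup_data import CovariateSpec, SubjectTable
from .survival_core import CoxFit, TestResult, cox_fit, wald_block_test

__all__ = ["TestResult", "univariate_interaction_test",
           "unstructured_interaction_test", "bonferroni_adjust"]


def _resolve_covariates(data: SubjectTable, which) -> list[CovariateSpec]:
    by_name = {c.name: c for c in data.covariates}
    out = []
    for item in which:
        if isinstance(item, CovariateSpec):
            out.append(item)
        elif item in by_name:
            out.append(by_name[item])
        else:
            raise ValidationError(f"unknown covariate {item!r}")
    return out


def _check_cells(df: pd.DataFrame, covariates) -> None:
    for cov in covariates:
        for level in cov.levels:
            for arm in (0, 1):
                n = int(((df[cov.name].astype(str) == level)
                         & (df["treatment"] == arm)).sum())
                if n == 0:
                    raise EstimabilityError(
                        f"covariate {cov.name!r} level {level!r} unobserved "
                        f"in arm {arm}")


def _interaction_design(df: pd.DataFrame, covariates, intercept: bool):
    """Main effects + treatment + treatment-by-level interaction columns.

    Returns (X, names, interaction_block) where the block indexes the
    gamma coefficients whose joint nullity the tests examine.
    """
    T = df["treatment"].to_numpy(dtype=float)
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    cols.append(T)
    names.append("treatment")
    mains = []
    for cov in covariates:
        vals = df[cov.name].astype(str)
        for level in cov.levels[1:]:
            mains.append(((vals == level).to_numpy(dtype=float), f"{cov.name}:{level}"))
    for col, name in mains:
        cols.append(col)
        names.append(name)
    block = []
    for col, name in mains:
        block.append(len(cols))
        cols.append(T * col)
        names.append(f"treatment*{name}")
    X = np.column_stack(cols)
    # aliased columns make the gamma block untestable; name the culprits
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased, rank = [], 0
        kept = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > rank:
                kept, rank = cand, rank + 1
            else:
                aliased.append(names[j])
        raise EstimabilityError(f"design is rank deficient; aliased columns {aliased}")
    return X, names, np.asarray(block, dtype=int)


def _wald_from_fit(params, cov, block, df_block, label) -> TestResult:
    b = np.asarray(params)[block]
    C = np.asarray(cov)[np.ix_(block, block)]
    try:
        sol = np.linalg.solve(C, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular covariance block in Wald test") from exc
    from scipy import stats
    statistic = float(b @ sol)
    return TestResult(statistic=statistic, df=df_block,
                      p=float(stats.chi2.sf(statistic, df_block)), label=label)


def _interaction_test(data: SubjectTable, covariates, label: str) -> TestResult:
    df = data.table
    names_cov = [c.name for c in covariates]
    missing = df[names_cov].isna().any(axis=1)
    if missing.any():
        df = df.loc[~missing]
    _check_cells(df, covariates)
    if data.outcome_kind == "survival":
        X, names, block = _interaction_design(df, covariates, intercept=False)
        # the proportional-hazards model has no intercept; column indices shift
        fit: CoxFit = cox_fit(df["time"].to_numpy(float), df["event"].to_numpy(),
                              X, names=names)
        return wald_block_test(fit, block, label=label)
    X, names, block = _interaction_design(df, covariates, intercept=True)
    y = df["outcome"].to_numpy(dtype=float)
    if data.outcome_kind == "continuous":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return _wald_from_fit(res.params, res.cov_params(), block, block.size, label)


def univariate_interaction_test(data: SubjectTable, covariate) -> TestResult:
    """Test H0: all treatment-by-level interactions for one covariate are 0.

    Fits outcome ~ treatment + covariate levels + treatment:levels and
    returns the joint Wald test of the K(j)-1 interaction coefficients.
    """
    covs = _resolve_covariates(data, [covariate])
    return _interaction_test(data, covs, label=f"univariate:{covs[0].name}")


def unstructured_interaction_test(data: SubjectTable) -> TestResult:
    """Joint test of every treatment-by-covariate interaction at once.

    All covariate main effects and all treatment-by-level interactions
    enter one model; df = sum_j (K(j) - 1).
    """
    covs = list(data.covariates)
    return _interaction_test(data, covs, label="unstructured")


def bonferroni_adjust(p_values) -> list[float]:
    """min(1, m * p) for each of the m tests."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p).tolist()
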