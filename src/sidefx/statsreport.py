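"""Phenotype-level statistics: group tests, correlations, GLM variance.

Thin, explicitly-parameterised wrappers around scipy/statsmodels that return a
uniform :class:`TestResult`, plus the exact Student-t and chi-square survival
functions used to check printed p-values against their test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "GlmSummary",
    "two_sample_t",
    "chisq_profile_test",
    "correlation",
    "glm_variance",
    "t_pvalue",
    "chisq_pvalue",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    effect: dict = field(default_factory=dict)
    n: tuple = ()


@dataclass
class GlmSummary:
    outcome: str
    r_squared: float
    p_values: pd.Series
    n: int
    model_p_value: float


def t_pvalue(t: float, df: float) -> float:
    """Two-sided p-value of a Student-t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def chisq_pvalue(chi2: float, df: int) -> float:
    """Upper-tail p-value of a chi-square statistic."""
    return float(stats.chi2.sf(chi2, df))


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2, two-sided).

    Pooled rather than Welch: the degrees of freedom reported alongside the
    clinical comparisons equal n1 + n2 - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        effect={
            "mean_x": float(x.mean()), "sd_x": float(x.std(ddof=1)),
            "mean_y": float(y.mean()), "sd_y": float(y.std(ddof=1)),
        },
        n=(len(x), len(y)),
    )


def chisq_profile_test(counts) -> TestResult:
    """Pearson chi-square homogeneity test on a 2 x C profile table.

    Used for e.g. male vs. female per-cluster affected counts; df = C - 1.
    Expected cell counts must be positive.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("counts must be a 2 x C table")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("all expected cell counts must be positive")
    return TestResult(
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        effect={"proportions": (table / table.sum(axis=1, keepdims=True)).tolist()},
        n=(int(table[0].sum()), int(table[1].sum())),
    )


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with its t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(
        statistic=float(r), df=float(len(x) - 2), p_value=float(p),
        effect={"method": method}, n=(len(x),),
    )


#: canonical predictor set for the variance-decomposition GLMs
DEFAULT_PREDICTORS = (
    "age",
    "gender",
    "diagnosis",
    "baseline_severity_score",
    "baseline_weight_kg",
    "onset",
    "n_drugs",
)


def glm_variance(
    data: pd.DataFrame,
    outcome: str,
    predictors=DEFAULT_PREDICTORS,
) -> GlmSummary:
    """Ordinary least-squares variance decomposition of an outcome.

    Categorical predictors (object/bool dtype) are dummy-coded; complete cases
    only. Returns R-square, the model F-test p-value, and per-predictor
    p-values (for dummy-coded predictors, the smallest p across its levels).
    """
    cols = [outcome, *predictors]
    sub = data[cols].dropna()
    if len(sub) < len(predictors) + 2:
        raise ValueError("need at least predictors + 2 complete cases")
    y = sub[outcome].astype(float)
    X_parts, owner = [], []
    for pred in predictors:
        col = sub[pred]
        if col.dtype == object or col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=pred, drop_first=True, dtype=float)
            X_parts.append(dummies)
            owner += [pred] * dummies.shape[1]
        else:
            X_parts.append(col.astype(float).to_frame(pred))
            owner.append(pred)
    X = sm.add_constant(pd.concat(X_parts, axis=1))
    fit = sm.OLS(y, X).fit()
    pvals = fit.pvalues.drop("const")
    per_pred = pd.Series(
        {p: float(pvals[[c for c, o in zip(pvals.index, owner) if o == p]].min())
         for p in predictors}
    )
    return GlmSummary(
        outcome=outcome,
        r_squared=float(fit.rsquared),
        p_values=per_pred,
        n=int(fit.nobs),
        model_p_value=float(fit.f_pvalue),
    )
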