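"""Confounder-adjusted standardized mean differences with noncentral-t CIs.

The effect of a binary factor (e.g. gender, diabetes) on SAF is quantified
after *residualizing*: SAF is regressed on the confounders (age, diabetes,
BMI, SR, …) by OLS and the residuals carry forward.  The standardized mean
difference (SMD, Cohen's d) between the factor's two groups is

    d = (x̄₁ − x̄₂) / s,   s² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2)

and its confidence interval is obtained by inverting the noncentral-t
distribution of t_obs = d / √(1/n₁ + 1/n₂) over the noncentrality parameter
(the same construction as the classical MBESS-style interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .cohort import Cohort

__all__ = ["AdjustedOutcome", "EffectSizeResult", "residualize", "smd",
           "smd_ci", "adjusted_group_effect"]


@dataclass
class AdjustedOutcome:
    subject_ids: pd.Series
    residual_saf: np.ndarray
    confounders: list[str]
    fit_coefficients: dict[str, float]


@dataclass
class EffectSizeResult:
    factor: str
    group_labels: tuple
    n1: int
    n2: int
    mean1: float
    mean2: float
    pooled_sd: float
    d: float
    raw_difference: float          # mean1 − mean2 on the outcome's own scale (AU)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level: float = 0.95
    adjusted_for: list[str] = field(default_factory=list)


def _design_matrix(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design from mixed columns; categoricals one-hot, drop-first."""
    parts = []
    for col in columns:
        s = df[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
        elif isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def residualize(cohort: Cohort | pd.DataFrame, outcome: str = "saf",
                confounders: list[str] | None = None) -> AdjustedOutcome:
    """OLS residuals of ``outcome`` on the confounders (intercept included).

    With no confounders the residuals are simply the centered outcome.
    A rank-deficient design raises, naming the collinear columns.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    confounders = list(confounders or [])
    y = df[outcome].astype(float).to_numpy()
    X = _design_matrix(df, confounders)
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    if len(y) <= Xc.shape[1]:
        raise ValueError("need n > number of confounders + 1")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError(f"rank-deficient design; check columns {list(X.columns)}")
    fit = sm.OLS(y, Xc).fit()
    coefs = dict(zip(["const"] + list(X.columns), fit.params))
    return AdjustedOutcome(subject_ids=df["id"] if "id" in df else pd.Series(df.index),
                           residual_saf=np.asarray(fit.resid),
                           confounders=confounders, fit_coefficients=coefs)


def smd(values, group_labels, factor: str = "") -> EffectSizeResult:
    """Cohen's d with pooled SD between exactly two groups (no CI yet).

    Group 1 is the first label in sorted order; d > 0 means group 1's mean
    is larger.
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    labels = sorted(pd.unique(group_labels).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = values[group_labels == labels[0]]
    g2 = values[group_labels == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = len(g1), len(g2)
    s = np.sqrt(((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1))
                / (n1 + n2 - 2))
    diff = g1.mean() - g2.mean()
    if s == 0:
        if diff != 0:
            raise ZeroDivisionError("pooled SD is zero with unequal means: "
                                    "effect size is infinite")
        d = 0.0
    else:
        d = diff / s
    return EffectSizeResult(factor=factor, group_labels=(labels[0], labels[1]),
                            n1=n1, n2=n2, mean1=float(g1.mean()),
                            mean2=float(g2.mean()), pooled_sd=float(s),
                            d=float(d), raw_difference=float(diff))


def smd_ci(d: float, n1: int, n2: int, level: float = 0.95,
           tol: float = 1e-8) -> tuple[float, float]:
    """Noncentral-t confidence interval for a standardized mean difference.

    Finds noncentrality parameters λ_lo < λ_hi such that the noncentral-t
    CDF (df = n1+n2−2) evaluated at t_obs = d/√(1/n1+1/n2) equals
    (1+level)/2 and (1−level)/2; the d-scale bounds are λ·√(1/n1+1/n2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must both be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    df = n1 + n2 - 2
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_obs = d / scale

    def cdf_at(nc):
        return stats.nct.cdf(t_obs, df, nc)

    bounds = []
    for target in ((1 + level) / 2, (1 - level) / 2):
        f = lambda nc: cdf_at(nc) - target
        lo, hi = t_obs - 2, t_obs + 2
        for _ in range(200):                       # expand the bracket
            if f(lo) > 0 and f(hi) < 0:
                break
            if f(lo) <= 0:
                lo -= 4
            if f(hi) >= 0:
                hi += 4
        else:
            raise RuntimeError(
                f"could not bracket noncentrality root (d={d}, n1={n1}, "
                f"n2={n2}, target={target})")
        nc = optimize.brentq(f, lo, hi, xtol=tol)
        bounds.append(nc * scale)
    return float(bounds[0]), float(bounds[1])


def adjusted_group_effect(cohort: Cohort | pd.DataFrame, factor: str,
                          confounders: list[str] | None = None,
                          outcome: str = "saf",
                          level: float = 0.95) -> EffectSizeResult:
    """Residualize the outcome on the confounders, then SMD + noncentral-t CI
    between the factor's two groups."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    confounders = list(confounders or [])
    if factor in confounders:
        raise ValueError(f"factor {factor!r} cannot also be a confounder")
    groups = df[factor]
    if groups.nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant")
    if groups.nunique() > 2:
        raise ValueError(f"factor {factor!r} has more than two levels")
    adj = residualize(df, outcome=outcome, confounders=confounders)
    res = smd(adj.residual_saf, groups.to_numpy(), factor=factor)
    lo, hi = smd_ci(res.d, res.n1, res.n2, level=level)
    res.ci_low, res.ci_high, res.level = lo, hi, level
    res.adjusted_for = confounders
    return res
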