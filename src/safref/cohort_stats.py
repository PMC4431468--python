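"""Descriptive summaries, stratified correlation heatmaps and the
univariate test-selection rule.

Numeric variables are summarized as mean (±SD) when a Shapiro–Wilk test at
α = 0.05 does not reject normality, and as median (min–max) otherwise.
Two-group comparisons use a t-test under normality and a two-sided Wilcoxon
rank-sum test otherwise; 2×2 categorical tables use the chi-square test with
Yates continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = ["CorrelationMatrix", "TestResult", "correlation_matrix",
           "univariate_group_test", "summarize_cohort", "SHAPIRO_ALPHA"]

SHAPIRO_ALPHA = 0.05
_SHAPIRO_MAX_N = 5000     # beyond this, a fixed-seed subsample is tested


@dataclass
class CorrelationMatrix:
    """Two triangular Pearson-correlation matrices packed into one square.

    The upper triangle holds one stratum (e.g. women, diabetics), the lower
    triangle the other (men, non-diabetics); the diagonal is 1.  Cells that
    are undefined (zero-variance variable in that stratum) are NaN and listed
    in ``undefined_cells`` — never silently zero.
    """
    variables: list[str]
    upper_stratum: str
    lower_stratum: str
    values: np.ndarray
    n_per_cell: np.ndarray
    undefined_cells: list[tuple[str, str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variables,
                            columns=self.variables)

    def to_long(self) -> pd.DataFrame:
        rows = []
        p = len(self.variables)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                stratum = self.upper_stratum if j > i else self.lower_stratum
                rows.append({"var1": self.variables[i], "var2": self.variables[j],
                             "stratum": stratum, "r": self.values[i, j],
                             "n": int(self.n_per_cell[i, j])})
        return pd.DataFrame(rows)


@dataclass
class TestResult:
    test_name: str           # "t", "wilcoxon" or "chi-square"
    statistic: float
    p_value: float
    normality_used: bool

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _pairwise_pearson(df: pd.DataFrame, variables: list[str]):
    p = len(variables)
    r = np.full((p, p), np.nan)
    n = np.zeros((p, p), int)
    undef = []
    for i in range(p):
        for j in range(i, p):
            a, b = df[variables[i]], df[variables[j]]
            mask = a.notna() & b.notna()
            n[i, j] = n[j, i] = mask.sum()
            if i == j:
                r[i, j] = 1.0
                continue
            x, y = a[mask].astype(float), b[mask].astype(float)
            if len(x) < 3 or x.std() == 0 or y.std() == 0:
                undef.append((variables[i], variables[j]))
                continue
            r[i, j] = r[j, i] = stats.pearsonr(x, y).statistic
    return r, n, undef


def correlation_matrix(cohort: Cohort, variables: list[str],
                       split_by: str = "gender") -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations per stratum, two triangles.

    ``split_by="gender"`` puts women in the upper triangle and men in the
    lower; ``split_by="diabetes"`` puts diabetics upper, non-diabetics lower.
    """
    df = cohort.df
    if split_by == "gender":
        upper, lower = df[df.gender == "F"], df[df.gender == "M"]
        up_lab, lo_lab = "women", "men"
    elif split_by == "diabetes":
        upper, lower = df[df.diabetes], df[~df.diabetes]
        up_lab, lo_lab = "diabetic", "non-diabetic"
    else:
        raise ValueError("split_by must be 'gender' or 'diabetes'")
    if len(upper) < 3 or len(lower) < 3:
        raise ValueError("each stratum needs n >= 3")

    r_up, n_up, undef_up = _pairwise_pearson(upper, variables)
    r_lo, n_lo, undef_lo = _pairwise_pearson(lower, variables)
    p = len(variables)
    vals = np.full((p, p), np.nan)
    ns = np.zeros((p, p), int)
    iu = np.triu_indices(p, 1)
    il = np.tril_indices(p, -1)
    vals[iu], ns[iu] = r_up[iu], n_up[iu]
    vals[il], ns[il] = r_lo[il], n_lo[il]
    np.fill_diagonal(vals, 1.0)
    np.fill_diagonal(ns, 0)
    undefined = ([(a, b, up_lab) for a, b in undef_up]
                 + [(a, b, lo_lab) for a, b in undef_lo])
    return CorrelationMatrix(list(variables), up_lab, lo_lab, vals, ns, undefined)


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    if len(x) > _SHAPIRO_MAX_N:
        idx = np.random.default_rng(0).choice(len(x), _SHAPIRO_MAX_N,
                                              replace=False)
        x = x[idx]
    return stats.shapiro(x).pvalue >= SHAPIRO_ALPHA


def univariate_group_test(values=None, groups=None, table=None) -> TestResult:
    """The study's test-selection rule for a two-group comparison.

    Numeric data: Shapiro–Wilk at α = 0.05 in *both* groups gates a two-sided
    t-test versus a two-sided Wilcoxon rank-sum test.  A 2×2 count ``table``
    instead runs the chi-square test with Yates continuity correction.
    """
    if table is not None:
        table = np.asarray(table, float)
        if table.shape != (2, 2):
            raise ValueError("categorical table must be 2x2")
        res = stats.chi2_contingency(table, correction=True)
        if (res.expected_freq == 0).any():
            raise ValueError("zero expected cell count")
        return TestResult("chi-square", float(res.statistic),
                          float(res.pvalue), normality_used=False)

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    g1, g2 = values[groups == labels[0]], values[groups == labels[1]]
    normal = _is_normal(g1) and _is_normal(g2)
    if normal:
        res = stats.ttest_ind(g1, g2)
        return TestResult("t", float(res.statistic), float(res.pvalue), True)
    if np.ptp(values) == 0:               # degenerate: identical everywhere
        return TestResult("wilcoxon", 0.0, 1.0, False)
    res = stats.ranksums(g1, g2)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), False)


_SUMMARY_VARS = ["age", "height", "weight", "bmi", "waist", "hip", "whr",
                 "sbp", "dbp", "sr", "saf"]
_FLAG_VARS = ["smoking", "diabetes", "hypertension"]


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Per-gender descriptive tables with the normality-dependent formatting.

    Returns ``{"numeric": ..., "categorical": ...}``; numeric rows carry the
    formatted summary per gender (mean (±SD) if normal, median (min–max)
    otherwise) plus the two-group p-value; categorical rows carry counts and
    the continuity-corrected chi-square p.
    """
    df = cohort.df
    men, women = cohort.men, cohort.women
    rows = []
    for var in _SUMMARY_VARS:
        cells = {}
        for lab, sub in (("men", men), ("women", women)):
            x = sub[var].dropna().astype(float).to_numpy()
            if _is_normal(x):
                cells[lab] = f"{x.mean():.2f} (±{x.std(ddof=1):.2f})"
            else:
                cells[lab] = f"{np.median(x):.2f} ({x.min():.2f} - {x.max():.2f})"
        t = univariate_group_test(df[var].to_numpy(), df["gender"].to_numpy())
        rows.append({"variable": var, "men": cells["men"], "women": cells["women"],
                     "test": t.test_name, "p_value": t.p_value})
    numeric = pd.DataFrame(rows)

    rows = []
    for var in _FLAG_VARS:
        tab = [[int(men[var].sum()), int((~men[var]).sum())],
               [int(women[var].sum()), int((~women[var]).sum())]]
        if df[var].nunique() < 2:        # degenerate flag: no test possible
            name, p = "none", float("nan")
        else:
            t = univariate_group_test(table=tab)
            name, p = t.test_name, t.p_value
        rows.append({"variable": var,
                     "men": f"Yes = {tab[0][0]}, No = {tab[0][1]}",
                     "women": f"Yes = {tab[1][0]}, No = {tab[1][1]}",
                     "test": name, "p_value": p})
    categorical = pd.DataFrame(rows)
    return {"numeric": numeric, "categorical": categorical}
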