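"""Stratified SAF reference statistics and linear age-reference curves.

The reference model is deliberately simple: within each gender (and, for
women, skin-reflectance) stratum, mean SAF and its SD are modelled as linear
functions of age, fit to per-age-group summary statistics by weighted least
squares.  Risk boundaries downstream are mean(age) + k·SD(age).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "StratumStats", "ReferenceTable", "ReferenceCurve",
    "DEFAULT_AGE_BREAKS", "load_reference_grid", "read_reference_table",
    "write_reference_table", "compute_stratum_stats", "pool_stats",
    "fit_reference_curve", "evaluate_curve", "subject_level_slope",
]

#: Upper edges of the study's seven age groups: 18–19, 20–29, …, 60–69, 70–99.
DEFAULT_AGE_BREAKS = [19, 29, 39, 49, 59, 69, 99]


@dataclass(frozen=True)
class StratumStats:
    """Summary of one gender × age-group cell: n, mean SAF, SD (n−1)."""
    gender: str
    age_low: int
    age_high: int
    n: int
    mean_saf: float
    sd_saf: float
    label: str = ""          # optional sub-stratum, e.g. "low_sr"/"high_sr"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("stratum n must be >= 0")
        if self.age_low > self.age_high:
            raise ValueError("age_low must be <= age_high")
        if self.n >= 1 and not np.isnan(self.sd_saf) and self.sd_saf < 0:
            raise ValueError("sd_saf must be >= 0")

    @property
    def midpoint(self) -> float:
        """Age-group midpoint; open-ended tail groups are capped at 10 years
        of width (70–99 → 74.5), matching the simulator's support."""
        return (self.age_low + min(self.age_high, self.age_low + 9)) / 2.0


@dataclass
class ReferenceTable:
    """Ordered list of stratum summaries (houses the printed reference grid)."""
    strata: list[StratumStats]
    label: str = ""

    def __post_init__(self):
        for g in {s.gender for s in self.strata}:
            for lab in {s.label for s in self.strata if s.gender == g}:
                rows = [s for s in self.strata if s.gender == g and s.label == lab]
                rows = sorted(rows, key=lambda s: s.age_low)
                for a, b in zip(rows, rows[1:]):
                    if b.age_low <= a.age_high:
                        raise ValueError(
                            f"overlapping age groups for gender {g}: "
                            f"{a.age_low}-{a.age_high} and {b.age_low}-{b.age_high}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.strata])

    def filter(self, gender=None, label=None) -> "ReferenceTable":
        keep = [s for s in self.strata
                if (gender is None or s.gender == gender)
                and (label is None or s.label == label)]
        return ReferenceTable(keep, label=self.label)

    @property
    def total_n(self) -> int:
        return int(sum(s.n for s in self.strata))


@dataclass
class ReferenceCurve:
    """Linear mean(age) and SD(age) models for one risk stratum."""
    stratum_label: str
    mean_intercept: float
    mean_slope: float
    sd_intercept: float
    sd_slope: float
    age_domain: tuple[float, float] = (18.0, 80.0)
    fit_weights: str = "by_n"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        ages = np.linspace(self.age_domain[0], self.age_domain[1], 201)
        sd = self.sd_intercept + self.sd_slope * ages
        if (sd <= 0).any():
            raise ValueError(
                f"SD model for stratum {self.stratum_label!r} is non-positive "
                f"inside the age domain {self.age_domain}")

    def mean_at(self, age):
        return self.mean_intercept + self.mean_slope * np.asarray(age, float)

    def sd_at(self, age):
        return self.sd_intercept + self.sd_slope * np.asarray(age, float)


def load_reference_grid() -> ReferenceTable:
    """Packaged transcription of the study's gender × age-group reference grid."""
    with importlib.resources.files("safref.data").joinpath(
            "saudi_reference_grid.csv").open() as fh:
        df = pd.read_csv(fh)
    return _table_from_frame(df, label="saudi_reference")


def read_reference_table(path, label: str = "") -> ReferenceTable:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return _table_from_frame(pd.read_csv(path, sep=sep), label=label)


def write_reference_table(table: ReferenceTable, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    cols = ["gender", "age_low", "age_high", "n", "mean_saf", "sd_saf", "label"]
    table.to_frame()[cols].to_csv(path, sep=sep, index=False)


def _table_from_frame(df: pd.DataFrame, label: str = "") -> ReferenceTable:
    strata = [StratumStats(gender=r.gender, age_low=int(r.age_low),
                           age_high=int(r.age_high), n=int(r.n),
                           mean_saf=float(r.mean_saf), sd_saf=float(r.sd_saf),
                           label=str(getattr(r, "label", "") or ""))
              for r in df.itertuples()]
    return ReferenceTable(strata, label=label)


def _age_groups(breaks) -> list[tuple[int, int]]:
    lows = [18] + [b + 1 for b in breaks[:-1]]
    return list(zip(lows, breaks))


def compute_stratum_stats(cohort: Cohort, age_breaks=None, by: str = "gender",
                          sr_threshold: float = 10.0,
                          valid_only: bool = True, ddof: int = 1) -> ReferenceTable:
    """Per-stratum n / sample mean / sample SD (n−1 by default) of SAF.

    ``by`` is ``"gender"`` or ``"gender_sr"`` (women additionally split at the
    skin-reflectance threshold; men are never split — SR does not measurably
    shift male SAF).  Empty strata are emitted with n=0 and NaN statistics.
    ``ddof=0`` gives population SDs, under which :func:`pool_stats` recovers
    the whole-cohort population SD exactly (law of total variance).
    """
    if by not in ("gender", "gender_sr"):
        raise ValueError("by must be 'gender' or 'gender_sr'")
    breaks = list(age_breaks or DEFAULT_AGE_BREAKS)
    df = cohort.df
    if valid_only and "sr_valid" in df.columns:
        df = df[df["sr_valid"]]
    if (df["age"] > breaks[-1]).any():
        raise ValueError("subjects older than the last age break")

    strata: list[StratumStats] = []
    for gender in ("M", "F"):
        sub = df[df["gender"] == gender]
        if by == "gender_sr" and gender == "F":
            groups = [("low_sr", sub[sub["sr"] <= sr_threshold]),
                      ("high_sr", sub[sub["sr"] > sr_threshold])]
        else:
            groups = [("", sub)]
        for lab, g in groups:
            for lo, hi in _age_groups(breaks):
                saf = g.loc[(g["age"] >= lo) & (g["age"] <= hi), "saf"]
                n = len(saf)
                mean = float(saf.mean()) if n >= 1 else float("nan")
                sd = float(saf.std(ddof=ddof)) if n >= 1 + ddof else float("nan")
                strata.append(StratumStats(gender, lo, hi, n, mean, sd, label=lab))
    return ReferenceTable(strata, label=f"computed(by={by})")


def pool_stats(reference: ReferenceTable) -> tuple[float, float]:
    """N-weighted grand mean and law-of-total-variance pooled SD.

    grand_sd² = Σ n_g (s_g² + (x̄_g − grand_mean)²) / Σ n_g — the population
    (total-variance) weighting; within-stratum s_g may use the n−1 convention.
    """
    rows = [s for s in reference.strata if s.n >= 1]
    if not rows:
        raise ValueError("reference table has zero total n")
    for s in rows:
        if np.isnan(s.mean_saf) or np.isnan(s.sd_saf):
            raise ValueError("pool_stats requires defined mean/SD in every stratum")
    n = np.array([s.n for s in rows], float)
    m = np.array([s.mean_saf for s in rows])
    sd = np.array([s.sd_saf for s in rows])
    grand_mean = float((n * m).sum() / n.sum())
    grand_sd = float(np.sqrt((n * (sd**2 + (m - grand_mean) ** 2)).sum() / n.sum()))
    return grand_mean, grand_sd


def _wls_line(x, y, w):
    # closed-form normal equations for y = a + b x with weights w
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("identical age midpoints: slope is unidentifiable")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    return ybar - slope * xbar, slope


def fit_reference_curve(reference: ReferenceTable, gender=None, label=None,
                        stratum_label: str | None = None,
                        weighting: str = "by_n",
                        age_domain: tuple[float, float] = (18.0, 80.0),
                        ) -> ReferenceCurve:
    """Weighted least squares of stratum mean (and SD) on age-group midpoint.

    Weights are the stratum n when ``weighting="by_n"``; SD(age) is fit by
    the same normal equations on the stratum SDs.
    """
    if weighting not in ("by_n", "unweighted"):
        raise ValueError("weighting must be 'by_n' or 'unweighted'")
    table = reference.filter(gender=gender, label=label)
    rows = [s for s in table.strata if s.n >= 1 and not np.isnan(s.mean_saf)
            and not np.isnan(s.sd_saf)]
    if len(rows) < 2:
        raise ValueError("need >= 2 strata with defined statistics to fit a line")
    x = [s.midpoint for s in rows]
    w = [s.n for s in rows] if weighting == "by_n" else [1.0] * len(rows)
    mean_i, mean_s = _wls_line(x, [s.mean_saf for s in rows], w)
    sd_i, sd_s = _wls_line(x, [s.sd_saf for s in rows], w)
    lab = stratum_label or (f"{gender or 'all'}" + (f"_{label}" if label else ""))
    return ReferenceCurve(lab, mean_i, mean_s, sd_i, sd_s,
                          age_domain=age_domain, fit_weights=weighting,
                          diagnostics={"n_strata": len(rows),
                                       "total_n": int(sum(s.n for s in rows))})


def evaluate_curve(curve: ReferenceCurve, age: float) -> tuple[float, float]:
    """Evaluate mean(age) and SD(age); warns outside the fitted age domain."""
    lo, hi = curve.age_domain
    if age < lo or age > hi:
        warnings.warn(f"age {age} outside fitted domain [{lo}, {hi}]: extrapolating")
    mean = float(curve.mean_at(age))
    sd = float(curve.sd_at(age))
    if sd <= 0:
        raise ValueError(f"SD model non-positive at age {age}: invalid scheme region")
    return mean, sd


def subject_level_slope(cohort: Cohort, gender: str) -> float:
    """OLS slope of subject-level SAF on age for one gender (AU/year).

    Complements the canonical midpoint fit; on cohorts whose stratum means
    are linear in age the two agree closely.
    """
    sub = cohort.df[cohort.df["gender"] == gender]
    _, slope = _wls_line(sub["age"], sub["saf"], np.ones(len(sub)))
    return float(slope)
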