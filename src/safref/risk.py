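"""Gender- and skin-reflectance-specific CVD risk stratification.

A risk scheme holds one age-linear reference curve per stratum (men, women
with SR ≤ threshold, women with SR > threshold) and assigns each subject an
ordinal risk group from SAF relative to mean(age) + k·SD(age) boundaries:

* group 0 — SAF below mean + 1 SD (no elevated risk)
* group 1 — between mean + 1 SD and mean + 2 SD (limited increase)
* group 2+ — at or above mean + 2 SD (increased/definite risk; the two top
  groups are merged, as in the adjusted scheme)

Boundary ties escalate: the interval convention is half-open upward,
[b1, b2) → group 1, so a subject sitting exactly on a boundary lands in the
higher group (conservative for a screening tool, and deterministic — the
strict inequalities of the prose definition leave ties undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .reference import ReferenceCurve

__all__ = [
    "RiskScheme", "RiskAssignment", "STRATA", "GROUP_LABELS",
    "assign_stratum", "build_scheme", "classify", "compare_schemes",
    "read_scheme", "write_scheme",
]

STRATA = ["men", "women_low_sr", "women_high_sr"]
GROUP_LABELS = ["0", "1", "2+"]


@dataclass
class RiskScheme:
    name: str
    strata: dict[str, ReferenceCurve]
    multipliers: tuple[float, ...] = (1.0, 2.0)
    sr_threshold: float = 10.0

    def boundary(self, stratum: str, k: int, age) -> np.ndarray:
        """k-th boundary b_k(age) = mean(age) + m_k · SD(age) (lazy)."""
        c = self.strata[stratum]
        return c.mean_at(age) + self.multipliers[k] * c.sd_at(age)


@dataclass(frozen=True)
class RiskAssignment:
    subject_id: str
    stratum_label: str
    b1: float
    b2: float
    group: str


def build_scheme(curves: dict[str, ReferenceCurve],
                 multipliers=(1.0, 2.0), sr_threshold: float = 10.0,
                 name: str = "proposed") -> RiskScheme:
    """Assemble and validate a scheme from per-stratum curves.

    Validates that the multipliers are positive and strictly increasing and
    that the boundary curves stay ordered over each stratum's age domain.
    """
    missing = [s for s in STRATA if s not in curves]
    if missing:
        raise ValueError(f"scheme must cover all strata; missing {missing}")
    m = tuple(float(x) for x in multipliers)
    if len(m) < 2 or any(b <= a for a, b in zip(m, m[1:])) or m[0] <= 0:
        raise ValueError("multipliers must be positive and strictly increasing")
    scheme = RiskScheme(name=name, strata=dict(curves), multipliers=m,
                        sr_threshold=float(sr_threshold))
    for label, curve in scheme.strata.items():
        ages = np.linspace(*curve.age_domain, 201)
        b1 = scheme.boundary(label, 0, ages)
        b2 = scheme.boundary(label, 1, ages)
        if not (b1 < b2).all():
            raise ValueError(f"boundary curves cross inside the domain for {label}")
    return scheme


def assign_stratum(gender: str, sr: float | None, scheme: RiskScheme) -> str:
    """Men → "men" (SR ignored); women split at the SR threshold (≤ → low)."""
    if gender == "M":
        return "men"
    if sr is None or (isinstance(sr, float) and np.isnan(sr)):
        raise ValueError("cannot assign a woman without a skin-reflectance value")
    return "women_low_sr" if sr <= scheme.sr_threshold else "women_high_sr"


def _classify_one(subject_id, gender, sr, age, saf, scheme) -> RiskAssignment:
    if not np.isfinite(saf):
        raise ValueError(f"non-finite SAF for subject {subject_id}")
    stratum = assign_stratum(gender, sr, scheme)
    lo, hi = scheme.strata[stratum].age_domain
    if age < lo or age > hi:
        warnings.warn(f"subject {subject_id}: age {age} outside scheme domain "
                      f"[{lo}, {hi}]; classified by extrapolation")
    b1 = float(scheme.boundary(stratum, 0, age))
    b2 = float(scheme.boundary(stratum, 1, age))
    group = "0" if saf < b1 else ("1" if saf < b2 else "2+")
    return RiskAssignment(subject_id, stratum, b1, b2, group)


def classify(cohort_or_subject, scheme: RiskScheme):
    """Classify one subject (a mapping/row) or a whole cohort.

    Cohorts return a DataFrame with one row per subject: stratum, both
    boundaries evaluated at the subject's age, and the assigned group.
    """
    if isinstance(cohort_or_subject, Cohort):
        df = cohort_or_subject.df
        rows = [_classify_one(r.id, r.gender, r.sr, r.age, r.saf, scheme)
                for r in df.itertuples()]
        out = pd.DataFrame([vars(a) for a in rows])
        out["group"] = pd.Categorical(out["group"], categories=GROUP_LABELS,
                                      ordered=True)
        return out
    s = cohort_or_subject
    get = s.get if hasattr(s, "get") else lambda k, d=None: getattr(s, k, d)
    return _classify_one(get("id", "?"), get("gender"), get("sr"),
                         get("age"), get("saf"), scheme)


def compare_schemes(cohort: Cohort, schemes: list[RiskScheme]):
    """Per scheme × stratum group counts/percentages, plus migrations.

    Returns ``(distribution, migrations)``: the distribution table has one
    row per scheme × stratum × group with count and percentage (percentages
    sum to 100 within each scheme × stratum); ``migrations`` maps scheme-name
    pairs to the cross-tabulation of group assignments.
    """
    if not schemes:
        raise ValueError("need at least one scheme")
    assignments = {sch.name: classify(cohort, sch) for sch in schemes}
    rows = []
    for name, asg in assignments.items():
        for stratum, sub in asg.groupby("stratum_label", observed=False):
            counts = sub["group"].value_counts().reindex(GROUP_LABELS, fill_value=0)
            total = counts.sum()
            for grp in GROUP_LABELS:
                rows.append({"scheme": name, "stratum": stratum, "group": grp,
                             "count": int(counts[grp]),
                             "percent": 100.0 * counts[grp] / total if total else 0.0})
    distribution = pd.DataFrame(rows)
    migrations = {}
    names = [s.name for s in schemes]
    for a, b in zip(names, names[1:]):
        migrations[(a, b)] = pd.crosstab(
            assignments[a]["group"], assignments[b]["group"], dropna=False)
    return distribution, migrations


def write_scheme(scheme: RiskScheme, path) -> None:
    doc = {"name": scheme.name, "sr_threshold": float(scheme.sr_threshold),
           "multipliers": [float(m) for m in scheme.multipliers],
           "strata": {lab: {"mean_intercept": float(c.mean_intercept),
                            "mean_slope": float(c.mean_slope),
                            "sd_intercept": float(c.sd_intercept),
                            "sd_slope": float(c.sd_slope),
                            "age_domain": [float(a) for a in c.age_domain]}
                      for lab, c in scheme.strata.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scheme(path) -> RiskScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    curves = {lab: ReferenceCurve(stratum_label=lab,
                                  mean_intercept=c["mean_intercept"],
                                  mean_slope=c["mean_slope"],
                                  sd_intercept=c["sd_intercept"],
                                  sd_slope=c["sd_slope"],
                                  age_domain=tuple(c.get("age_domain", (18, 80))))
              for lab, c in doc["strata"].items()}
    return build_scheme(curves, multipliers=doc.get("multipliers", (1, 2)),
                        sr_threshold=doc.get("sr_threshold", 10.0),
                        name=doc.get("name", "scheme"))
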