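"""Synthetic cohort generator calibrated to the printed study tables.

The generator emulates a Middle Eastern screening cohort (n≈2,000) with the
statistical structure the downstream analyses assume:

* gender × age-group strata with fixed counts and per-stratum SAF mean/SD
  (calibrated from the published reference grid),
* skin reflectance (SR) with marginal mean 9.5% / SD 3.0% and a hard floor
  at 6% (below which the instrument cannot produce a valid SAF reading) —
  achieved by moment-matching a truncated normal,
* categorical margins (diabetes, smoking, exercise, nationality) assigned as
  *exact counts* by permutation, never sampled,
* anthropometrics from a Gaussian copula with a fixed target correlation
  matrix; BMI and waist-hip ratio recomputed from their components,
* injected covariate effects on SAF (per-gender diabetes shifts, a BMI slope
  in men, an SR slope in women), with residual noise rescaled so each
  stratum's marginal mean/SD still matches the calibration in expectation.

Identical config + seed ⇒ bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, EXERCISE_LEVELS, validate_cohort
from .reference import ReferenceTable, load_reference_grid

__all__ = [
    "GeneratorConfig", "MarginalSummaries", "CalibrationError",
    "calibrate_generator", "default_margins", "default_generator_config",
    "generate_cohort", "ANTHRO_VARS",
]

#: Copula variables, in draw order.
ANTHRO_VARS = ["height", "weight", "waist", "hip", "sbp", "dbp"]

# Target pairwise correlations: weight/waist/hip mutually ~0.85 (hence, with
# BMI recomputed from weight/height², each pair among weight-BMI-waist-hip
# lands above 0.8); systolic-diastolic ~0.65.
_DEFAULT_CORR = np.array([
    #  height weight waist  hip    sbp    dbp
    [1.00, 0.45, 0.20, 0.15, 0.10, 0.05],   # height
    [0.45, 1.00, 0.87, 0.87, 0.35, 0.30],   # weight
    [0.20, 0.87, 1.00, 0.87, 0.35, 0.30],   # waist
    [0.15, 0.87, 0.87, 1.00, 0.30, 0.25],   # hip
    [0.10, 0.35, 0.35, 0.30, 1.00, 0.65],   # sbp
    [0.05, 0.30, 0.30, 0.25, 0.65, 1.00],   # dbp
])

# Marginal (mean, sd) per gender, chosen to bracket the printed medians and
# ranges of the cohort's numerical summary table.
_ANTHRO_MARGINS = {
    "M": {"height": (1.70, 0.07), "weight": (87.0, 16.0), "waist": (101.0, 15.0),
          "hip": (107.0, 12.0), "sbp": (132.0, 16.0), "dbp": (80.0, 12.0)},
    "F": {"height": (1.56, 0.065), "weight": (73.0, 15.0), "waist": (94.0, 14.0),
          "hip": (109.0, 14.0), "sbp": (123.0, 18.0), "dbp": (76.0, 12.0)},
}

_CLIP = {"height": (1.22, 2.10), "weight": (35.0, 170.0), "waist": (50.0, 170.0),
         "hip": (55.0, 185.0), "sbp": (85.0, 230.0), "dbp": (40.0, 185.0)}

# Default injected covariate effects (AU): per-gender diabetes shifts from the
# published adjusted contrasts; slopes consistent with the published
# overweight-men and high-SR-women contrasts.
_DEFAULT_EFFECTS = {
    "diabetes_shift_M": 0.41,
    "diabetes_shift_F": 0.53,
    "bmi_coeff_M": 0.01,      # AU per kg/m², men only
    "sr_coeff_F": 0.065,      # AU per percent SR, women only
}

# Categorical margins per gender (counts; hypertension is a package default
# of 25% per gender — the study never printed its prevalence).
_DEFAULT_PREVALENCES = {
    "M": {"diabetes": 163, "smoking": 328, "hypertension": 281,
          "exercise": {"none": 530, "1-2/month": 142, "1-2/week": 207,
                       "3+/week": 243},
          "nationality": {"Saudi": 640, "Other": 482}},
    "F": {"diabetes": 121, "smoking": 64, "hypertension": 219,
          "exercise": {"none": 464, "1-2/month": 88, "1-2/week": 156,
                       "3+/week": 169},
          "nationality": {"Saudi": 503, "Other": 374}},
}

#: Floor (AU) for the truncated-normal SAF option.
SAF_FLOOR = 0.5


class CalibrationError(ValueError):
    """Reference table unusable for calibration."""


@dataclass
class MarginalSummaries:
    """Marginal targets the generator must hit, apart from the SAF grid."""
    sr_mean: float = 9.5
    sr_sd: float = 3.0
    sr_min: float = 6.0
    prevalences: dict = field(default_factory=lambda: _copy_prev(_DEFAULT_PREVALENCES))
    anthro_margins: dict = field(default_factory=lambda: {g: dict(v) for g, v in _ANTHRO_MARGINS.items()})
    anthropometric_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    covariate_effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))


def _copy_prev(p):
    return {g: {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}
            for g, d in p.items()}


@dataclass
class GeneratorConfig:
    """Fully-specified generator state; serializable to plain dicts."""
    stratum_params: list  # (gender, age_low, age_high, n, saf_mean, saf_sd)
    sr_mean: float
    sr_sd: float
    sr_min: float
    covariate_effects: dict
    prevalences: dict
    anthro_margins: dict
    anthropometric_corr: np.ndarray
    saf_distribution: str = "normal"
    seed: int | None = None

    def __post_init__(self):
        if self.saf_distribution not in ("normal", "lognormal"):
            raise ValueError("saf_distribution must be 'normal' or 'lognormal'")
        for g, lo, hi, n, m, sd in self.stratum_params:
            if n < 0:
                raise ValueError(f"stratum n must be >= 0 ({g} {lo}-{hi})")
            if sd <= 0:
                raise ValueError(f"stratum SAF SD must be > 0 ({g} {lo}-{hi})")
        c = np.asarray(self.anthropometric_corr, float)
        if c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be square and symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")

    def gender_total(self, gender: str) -> int:
        return sum(n for g, _, _, n, _, _ in self.stratum_params if g == gender)


def default_margins() -> MarginalSummaries:
    """The study's printed marginal targets (the calibration conditions)."""
    return MarginalSummaries()


def calibrate_generator(reference: ReferenceTable,
                        margins: MarginalSummaries | None = None,
                        reconcile_female_total: int | None = None,
                        saf_distribution: str = "normal",
                        seed: int | None = None) -> GeneratorConfig:
    """Build a generator config whose stratum parameters mirror ``reference``.

    ``reconcile_female_total``: if given and larger than the reference's
    female total, the difference is added to the female 30–39 stratum (the
    published gender totals and the reference grid disagree by two women;
    the grid itself is kept verbatim).  Categorical margins are rescaled to
    each gender's total by largest remainder when the totals differ.
    """
    margins = margins or default_margins()
    if len(reference.strata) == 0:
        raise CalibrationError("empty reference table")
    for s in reference.strata:
        if not np.isnan(s.sd_saf) and s.sd_saf <= 0:
            raise ValueError(f"non-positive SD in stratum {s.gender} "
                             f"{s.age_low}-{s.age_high}")

    params = [(s.gender, s.age_low, s.age_high, s.n, s.mean_saf, s.sd_saf)
              for s in reference.strata]
    if reconcile_female_total is not None:
        f_total = sum(p[3] for p in params if p[0] == "F")
        extra = reconcile_female_total - f_total
        if extra < 0:
            raise ValueError("reconciled female total below the reference total")
        params = [(g, lo, hi, n + (extra if (g == "F" and lo == 30) else 0), m, sd)
                  for g, lo, hi, n, m, sd in params]

    prevalences = _copy_prev(margins.prevalences)
    for g in ("M", "F"):
        total = sum(n for gg, _, _, n, _, _ in params if gg == g)
        if g in prevalences and total > 0:
            prevalences[g] = _rescale_margins(prevalences[g], total)

    return GeneratorConfig(
        stratum_params=params, sr_mean=margins.sr_mean, sr_sd=margins.sr_sd,
        sr_min=margins.sr_min, covariate_effects=dict(margins.covariate_effects),
        prevalences=prevalences, anthro_margins={g: dict(v) for g, v in margins.anthro_margins.items()},
        anthropometric_corr=np.asarray(margins.anthropometric_corr, float),
        saf_distribution=saf_distribution, seed=seed)


def _rescale_margins(prev: dict, total: int) -> dict:
    """Largest-remainder rescale of count margins to a new gender total."""
    out = {}
    ref_total = None
    # infer the margin base from the largest complete categorical (exercise)
    if isinstance(prev.get("exercise"), dict):
        ref_total = sum(prev["exercise"].values())
    if ref_total is None or ref_total == total:
        return _copy_prev({"x": prev})["x"]
    for key, val in prev.items():
        if isinstance(val, dict):
            out[key] = _largest_remainder(val, total)
        else:
            out[key] = int(round(val * total / ref_total))
    return out


def _largest_remainder(counts: dict, total: int) -> dict:
    keys = list(counts)
    base = sum(counts.values())
    quotas = np.array([counts[k] * total / base for k in keys])
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(quotas - floors))
    for i in order[:short]:
        floors[i] += 1
    return dict(zip(keys, floors.tolist()))


def default_generator_config(saf_distribution: str = "normal") -> GeneratorConfig:
    """Default calibration: reference grid verbatim, female total reconciled
    to the published 877 so the categorical margins (which sum to 877) can be
    assigned exactly; cohort size 1,999."""
    return calibrate_generator(load_reference_grid(), default_margins(),
                               reconcile_female_total=877,
                               saf_distribution=saf_distribution)


@lru_cache(maxsize=32)
def _truncnorm_parent(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (μ, σ) of a normal truncated below at ``lower`` whose truncated
    moments equal (mean, sd).  Solved once per (mean, sd, lower)."""
    def resid(p):
        mu, sig = p
        a = (lower - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]
    sol, info, ier, msg = optimize.fsolve(resid, [mean - sd, sd * 1.5],
                                          full_output=True)
    if ier != 1 or not np.all(np.isfinite(sol)) or sol[1] <= 0:
        raise RuntimeError(f"truncated-normal calibration failed: {msg}")
    return float(sol[0]), float(sol[1])


def _exact_count_vector(counts: dict, total: int, rng, dtype=object):
    if sum(counts.values()) != total:
        raise ValueError(f"categorical counts {counts} do not sum to {total}")
    vals = np.concatenate([np.full(c, k, dtype=dtype) for k, c in counts.items()])
    return rng.permutation(vals)


def _exact_flag_vector(k: int, total: int, rng):
    v = np.zeros(total, bool)
    v[:k] = True
    return rng.permutation(v)


def _lognormal_moments(mean: float, sd: float):
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate one cohort; ``seed`` (or ``config.seed``) is mandatory."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory: reproducibility is non-negotiable")
    rng = np.random.default_rng(seed)

    frames = []
    for gender in ("M", "F"):
        strata = [p for p in config.stratum_params if p[0] == gender and p[3] > 0]
        if not strata:
            continue
        n_g = sum(p[3] for p in strata)

        ages = np.concatenate([
            rng.integers(lo, min(hi, lo + 10) + 1, size=n)   # 70–99 → 70–80
            for _, lo, hi, n, _, _ in strata])
        stratum_idx = np.concatenate([np.full(n, i) for i, (_, _, _, n, _, _)
                                      in enumerate(strata)])

        # anthropometrics: Gaussian copula with normal marginals
        corr = np.asarray(config.anthropometric_corr, float)
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
        z = rng.standard_normal((n_g, len(ANTHRO_VARS))) @ L.T
        anthro = {}
        for j, var in enumerate(ANTHRO_VARS):
            mu, sd = config.anthro_margins[gender][var]
            lo, hi = _CLIP[var]
            anthro[var] = np.clip(mu + sd * z[:, j], lo, hi)
        bmi = anthro["weight"] / anthro["height"] ** 2
        whr = anthro["waist"] / anthro["hip"]

        # skin reflectance: moment-matched truncated normal
        mu, sig = _truncnorm_parent(config.sr_mean, config.sr_sd, config.sr_min)
        a = (config.sr_min - mu) / sig
        sr = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=n_g,
                                 random_state=rng)

        # categorical margins: exact counts by permutation
        prev = config.prevalences[gender]
        diabetes = _exact_flag_vector(prev["diabetes"], n_g, rng)
        smoking = _exact_flag_vector(prev["smoking"], n_g, rng)
        hypertension = _exact_flag_vector(prev["hypertension"], n_g, rng)
        exercise = _exact_count_vector(prev["exercise"], n_g, rng)
        nationality = _exact_count_vector(prev["nationality"], n_g, rng)

        # SAF: stratum mean + centered covariate effects + rescaled noise
        eff = config.covariate_effects
        saf = np.empty(n_g)
        for i, (_, _, _, n, m_s, sd_s) in enumerate(strata):
            idx = np.flatnonzero(stratum_idx == i)
            e = np.zeros(len(idx))
            shift = eff.get(f"diabetes_shift_{gender}", 0.0)
            e += shift * diabetes[idx]
            if gender == "M":
                e += eff.get("bmi_coeff_M", 0.0) * bmi[idx]
            else:
                e += eff.get("sr_coeff_F", 0.0) * sr[idx]
            e -= e.mean()
            noise_sd = np.sqrt(max(sd_s**2 - (e.var() if len(idx) > 1 else 0.0),
                                   (0.25 * sd_s) ** 2))
            if config.saf_distribution == "lognormal":
                lmu, lsd = _lognormal_moments(m_s, noise_sd)
                base = rng.lognormal(lmu, lsd, size=len(idx))
                vals = base + e
            else:
                noise = rng.normal(0.0, noise_sd, size=len(idx))
                vals = m_s + e + noise
                for _ in range(100):         # truncate below the SAF floor
                    bad = vals <= SAF_FLOOR
                    if not bad.any():
                        break
                    vals[bad] = m_s + e[bad] + rng.normal(0.0, noise_sd, bad.sum())
            saf[idx] = np.maximum(vals, SAF_FLOOR + 1e-6)

        frames.append(pd.DataFrame({
            "gender": gender, "age": ages, "nationality": nationality,
            "height": anthro["height"], "weight": anthro["weight"],
            "bmi": bmi, "waist": anthro["waist"], "hip": anthro["hip"],
            "whr": whr, "sbp": anthro["sbp"], "dbp": anthro["dbp"],
            "sr": sr, "saf": saf, "diabetes": diabetes,
            "hypertension": hypertension, "smoking": smoking,
            "exercise": pd.Categorical(exercise, categories=EXERCISE_LEVELS,
                                       ordered=True),
        }))

    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"S{i:05d}" for i in range(len(df))])
    msgs = validate_cohort(df)
    return Cohort(df=df, seed=int(seed), warnings=msgs,
                  provenance=f"synthetic cohort (seed={seed}, "
                             f"saf_distribution={config.saf_distribution})")
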