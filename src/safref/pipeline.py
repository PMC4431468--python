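"""End-to-end analysis orchestration: simulate → reference → stratify →
effects → descriptive stats → O-PLS → report.

Every stage is independently invokable (see :mod:`safref.cli`); a run is
fully determined by its configuration and seed, and the provenance manifest
records a hash of every emitted artifact so reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .cohort_stats import correlation_matrix, summarize_cohort
from .effects import adjusted_group_effect
from .opls import cross_validate, fit_oplsr, permutation_test
from .reference import (compute_stratum_stats, fit_reference_curve,
                        load_reference_grid, pool_stats,
                        write_reference_table, DEFAULT_AGE_BREAKS)
from .risk import build_scheme, classify, compare_schemes, read_scheme, write_scheme
from .simulate import default_generator_config, generate_cohort

__all__ = ["RunConfig", "ReportBundle", "run_analysis", "render_report",
           "StageError", "ConfigError", "STAGES"]

log = logging.getLogger("safref")

STAGES = ["simulate", "reference", "stratify", "effects", "stats", "oplsr",
          "report"]

DEFAULT_OPLSR_PREDICTORS = ["age", "height", "weight", "bmi", "waist", "hip",
                            "whr", "sbp", "dbp", "sr", "diabetes",
                            "hypertension", "smoking"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int | None = None
    cohort_path: str | None = None           # if None, simulate
    age_breaks: list[int] = field(default_factory=lambda: list(DEFAULT_AGE_BREAKS))
    sr_threshold: float = 10.0
    multipliers: list[float] = field(default_factory=lambda: [1.0, 2.0])
    conventional_scheme_path: str | None = None
    effect_factor: str = "gender"
    effect_confounders: list[str] = field(
        default_factory=lambda: ["age", "diabetes", "bmi", "sr"])
    correlation_variables: list[str] = field(
        default_factory=lambda: ["age", "height", "weight", "bmi", "waist",
                                 "hip", "whr", "sbp", "dbp", "sr", "saf"])
    oplsr_predictors: list[str] = field(
        default_factory=lambda: list(DEFAULT_OPLSR_PREDICTORS))
    oplsr_n_ortho: int = 1
    oplsr_folds: int = 7
    oplsr_n_perm: int = 0                    # 0 disables the permutation test
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "results/run"
    format: str = "tsv"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.cohort_path is None and self.seed is None:
            raise ConfigError("a seed is mandatory when the generator is enabled")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        if self.format not in ("tsv", "json"):
            raise ConfigError(f"unsupported format {self.format!r}; use tsv|json")


@dataclass
class ReportBundle:
    config: RunConfig
    cohort: Cohort | None = None
    summary_tables: dict | None = None
    reference_table: object = None
    curves: dict | None = None
    scheme: object = None
    risk_distribution: pd.DataFrame | None = None
    migrations: dict | None = None
    effect_sizes: list = field(default_factory=list)
    correlations: dict | None = None
    oplsr_summaries: dict | None = None
    manifest: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)   # name -> path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "tsv":
        path = path.with_suffix(".tsv")
        df.to_csv(path, sep="\t", index=False)
    else:
        path = path.with_suffix(".json")
        path.write_text(df.to_json(orient="records", indent=1))
    return path


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in order; abort on first failure with the
    stage name, preserving artifacts already written."""
    config.validate()
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(config=config)
    fmt = config.format
    warnings_log: list[str] = []

    def emit(name, df):
        path = _write_table(df, out / name, fmt)
        bundle.artifacts[name] = str(path)

    stage = "simulate"
    try:
        if config.cohort_path:
            bundle.cohort = read_cohort(config.cohort_path)
        else:
            gen = default_generator_config()
            bundle.cohort = generate_cohort(gen, seed=config.seed)
        warnings_log += bundle.cohort.warnings
        if "simulate" in config.stages:
            cpath = out / "cohort.tsv"
            write_cohort(bundle.cohort, cpath)
            bundle.artifacts["cohort"] = str(cpath)
        log.info("cohort ready: %d subjects", len(bundle.cohort))

        if "reference" in config.stages:
            stage = "reference"
            ref = compute_stratum_stats(bundle.cohort, config.age_breaks)
            bundle.reference_table = ref
            gm, gsd = pool_stats(ref)
            rpath = out / "reference_table.tsv"
            write_reference_table(ref, rpath)
            bundle.artifacts["reference_table"] = str(rpath)
            emit("pooled_stats", pd.DataFrame([{"grand_mean": gm, "grand_sd": gsd}]))
            log.info("pooled SAF: mean %.3f, SD %.3f", gm, gsd)

        if "stratify" in config.stages:
            stage = "stratify"
            by_sr = compute_stratum_stats(bundle.cohort, config.age_breaks,
                                          by="gender_sr",
                                          sr_threshold=config.sr_threshold)
            curves = {
                "men": fit_reference_curve(by_sr, gender="M", stratum_label="men"),
                "women_low_sr": fit_reference_curve(
                    by_sr, gender="F", label="low_sr",
                    stratum_label="women_low_sr"),
                "women_high_sr": fit_reference_curve(
                    by_sr, gender="F", label="high_sr",
                    stratum_label="women_high_sr"),
            }
            bundle.curves = curves
            scheme = build_scheme(curves, multipliers=config.multipliers,
                                  sr_threshold=config.sr_threshold)
            bundle.scheme = scheme
            write_scheme(scheme, out / "scheme_proposed.yaml")
            bundle.artifacts["scheme_proposed"] = str(out / "scheme_proposed.yaml")
            schemes = [scheme]
            if config.conventional_scheme_path:
                schemes.append(read_scheme(config.conventional_scheme_path))
            dist, mig = compare_schemes(bundle.cohort, schemes)
            bundle.risk_distribution, bundle.migrations = dist, mig
            emit("risk_distribution", dist)
            for (a, b), tab in mig.items():
                emit(f"migration_{a}_vs_{b}", tab.reset_index())

        if "effects" in config.stages:
            stage = "effects"
            results = []
            for factor, confs in [(config.effect_factor, config.effect_confounders),
                                  ("diabetes", ["age", "bmi", "sr"]),
                                  ("hypertension", ["age", "diabetes", "bmi", "sr"]),
                                  ("smoking", ["age", "diabetes", "bmi", "sr"])]:
                confs = [c for c in confs if c != factor]
                res = adjusted_group_effect(bundle.cohort, factor, confs)
                results.append(res)
            bundle.effect_sizes = results
            emit("effect_sizes", pd.DataFrame([asdict(r) for r in results]))

        if "stats" in config.stages:
            stage = "stats"
            bundle.summary_tables = summarize_cohort(bundle.cohort)
            emit("summary_numeric", bundle.summary_tables["numeric"])
            emit("summary_categorical", bundle.summary_tables["categorical"])
            bundle.correlations = {
                split: correlation_matrix(bundle.cohort,
                                          config.correlation_variables,
                                          split_by=split)
                for split in ("gender", "diabetes")}
            for split, cm in bundle.correlations.items():
                emit(f"correlation_{split}", cm.to_frame().reset_index())
                emit(f"correlation_{split}_long", cm.to_long())

        if "oplsr" in config.stages:
            stage = "oplsr"
            summaries = {}
            rng = np.random.default_rng(config.seed or 0)
            for gender in ("M", "F"):
                sub = bundle.cohort.df[bundle.cohort.df.gender == gender]
                X = sub[config.oplsr_predictors].astype(float).to_numpy()
                y = sub["saf"].to_numpy()
                model = fit_oplsr(X, y, n_ortho=config.oplsr_n_ortho,
                                  columns=config.oplsr_predictors)
                q2 = cross_validate(X, y, n_ortho=config.oplsr_n_ortho,
                                    folds=config.oplsr_folds,
                                    seed=int(rng.integers(2**31)))
                entry = {"gender": gender, "n": len(sub),
                         "n_ortho": config.oplsr_n_ortho,
                         "r2x": model.r2x, "r2y": model.r2y, "q2y": q2}
                if config.oplsr_n_perm:
                    perm = permutation_test(X, y, n_ortho=config.oplsr_n_ortho,
                                            n_perm=config.oplsr_n_perm,
                                            seed=int(rng.integers(2**31)),
                                            folds=config.oplsr_folds)
                    entry["p_q2y"] = perm.p_q2y
                summaries[gender] = {"model": model, "stats": entry}
                loadings = pd.DataFrame({
                    "variable": config.oplsr_predictors,
                    "predictive_weight": model.predictive_weights,
                    "predictive_loading": model.predictive_loadings})
                emit(f"oplsr_loadings_{gender}", loadings)
            bundle.oplsr_summaries = summaries
            emit("oplsr_summary",
                 pd.DataFrame([v["stats"] for v in summaries.values()]))
    except (ConfigError, StageError):
        raise
    except Exception as exc:                     # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "warnings": warnings_log,
        "artifact_hashes": {name: _sha256(Path(p))
                            for name, p in sorted(bundle.artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle.manifest = manifest

    if "report" in config.stages:
        render_report(bundle, fmt=config.format)
    return bundle


def render_report(bundle: ReportBundle, fmt: str = "tsv") -> dict:
    """Human-readable summary plus figures (reference bands, risk bars,
    O-PLS scores/loadings).  Returns {name: path} of everything written."""
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown format {fmt!r}: supported formats are tsv, json")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle.config.out_dir)
    written = {}

    lines = [f"safref analysis report (seed={bundle.config.seed})", ""]
    if bundle.cohort is not None:
        lines.append(f"cohort: {len(bundle.cohort)} subjects "
                     f"({len(bundle.cohort.men)} men, {len(bundle.cohort.women)} women)")
    if bundle.reference_table is not None:
        gm, gsd = pool_stats(bundle.reference_table)
        lines.append(f"pooled SAF: {gm:.2f} (SD {gsd:.2f}) AU")
    for res in bundle.effect_sizes:
        lines.append(f"adjusted effect of {res.factor}: d={res.d:.2f} "
                     f"(raw {res.raw_difference:+.2f} AU, "
                     f"{int(res.level*100)}% CI {res.ci_low:.2f}..{res.ci_high:.2f}, "
                     f"adjusted for {','.join(res.adjusted_for) or 'nothing'})")
    if bundle.oplsr_summaries:
        for g, v in bundle.oplsr_summaries.items():
            s = v["stats"]
            lines.append(f"O-PLS ({g}): R2X={s['r2x']:.2f} R2Y={s['r2y']:.2f} "
                         f"Q2Y={s['q2y']:.2f}")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    written["report"] = str(path)

    if bundle.scheme is not None and bundle.cohort is not None:
        fig, axes = plt.subplots(1, len(bundle.scheme.strata), figsize=(12, 4),
                                 sharey=True)
        for ax, (label, curve) in zip(np.atleast_1d(axes),
                                      bundle.scheme.strata.items()):
            ages = np.linspace(*curve.age_domain, 100)
            b1 = bundle.scheme.boundary(label, 0, ages)
            b2 = bundle.scheme.boundary(label, 1, ages)
            top = max(b2.max() * 1.2, 5)
            ax.fill_between(ages, 0, b1, alpha=.25, color="green", label="group 0")
            ax.fill_between(ages, b1, b2, alpha=.25, color="orange", label="group 1")
            ax.fill_between(ages, b2, top, alpha=.25, color="red", label="group 2+")
            ax.plot(ages, curve.mean_at(ages), "k-", lw=1)
            ax.plot(ages, b1, "k--", lw=1)
            ax.plot(ages, b2, "k--", lw=1)
            ax.set_title(label)
            ax.set_xlabel("age (years)")
        np.atleast_1d(axes)[0].set_ylabel("SAF (AU)")
        fig.tight_layout()
        fig.savefig(out / "risk_bands.png", dpi=110)
        plt.close(fig)
        written["risk_bands"] = str(out / "risk_bands.png")

    if bundle.risk_distribution is not None:
        dist = bundle.risk_distribution
        fig, axes = plt.subplots(1, dist["stratum"].nunique(), figsize=(12, 4),
                                 sharey=True)
        for ax, (stratum, sub) in zip(np.atleast_1d(axes),
                                      dist.groupby("stratum")):
            width = 0.8 / max(sub["scheme"].nunique(), 1)
            for k, (scheme, ssub) in enumerate(sub.groupby("scheme")):
                x = np.arange(len(ssub))
                ax.bar(x + k * width, ssub["percent"], width, label=scheme)
            ax.set_xticks(np.arange(len(ssub)), ssub["group"])
            ax.set_title(stratum)
            ax.set_xlabel("risk group")
        np.atleast_1d(axes)[0].set_ylabel("percent of stratum")
        np.atleast_1d(axes)[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "risk_distribution.png", dpi=110)
        plt.close(fig)
        written["risk_distribution_fig"] = str(out / "risk_distribution.png")

    if bundle.oplsr_summaries:
        for g, v in bundle.oplsr_summaries.items():
            model = v["model"]
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
            t_o = (model.ortho_scores[0] if model.n_ortho
                   else np.zeros_like(model.predictive_scores))
            ax1.scatter(model.predictive_scores, t_o, s=6, alpha=.5)
            ax1.set_xlabel("predictive score t")
            ax1.set_ylabel("orthogonal score t_o")
            ax1.set_title(f"O-PLS scores ({g})")
            ax2.barh(model.columns or range(len(model.predictive_loadings)),
                     model.predictive_loadings)
            ax2.set_title("predictive loadings")
            fig.tight_layout()
            fig.savefig(out / f"oplsr_{g}.png", dpi=110)
            plt.close(fig)
            written[f"oplsr_{g}"] = str(out / f"oplsr_{g}.png")
    return written
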