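"""End-to-end experiment orchestration.

``run_pipeline`` composes the library stages — generate (or load) registry
data, build the cohort, fit the two risk-adjustment models, profile
hospitals under both, and compare the profiles — writing every intermediate
artifact to the output directory together with a manifest (seed, config
hash, versions) that suffices to reproduce the run. Any stage failure
aborts with a stage-labelled error; artifacts from completed stages are
preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, models, profiling, synthetic
from .cohort import build_ami_cohort, build_hip_cohort
from .config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ("generate", "cohort", "model", "profile", "compare")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: RunConfig) -> str:
    as_dict = dataclasses.asdict(config)
    as_dict.pop("outdir", None)      # hash the scientific config, not paths
    payload = yaml.safe_dump(as_dict, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _describe(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: n and % per binary covariate, mean/sd for age."""
    rows = [("n_episodes", len(cohort), np.nan),
            ("age_mean_sd", round(cohort["age"].mean(), 1),
             round(cohort["age"].std(), 1)),
            ("outcome", int(cohort["outcome"].sum()),
             round(100 * cohort["outcome"].mean(), 2))]
    skip = {"episode_id", "patient_id", "hospital_id", "outcome", "age",
            "gender", "sbp_cat", "inr_cat"}
    for col in cohort.columns:
        if col in skip or cohort[col].dtype == object:
            continue
        n = int(cohort[col].sum())
        rows.append((col, n, round(100 * n / len(cohort), 2)))
    return pd.DataFrame(rows, columns=["risk_factor", "n", "pct"])


def run_pipeline(config: RunConfig, through: str = "compare") -> dict:
    """Run the pipeline up to and including stage ``through``.

    Returns a report dict with the in-memory results of each completed stage
    and the paths of all written artifacts.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; one of {STAGES}")
    last = STAGES.index(through)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": outdir, "artifacts": []}

    def _save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        report["artifacts"].append(path)

    manifest = {
        "seed": config.seed,
        "cohort": config.cohort,
        "config_sha256": _config_hash(config),
        "riskprofiler_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages": STAGES[:last + 1],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")

    # -- generate / load ----------------------------------------------------
    try:
        if config.generator is not None:
            gen = config.generator.replace(seed=config.seed)
            registry = synthetic.generate_population(gen)
            registry.write_csvs(outdir / "data")
        else:
            registry = synthetic.read_registry(config.input_dir)
        report["registry"] = registry
        logger.info("stage generate: %d discharge rows", len(registry.discharges))
    except Exception as e:                             # noqa: BLE001
        raise StageError("generate", e) from e
    if last < 1:
        return report

    # -- cohort -------------------------------------------------------------
    try:
        builder = build_ami_cohort if config.cohort == "ami" else build_hip_cohort
        cohort, attrition = builder(registry, config.cohort_spec)
        _save(cohort, "cohort.csv")
        _save(attrition, "attrition.csv")
        _save(_describe(cohort), "descriptive.csv")
        report["cohort"], report["attrition"] = cohort, attrition
        logger.info("stage cohort: %d episodes, %d excluded",
                    len(cohort), int(attrition["n_excluded"].sum()))
    except Exception as e:                             # noqa: BLE001
        raise StageError("cohort", e) from e
    if last < 2:
        return report

    # -- model pair ---------------------------------------------------------
    try:
        cand_a, cand_b = models.candidate_sets(cohort, config.cohort)
        sel_cfg = dataclasses.replace(config.selection, seed=config.seed)
        pair = models.build_model_pair(cohort, cohort["outcome"].to_numpy(),
                                       cand_a, cand_b, sel_cfg)
        _save(models.model_report(pair, cohort, cohort["outcome"].to_numpy()),
              "model_report.csv")
        freq = pd.DataFrame({
            "candidate": pair.selection_b.frequencies.index,
            "frequency_full": pair.selection_b.frequencies.to_numpy(),
            "frequency_discharge": pair.selection_a.frequencies.reindex(
                pair.selection_b.frequencies.index).to_numpy(),
            "retained_full": [c in pair.selection_b.retained
                              for c in pair.selection_b.frequencies.index],
        })
        _save(freq, "selection_frequencies.csv")
        report["pair"] = pair
        logger.info("stage model: c=%.3f (discharge) vs %.3f (full)",
                    pair.model_a.c, pair.model_b.c)
    except Exception as e:                             # noqa: BLE001
        raise StageError("model", e) from e
    if last < 3:
        return report

    # -- profile ------------------------------------------------------------
    try:
        prof_cfg = config.profiling
        charts: dict[str, profiling.FunnelChart] = {}
        results: dict[str, profiling.StandardisationResult] = {}
        for tag, model in (("discharge", pair.model_a), ("full", pair.model_b)):
            covs = list(model.columns)
            res = profiling.standardise(cohort, covs, prof_cfg)
            chart = profiling.classify_hospitals(res, prof_cfg)
            merged = res.table.merge(
                chart.points[["hospital_id", "classification", "direction"]],
                on="hospital_id")
            _save(merged, f"hospital_profile_{tag}.csv")
            results[tag], charts[tag] = res, chart
        summary = pd.DataFrame({
            "model": list(results),
            "k": [results[t].k for t in results],
            "total_events": [results[t].total_events for t in results],
            "overall_rate": [results[t].overall_rate for t in results],
            "n_hospitals": [len(results[t].table) for t in results],
            "n_excluded_low_volume": [len(results[t].excluded) for t in results],
        })
        _save(summary, "profiling_summary.csv")
        for ext in ("svg", "png"):
            profiling.funnel_plot(
                charts, outdir / f"funnel.{ext}",
                title=f"Adjusted outcome proportion by hospital ({config.cohort})")
            report["artifacts"].append(outdir / f"funnel.{ext}")
        mlm = profiling.multilevel_sensitivity(cohort, list(pair.model_b.columns))
        report["multilevel"] = mlm
        report["profiles"], report["charts"] = results, charts
        logger.info("stage profile: k=%.4f, between-hospital sd=%.3f",
                    results["full"].k, mlm.sd)
    except Exception as e:                             # noqa: BLE001
        raise StageError("profile", e) from e
    if last < 4:
        return report

    # -- compare ------------------------------------------------------------
    try:
        rho, concord = profiling.rank_agreement(charts["discharge"].points,
                                                charts["full"].points)
        mlm_rho = float(pd.Series(mlm.shrunken_logodds).corr(
            results["full"].table.set_index("hospital_id")["estimate"],
            method="spearman"))
        comparison = pd.DataFrame([
            ("c_discharge", pair.model_a.c),
            ("c_full", pair.model_b.c),
            ("delta_c", pair.delta_c),
            ("spearman_rho_profiles", rho),
            ("outlier_concordance", concord),
            ("between_hospital_sd", mlm.sd),
            ("spearman_rho_multilevel_vs_fixed", mlm_rho),
        ], columns=["quantity", "value"])
        comparison["value"] = comparison["value"].round(6)
        _save(comparison, "comparison.csv")
        report["comparison"] = comparison
    except Exception as e:                             # noqa: BLE001
        raise StageError("compare", e) from e
    return report
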