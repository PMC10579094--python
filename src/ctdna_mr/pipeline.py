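"""End-to-end orchestration: validate -> origins -> response calls ->
concordance -> depth/ROC -> LOD -> survival, with a run manifest.

Stages short-circuit gracefully: a cohort without tumor samples skips
the tissue-concordance stage with a notice, a cohort without both
responder classes skips the ROC, and so on.  Output files are
deterministic for fixed inputs and seed; the manifest records the
config snapshot, per-stage row counts and output checksums, so a run is
reproducible from the manifest alone.  Patient attrition (enrolled ->
radiographically evaluable -> ctDNA-evaluable -> detectable) is logged
per stage.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (cohort_io, concordance_stats, depth_response_roc, lod_model,
               survival_analysis, tumor_load_response, variant_origin)
from .cohort_io import CohortDataset, write_analysis_outputs

logger = logging.getLogger("ctdna_mr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(dataset: CohortDataset, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every analysis stage on a validated cohort.

    Returns the run manifest (also written as ``manifest.json`` minus
    wall-clock timestamps, keeping the output tree byte-reproducible).
    """
    out_dir = Path(out_dir)
    seed = dataset.config.seed if seed is None else seed
    started = time.time()
    results: dict[str, object] = {}
    stages: dict[str, dict] = {}

    def stage(name):
        def deco(fn):
            try:
                info = fn() or {}
                stages[name] = {"status": "completed", **info}
                logger.info("stage %s: %s", name, stages[name])
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
        return deco

    @stage("validate")
    def _validate():
        report = cohort_io.validate_cohort(dataset)
        if report:
            raise cohort_io.CohortValidationError("; ".join(report))
        return {"n_patients": len(dataset.patients),
                "n_variant_observations": len(dataset.variants)}

    @stage("classify_origins")
    def _classify():
        annotated = variant_origin.annotate_cohort_origins(dataset)
        results["annotated_variants"] = annotated
        results["origin_summary"] = variant_origin.origin_summary(annotated)
        tumor_obs = dataset.tumor_variants()
        if len(tumor_obs):
            conc = variant_origin.tumor_plasma_origin_concordance(
                annotated, tumor_obs)
            results["tumor_origin_concordance"] = {
                k: v for k, v in conc.items() if k != "table"}
            results["tumor_origin_concordance_table"] = conc["table"]
        else:
            return {"n_unique_plasma_variants": len(annotated),
                    "notice": "no tumor samples; tissue concordance skipped"}
        return {"n_unique_plasma_variants": len(annotated)}

    @stage("call_responses")
    def _respond():
        calls = tumor_load_response.call_cohort_responses(
            results["annotated_variants"], dataset)
        results["response_calls"] = calls
        results["molecular_response_rate"] = \
            tumor_load_response.molecular_response_rate(
                calls, dataset.config.ci_level)
        results["pattern_counts"] = tumor_load_response.pattern_counts(calls)
        counts = calls["status"].value_counts().to_dict()
        return {"status_counts": counts}

    @stage("concordance")
    def _concordance():
        calls = results["response_calls"]
        if not calls["status"].isin(["mR", "mPD"]).any():
            return {"notice": "no evaluable patients; concordance skipped"}
        out = {}
        for criterion in ("RECIST", "iRECIST"):
            table = concordance_stats.build_concordance_table(
                calls, dataset.patients, criterion)
            if table.n == 0:
                out[criterion] = {"notice": "empty table"}
                continue
            out[criterion] = concordance_stats.concordance_performance(
                table, dataset.config.ci_level)
        results["concordance"] = out
        results["subgroup_concordance"] = \
            concordance_stats.subgroup_concordance_by_baseline_maf(
                calls, dataset.patients, level=dataset.config.ci_level)
        return {"criteria": list(out)}

    @stage("depth_roc")
    def _roc():
        calls = results["response_calls"]
        roc_summaries = {}
        roc_tables = []
        for tp in ("C2D1", "C3D1"):
            for metric in ("max", "mean", "median"):
                try:
                    depths = depth_response_roc.cohort_depth_table(
                        calls[calls["status"].isin(["mR", "mPD"])],
                        tp, metric)
                    curve = depth_response_roc.roc_auc(
                        depths, dataset.patients, seed=seed)
                except ValueError as exc:
                    roc_summaries[f"{metric}_{tp}"] = {"notice": str(exc)}
                    continue
                roc_summaries[f"{metric}_{tp}"] = {
                    "auc": curve.auc, "ci": [curve.ci_lower, curve.ci_upper],
                    "n_positive": curve.n_positive,
                    "n_negative": curve.n_negative}
                roc_tables.append(pd.DataFrame({
                    "timepoint": tp, "metric": metric,
                    "threshold": curve.thresholds,
                    "fpr": curve.fpr, "tpr": curve.tpr}))
        results["roc_summary"] = roc_summaries
        if roc_tables:
            results["roc_curves"] = pd.concat(roc_tables, ignore_index=True)
        return {"n_roc": len(roc_summaries)}

    @stage("lod")
    def _lod():
        positions = lod_model.baseline_positions_from_calls(
            results["annotated_variants"], dataset.variants)
        if positions.empty:
            return {"notice": "no baseline tumor variants; LOD skipped"}
        profile = lod_model.assay_sensitivity_profile(positions)
        results["lod_table"] = lod_model.lod_summary_table(profile)
        results["lod_median_sensitivity"] = {
            str(maf): p for maf, p in profile.median_sensitivity.items()}
        return {"n_positions": len(positions)}

    @stage("survival")
    def _survival():
        calls = results["response_calls"]
        surv = {}
        for endpoint in ("pfs", "os"):
            try:
                surv[endpoint] = survival_analysis.survival_by_response(
                    dataset.patients, calls, endpoint,
                    dataset.config.ci_level)
            except ValueError as exc:
                surv[endpoint] = {"notice": str(exc)}
        if "collection_day" in dataset.samples.columns:
            ttr = survival_analysis.build_time_to_molecular_response(
                calls, dataset.samples)
            if len(ttr) and ttr["event"].any():
                curve = survival_analysis.kaplan_meier(
                    ttr["months"], ttr["event"],
                    level=dataset.config.ci_level)
                surv["time_to_mr"] = survival_analysis.median_survival(curve)
        results["survival"] = surv
        return {"endpoints": list(surv)}

    file_manifest = write_analysis_outputs(results, out_dir)
    manifest = {
        "seed": seed,
        "config": {k: getattr(dataset.config, k)
                   for k in vars(dataset.config)},
        "stages": stages,
        "outputs": file_manifest,
        "n_stages_completed": sum(1 for s in stages.values()
                                  if s.get("status") == "completed"),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(cohort_io._jsonable(manifest), indent=1,
                   sort_keys=True) + "\n")
    manifest["started_at"] = datetime.datetime.fromtimestamp(
        started).isoformat()
    manifest["elapsed_s"] = time.time() - started
    return manifest
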