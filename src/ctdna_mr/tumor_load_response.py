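"""Circulating tumor load and molecular-response calling.

The maximal mutant allele fraction (maxMAF) over a patient's
tumor-derived plasma variants is used as the indicator of circulating
tumor load at each timepoint (mean and median MAF are computed
alongside).  A variant tracked for a patient but not called at an
available timepoint contributes MAF 0 there.

Molecular response (mR) is clearance of maxMAF to undetectable levels by
the third treatment cycle: maxMAF at or below the clearance threshold
(default exactly 0) at C3D1, or at C2D1 when the C3D1 draw was missed.
Persistent maxMAF at C3D1 is molecular progressive disease (mPD) — this
includes transient clearance at C2D1 followed by detectable ctDNA at
C3D1.  Patients with no tumor-derived variant detected at any available
timepoint are "undetectable"; patients without a baseline plus at least
one on-therapy plasma sample are not evaluable.

Four kinetic patterns are distinguished among evaluable patients with
detectable ctDNA: clearance at C2D1, clearance at C3D1, deep reduction
(best on-therapy maxMAF reduction > 85% without sustained clearance)
and persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import (BASELINE, CohortDataset, ON_THERAPY, TIMEPOINTS)
from .concordance_stats import BinomialCI, clopper_pearson_interval

STATUSES = ("mR", "mPD", "undetectable", "not_evaluable")
PATTERNS = ("clearance_C2", "clearance_C3", "deep_reduction",
            "persistence", "none")

DEFAULT_REDUCTION_THRESHOLD = 0.85


@dataclass
class LoadTrajectory:
    """Per-patient circulating tumor load at each timepoint.

    ``metrics`` maps timepoint -> dict with keys ``max_maf``,
    ``mean_maf``, ``median_maf``, ``n_tumor_variants`` and
    ``sample_available``; the MAF metrics are None when the plasma draw
    is unavailable.
    """

    patient_id: str
    metrics: dict[str, dict]

    def value(self, timepoint: str, metric: str = "max") -> float | None:
        m = self.metrics[timepoint]
        if not m["sample_available"]:
            return None
        return m[f"{metric}_maf"]

    def available_timepoints(self) -> list[str]:
        return [tp for tp in TIMEPOINTS
                if self.metrics[tp]["sample_available"]]


@dataclass
class MolecularResponseCall:
    patient_id: str
    status: str
    clearance_timepoint: str | None
    kinetic_pattern: str
    best_on_therapy_reduction: float | None
    reason: str = ""


def compute_load_trajectory(annotated: pd.DataFrame,
                            samples: pd.DataFrame,
                            patient_id: str) -> LoadTrajectory:
    """Tumor-load metrics over the patient's tumor-derived variants.

    Germline and hematopoietic variants must already be excluded via the
    annotation's ``excluded_from_load`` flag.  Metrics are 0 when an
    available sample shows no tumor-derived variant, and None when the
    sample itself is unavailable.
    """
    mine = annotated[(annotated["patient_id"] == patient_id)
                     & (~annotated["excluded_from_load"].astype(bool))]
    plasma = samples[(samples["patient_id"] == patient_id)
                     & (samples["compartment"] == "plasma")]
    available = {tp: bool(plasma[(plasma["timepoint"] == tp)
                                 & plasma["available"]].shape[0])
                 for tp in TIMEPOINTS}
    return _trajectory_core(patient_id, mine, available)


def _trajectory_core(patient_id: str, mine: pd.DataFrame,
                     available: dict[str, bool]) -> LoadTrajectory:
    metrics: dict[str, dict] = {}
    for tp in TIMEPOINTS:
        if not available[tp]:
            metrics[tp] = {"max_maf": None, "mean_maf": None,
                           "median_maf": None, "n_tumor_variants": 0,
                           "sample_available": False}
            continue
        # tracked variants absent from this sample count as MAF 0
        mafs = mine[f"maf_{tp}"].fillna(0.0).to_numpy(dtype=float)
        detected = int((mafs > 0).sum())
        if len(mafs) == 0:
            mafs = np.array([0.0])
        metrics[tp] = {
            "max_maf": float(np.max(mafs)),
            "mean_maf": float(np.mean(mafs)),
            "median_maf": float(np.median(mafs)),
            "n_tumor_variants": detected,
            "sample_available": True,
        }
    return LoadTrajectory(patient_id=patient_id, metrics=metrics)


def call_molecular_response(trajectory: LoadTrajectory,
                            clearance_threshold: float = 0.0,
                            reduction_threshold: float =
                            DEFAULT_REDUCTION_THRESHOLD,
                            ) -> MolecularResponseCall:
    """Call mR / mPD / undetectable / not_evaluable for one patient."""
    pid = trajectory.patient_id
    avail = trajectory.available_timepoints()
    on_therapy_avail = [tp for tp in ON_THERAPY if tp in avail]
    if BASELINE not in avail:
        return MolecularResponseCall(pid, "not_evaluable", None, "none",
                                     None, reason="baseline_missing")
    if not on_therapy_avail:
        return MolecularResponseCall(pid, "not_evaluable", None, "none",
                                     None, reason="no_on_therapy_sample")

    def cleared(tp: str) -> bool:
        return trajectory.value(tp, "max") <= clearance_threshold

    if all(cleared(tp) for tp in avail):
        # no tumor-derived ctDNA detected at any available timepoint
        return MolecularResponseCall(pid, "undetectable", None, "none", None)

    # decision timepoint: C3D1, falling back to C2D1 when C3D1 was missed
    decision_tp = on_therapy_avail[-1]
    baseline = trajectory.value(BASELINE, "max")
    reduction = _best_reduction(trajectory, on_therapy_avail, baseline)
    if cleared(decision_tp):
        clearance_tp = decision_tp
        for tp in on_therapy_avail:
            if cleared(tp):
                clearance_tp = tp
                break
        pattern = ("clearance_C2" if clearance_tp == "C2D1"
                   else "clearance_C3")
        return MolecularResponseCall(pid, "mR", clearance_tp, pattern,
                                     reduction)
    pattern = classify_kinetic_pattern(trajectory, reduction_threshold,
                                       clearance_threshold)
    return MolecularResponseCall(pid, "mPD", None, pattern, reduction)


def _best_reduction(trajectory: LoadTrajectory, on_therapy: list[str],
                    baseline: float | None) -> float | None:
    if baseline is None or baseline <= 0:
        return None
    values = [trajectory.value(tp, "max") for tp in on_therapy]
    return max((baseline - v) / baseline for v in values)


def classify_kinetic_pattern(trajectory: LoadTrajectory,
                             reduction_threshold: float =
                             DEFAULT_REDUCTION_THRESHOLD,
                             clearance_threshold: float = 0.0) -> str:
    """Kinetic pattern for an evaluable patient with detectable ctDNA.

    mR patients are pattern ``clearance_C2``/``clearance_C3`` (assigned in
    :func:`call_molecular_response`); here the mPD side is split into
    ``deep_reduction`` (best on-therapy fractional maxMAF reduction
    strictly above the threshold, transient clearance included) versus
    ``persistence``.
    """
    avail = trajectory.available_timepoints()
    on_therapy = [tp for tp in ON_THERAPY if tp in avail]
    if BASELINE not in avail or not on_therapy:
        return "none"
    baseline = trajectory.value(BASELINE, "max")
    if baseline is None or baseline <= clearance_threshold:
        return "persistence"  # detectable only on therapy
    reduction = _best_reduction(trajectory, on_therapy, baseline)
    if reduction is not None and reduction > reduction_threshold:
        return "deep_reduction"
    return "persistence"


def call_cohort_responses(annotated: pd.DataFrame,
                          dataset: CohortDataset) -> pd.DataFrame:
    """Trajectories + response calls for every patient, as one table."""
    cfg = dataset.config
    load_vars = annotated[~annotated["excluded_from_load"].astype(bool)]
    by_patient = {pid: grp for pid, grp in load_vars.groupby("patient_id")}
    empty = load_vars.iloc[0:0]
    plasma = dataset.samples[dataset.samples["compartment"] == "plasma"]
    avail_map = {(r.patient_id, r.timepoint): bool(r.available)
                 for r in plasma.itertuples()}
    rows = []
    for pid in dataset.patients["patient_id"]:
        available = {tp: avail_map.get((pid, tp), False)
                     for tp in TIMEPOINTS}
        traj = _trajectory_core(pid, by_patient.get(pid, empty), available)
        call = call_molecular_response(traj, cfg.clearance_threshold,
                                       cfg.reduction_threshold)
        row = {
            "patient_id": pid,
            "status": call.status,
            "clearance_timepoint": call.clearance_timepoint or "",
            "kinetic_pattern": call.kinetic_pattern,
            "best_on_therapy_reduction": call.best_on_therapy_reduction,
            "reason": call.reason,
        }
        for tp in TIMEPOINTS:
            for metric in ("max", "mean", "median"):
                row[f"{metric}_maf_{tp}"] = traj.metrics[tp][f"{metric}_maf"]
            row[f"n_tumor_variants_{tp}"] = \
                traj.metrics[tp]["n_tumor_variants"]
            row[f"sample_available_{tp}"] = \
                traj.metrics[tp]["sample_available"]
        rows.append(row)
    columns = ["patient_id", "status", "clearance_timepoint",
               "kinetic_pattern", "best_on_therapy_reduction", "reason"]
    for tp in TIMEPOINTS:
        columns += [f"{m}_maf_{tp}" for m in ("max", "mean", "median")]
        columns += [f"n_tumor_variants_{tp}", f"sample_available_{tp}"]
    return pd.DataFrame(rows, columns=columns)


def molecular_response_rate(calls: pd.DataFrame,
                            level: float = 0.90) -> dict:
    """mR rate among evaluable patients (mR + mPD), with exact CI.

    Undetectable and not-evaluable patients are excluded from the
    denominator.  Returns rate None when nobody is evaluable.
    """
    n_mr = int((calls["status"] == "mR").sum())
    n_eval = int(calls["status"].isin(["mR", "mPD"]).sum())
    if n_eval == 0:
        return {"n_mr": 0, "n_evaluable": 0, "rate": None, "ci": None}
    ci = clopper_pearson_interval(n_mr, n_eval, level)
    return {"n_mr": n_mr, "n_evaluable": n_eval, "rate": n_mr / n_eval,
            "ci": ci}


def pattern_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Cohort counts of the four kinetic patterns (plus 'none')."""
    return {p: int((calls["kinetic_pattern"] == p).sum()) for p in PATTERNS}
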