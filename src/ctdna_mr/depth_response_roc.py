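"""Depth of ctDNA response and its ROC performance.

The depth of response for patient i at on-therapy timepoint Cx is the
fractional change in circulating tumor load relative to baseline,

    d = (m_C1 - m_Cx) / m_C1,

where m is the maxMAF (or mean/median MAF) over the patient's
tumor-derived variants.  d = 1 means complete clearance; negative d is
an increase.  When the baseline load is 0 the ratio is undefined; such
patients receive the smallest d observed among the remaining patients at
that timepoint (the largest increase in the cohort), flagged imputed.

The continuous d predicts binary radiographic response (responder =
CR/PR); performance is the area under the ROC curve with a DeLong-style
asymptotic confidence interval (seeded bootstrap available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .cohort_io import BASELINE, RECIST_RESPONDER


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    n_positive: int
    n_negative: int
    ci_method: str


def depth_of_response(baseline_value: float,
                      on_therapy_value: float) -> float:
    """d = (m1 - mx)/m1 for baseline load m1 > 0.

    Raises ValueError for m1 = 0 (undefined; impute at cohort level via
    :func:`cohort_depth_table`).
    """
    if baseline_value < 0 or on_therapy_value < 0:
        raise ValueError("loads must be non-negative")
    if baseline_value == 0:
        raise ValueError("depth of response undefined for zero baseline")
    return (baseline_value - on_therapy_value) / baseline_value


def cohort_depth_table(calls: pd.DataFrame, timepoint: str,
                       metric: str = "max") -> pd.DataFrame:
    """Per-patient depth of response at one timepoint, imputation applied.

    ``calls`` is the table from
    :func:`ctdna_mr.tumor_load_response.call_cohort_responses`.  Patients
    whose baseline or requested on-therapy sample is unavailable are
    excluded (reason recorded); patients with zero baseline load receive
    the cohort minimum of the defined d values, flagged ``imputed``.
    """
    if metric not in ("max", "mean", "median"):
        raise ValueError(f"unknown metric {metric!r}")
    base_col = f"{metric}_maf_{BASELINE}"
    tp_col = f"{metric}_maf_{timepoint}"
    if tp_col not in calls.columns:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rows = []
    for row in calls.itertuples():
        m1 = getattr(row, base_col)
        mx = getattr(row, tp_col)
        if m1 is None or (isinstance(m1, float) and np.isnan(m1)):
            rows.append((row.patient_id, np.nan, False, "baseline_missing"))
        elif mx is None or (isinstance(mx, float) and np.isnan(mx)):
            rows.append((row.patient_id, np.nan, False, "sample_missing"))
        elif m1 == 0:
            rows.append((row.patient_id, np.nan, True, ""))
        else:
            rows.append((row.patient_id, depth_of_response(m1, mx),
                         False, ""))
    table = pd.DataFrame(rows, columns=["patient_id", "d", "imputed",
                                        "reason"])
    table = table[table["reason"] == ""].drop(columns="reason")
    defined = table.loc[~table["imputed"], "d"]
    if table["imputed"].any():
        if defined.empty:
            raise ValueError("all depths undefined; imputation impossible")
        table.loc[table["imputed"], "d"] = float(defined.min())
    table["timepoint"] = timepoint
    table["metric"] = metric
    return table.reset_index(drop=True)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized pairwise-comparison (Mann–Whitney) statistic:
    ties between a positive and a negative count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _delong_variance(scores: np.ndarray, labels: np.ndarray,
                     auc: float) -> float:
    """Asymptotic AUC variance from paired placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement of each positive among negatives, and vice versa
    v10 = ((pos[:, None] > neg[None, :]).mean(axis=1)
           + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=1))
    v01 = ((pos[None, :] > neg[:, None]).mean(axis=1)
           + 0.5 * (pos[None, :] == neg[:, None]).mean(axis=1))
    s10 = np.var(v10, ddof=1) if len(pos) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(neg) > 1 else 0.0
    return s10 / len(pos) + s01 / len(neg)


def roc_auc(depth_table: pd.DataFrame, patients: pd.DataFrame,
            responder_set: frozenset = RECIST_RESPONDER,
            bor_column: str = "recist_bor",
            level: float = 0.95,
            ci_method: str = "delong",
            n_boot: int = 2000,
            seed: int = 0) -> RocCurve:
    """ROC of depth of response against radiographic response.

    Patients with NE radiographic status are excluded.  The AUC equals
    the normalized Mann–Whitney statistic; the CI is DeLong-style by
    default or a seeded percentile bootstrap.
    """
    merged = depth_table.merge(
        patients[["patient_id", bor_column]], on="patient_id")
    nonresp = {"recist_bor": {"SD", "PD"},
               "irecist_bor": {"iSD", "iPD"}}[bor_column]
    merged = merged[merged[bor_column].isin(responder_set | nonresp)]
    labels = merged[bor_column].isin(responder_set).to_numpy(int)
    scores = merged["d"].to_numpy(float)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both responder classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    if ci_method == "delong":
        from scipy.stats import norm
        se = float(np.sqrt(_delong_variance(scores, labels, auc)))
        z = float(norm.ppf(1 - (1 - level) / 2))
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(len(scores))
        draws = []
        for _ in range(n_boot):
            b = rng.choice(idx, size=len(idx), replace=True)
            if labels[b].sum() in (0, len(b)):
                continue
            draws.append(mann_whitney_auc(scores[b], labels[b]))
        alpha = 1 - level
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                    ci_lower=float(max(0.0, lo)),
                    ci_upper=float(min(1.0, hi)),
                    n_positive=int(labels.sum()),
                    n_negative=int(len(labels) - labels.sum()),
                    ci_method=ci_method)
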