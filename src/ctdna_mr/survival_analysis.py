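"""Time-to-event analysis for the molecular-response cohort.

Kaplan–Meier product-limit estimation (Greenwood variance, log-log
median CIs), log-rank comparison and Cox proportional-hazards
regression (Efron ties, Wald CIs) are provided through lifelines behind
a small stable surface, together with the trial's time-to-event
conventions: times in months (1 month = 30.4375 days), medians reported
with 90% CIs and hazard ratios with 95% CIs by default, and "not
reached" propagated as an explicit state rather than a number.

Time to molecular response runs from treatment start to the collection
day of the clearance sample for mR patients and is censored at the last
liquid-biopsy draw otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

DAYS_PER_MONTH = 30.4375


@dataclass
class SurvivalCurve:
    """A Kaplan–Meier estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None            # None = not reached
    median_ci: tuple[float | None, float | None]
    level: float
    label: str = ""
    n: int = 0
    n_events: int = 0


@dataclass
class HazardEstimate:
    covariates: list[str]
    hazard_ratios: dict[str, float]
    ci: dict[str, tuple[float, float]]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    level: float
    ties_rule: str
    converged: bool
    diagnostics: str = ""


def kaplan_meier(times, events, level: float = 0.90,
                 label: str = "") -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log-log median CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter(alpha=1 - level)
    kmf.fit(times, events, label=label or "KM")
    surv = kmf.survival_function_.iloc[:, 0]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    event_table = kmf.event_table
    return SurvivalCurve(
        times=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        at_risk=event_table["at_risk"].to_numpy(float),
        median=median, median_ci=median_ci, level=level, label=label,
        n=len(times), n_events=int(events.sum()))


def median_survival(curve: SurvivalCurve) -> dict:
    """Median survival as an explicit state: reached or not."""
    return {
        "median": curve.median,
        "reached": curve.median is not None,
        "ci": curve.median_ci,
        "level": curve.level,
    }


def log_rank_test(times, events, groups) -> dict:
    """Standard O-E chi-square log-rank test across >= 2 groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise ValueError("need at least two groups")
    if not events.any():
        raise ValueError("no events; log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    return {"statistic": float(res.test_statistic),
            "p_value": float(res.p_value),
            "df": int(res.degrees_of_freedom)}


def cox_ph(times, events, covariates: pd.DataFrame,
           ties_rule: str = "efron", level: float = 0.95,
           ) -> HazardEstimate:
    """Cox proportional-hazards fit (partial likelihood, Wald CIs).

    Monotone-likelihood/complete-separation situations are returned as a
    flagged estimate with a diagnostic instead of raising.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("at least one event is required")
    df = covariates.copy().reset_index(drop=True)
    names = list(df.columns)
    constant = [c for c in names if df[c].nunique() <= 1]
    df["_T"] = times
    df["_E"] = events.astype(int)
    if constant:
        # a constant covariate carries no information: coefficient 0
        df = df.drop(columns=constant)
    fitted = [c for c in names if c not in constant]
    cph = CoxPHFitter(alpha=1 - level)
    converged, diag = True, ""
    if fitted:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(df, duration_col="_T", event_col="_E")
            except Exception as exc:   # monotone likelihood etc.
                converged, diag = False, str(exc)
    hr, ci, coef, pval = {}, {}, {}, {}
    for c in names:
        if c in constant or not converged:
            hr[c], coef[c], pval[c] = 1.0, 0.0, 1.0
            ci[c] = (np.nan, np.nan)
        else:
            s = cph.summary.loc[c]
            hr[c] = float(s["exp(coef)"])
            coef[c] = float(s["coef"])
            pval[c] = float(s["p"])
            lo_col = [k for k in cph.summary.columns
                      if k.startswith("exp(coef) lower")][0]
            hi_col = [k for k in cph.summary.columns
                      if k.startswith("exp(coef) upper")][0]
            ci[c] = (float(s[lo_col]), float(s[hi_col]))
    return HazardEstimate(covariates=names, hazard_ratios=hr, ci=ci,
                          coefficients=coef, p_values=pval, level=level,
                          ties_rule=ties_rule, converged=converged,
                          diagnostics=diag)


def build_time_to_molecular_response(calls: pd.DataFrame,
                                     samples: pd.DataFrame) -> pd.DataFrame:
    """Per-patient (time, event) for time to molecular response.

    Event at the clearance sample's collection day (in months) for mR
    patients; censoring at the last liquid-biopsy collection day
    otherwise.  Patients without collection days (or not evaluable) are
    excluded with a notice column.
    """
    plasma = samples[(samples["compartment"] == "plasma")
                     & samples["available"]]
    if "collection_day" not in plasma.columns:
        raise ValueError("samples table lacks collection_day")
    rows = []
    for row in calls.itertuples():
        mine = plasma[plasma["patient_id"] == row.patient_id]
        if row.status == "not_evaluable" or mine.empty:
            continue
        days = mine.dropna(subset=["collection_day"])
        if len(days) < len(mine):
            rows.append((row.patient_id, np.nan, False,
                         "missing_collection_day"))
            continue
        if row.status == "mR":
            day = days.loc[days["timepoint"] == row.clearance_timepoint,
                           "collection_day"]
            if day.empty:
                rows.append((row.patient_id, np.nan, False,
                             "missing_collection_day"))
                continue
            rows.append((row.patient_id,
                         float(day.iloc[0]) / DAYS_PER_MONTH, True, ""))
        else:
            rows.append((row.patient_id,
                         float(days["collection_day"].max())
                         / DAYS_PER_MONTH, False, ""))
    df = pd.DataFrame(rows, columns=["patient_id", "months", "event",
                                     "notice"])
    return df[df["notice"] == ""].drop(columns="notice").reset_index(
        drop=True)


def survival_by_response(patients: pd.DataFrame, calls: pd.DataFrame,
                         endpoint: str = "os",
                         level: float = 0.90) -> dict:
    """KM per molecular-response stratum (mR vs mPD) for PFS or OS."""
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    merged = patients.merge(calls[["patient_id", "status"]], on="patient_id")
    out = {}
    for status in ("mR", "mPD"):
        grp = merged[merged["status"] == status]
        if grp.empty:
            continue
        curve = kaplan_meier(grp[tcol], grp[ecol], level=level,
                             label=status)
        out[status] = median_survival(curve) | {"n": curve.n,
                                                "n_events": curve.n_events}
    both = merged[merged["status"].isin(["mR", "mPD"])]
    if both["status"].nunique() == 2 and both[ecol].any():
        out["log_rank"] = log_rank_test(both[tcol], both[ecol],
                                        both["status"])
    return out
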