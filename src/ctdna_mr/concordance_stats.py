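"""Exact binomial statistics and molecular/radiographic concordance.

Sensitivity is the fraction of radiographic responders (best overall
response CR/PR, or iCR/iPR under iRECIST) called molecular responders;
specificity is the fraction of non-responders (SD/PD) called mPD.  Both
are estimated with exact (Clopper–Pearson) binomial confidence intervals
from beta-distribution quantiles; the lower endpoint of the two-sided
90% interval is the one-sided 95% lower confidence bound used as the
trial success criterion (> 50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (IRECIST_NONRESPONDER, IRECIST_RESPONDER,
                        RECIST_NONRESPONDER, RECIST_RESPONDER)


@dataclass
class BinomialCI:
    """An exact two-sided confidence interval for a binomial proportion."""

    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.k / self.n


@dataclass
class ConcordanceTable:
    """2x2 counts of molecular vs radiographic response.

    a = mR & responder, b = mPD & responder,
    c = mR & non-responder, d = mPD & non-responder.
    """

    a: int
    b: int
    c: int
    d: int
    criterion: str = "RECIST"

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def clopper_pearson_interval(k: int, n: int,
                             level: float = 0.90) -> BinomialCI:
    """Exact binomial CI via the beta-quantile identity.

    The lower endpoint solves P(Bin(n, p) >= k) = (1 - level)/2, i.e.
    Beta(k, n - k + 1).ppf(alpha/2); the upper endpoint is the analogous
    Beta(k + 1, n - k) quantile.  Endpoints clamp to 0 at k = 0 and to 1
    at k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1,
                                                    n - k))
    return BinomialCI(k=k, n=n, level=level, lower=lower, upper=upper)


def exact_binomial_test(k: int, n: int, p0: float,
                        sidedness: str = "two-sided") -> float:
    """Exact binomial test of H0: p = p0.

    ``sidedness`` is ``"two-sided"`` (minimum-likelihood rule: sum the
    probabilities of all outcomes no more likely than the observed one),
    ``"central"`` (twice the smaller tail, capped at 1), ``"lower"``
    (P(X <= k)) or ``"upper"`` (P(X >= k)).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if sidedness == "central":
        return float(min(1.0, 2 * min(stats.binom.cdf(k, n, p0),
                                      stats.binom.sf(k - 1, n, p0))))
    alt = {"two-sided": "two-sided", "lower": "less",
           "upper": "greater"}.get(sidedness)
    if alt is None:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(stats.binomtest(k, n, p0, alternative=alt).pvalue)


def build_concordance_table(calls: pd.DataFrame, patients: pd.DataFrame,
                            criterion: str = "RECIST") -> ConcordanceTable:
    """Cross-tabulate molecular response against radiographic BOR.

    Only patients with molecular status mR/mPD and a non-NE radiographic
    best overall response enter the table.
    """
    criterion = criterion.upper().replace("IRECIST", "iRECIST")
    if criterion == "RECIST":
        col, resp, nonresp = "recist_bor", RECIST_RESPONDER, \
            RECIST_NONRESPONDER
    elif criterion == "iRECIST":
        col, resp, nonresp = "irecist_bor", IRECIST_RESPONDER, \
            IRECIST_NONRESPONDER
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    merged = calls.merge(patients[["patient_id", col]], on="patient_id")
    merged = merged[merged["status"].isin(["mR", "mPD"])]
    is_resp = merged[col].isin(resp)
    is_nonresp = merged[col].isin(nonresp)
    is_mr = merged["status"] == "mR"
    return ConcordanceTable(
        a=int((is_mr & is_resp).sum()),
        b=int((~is_mr & is_resp).sum()),
        c=int((is_mr & is_nonresp).sum()),
        d=int((~is_mr & is_nonresp).sum()),
        criterion=criterion,
    )


def concordance_performance(table: ConcordanceTable,
                            level: float = 0.90) -> dict:
    """Sensitivity and specificity with exact CIs.

    Each statistic is reported absent (None) when its margin is empty.
    The ``*_lower_bound`` entries are the one-sided lower confidence
    bounds at (1 - level)/2 — at the default level, one-sided 95% bounds.
    """
    out: dict = {"criterion": table.criterion, "level": level,
                 "table": {"a": table.a, "b": table.b,
                           "c": table.c, "d": table.d}}
    if table.a + table.b >= 1:
        ci = clopper_pearson_interval(table.a, table.a + table.b, level)
        out["sensitivity"] = ci.estimate
        out["sensitivity_ci"] = ci
        out["sensitivity_lower_bound"] = ci.lower
    else:
        out["sensitivity"] = out["sensitivity_ci"] = None
        out["sensitivity_lower_bound"] = None
    if table.c + table.d >= 1:
        ci = clopper_pearson_interval(table.d, table.c + table.d, level)
        out["specificity"] = ci.estimate
        out["specificity_ci"] = ci
        out["specificity_lower_bound"] = ci.lower
    else:
        out["specificity"] = out["specificity_ci"] = None
        out["specificity_lower_bound"] = None
    return out


def subgroup_concordance_by_baseline_maf(calls: pd.DataFrame,
                                         patients: pd.DataFrame,
                                         thresholds=(0.03, 0.04),
                                         criterion: str = "RECIST",
                                         level: float = 0.90,
                                         ) -> pd.DataFrame:
    """Concordance performance stratified by baseline maxMAF.

    For each threshold t, patients are split into baseline maxMAF < t
    and >= t strata and sensitivity/specificity computed per stratum.
    ``calls`` must carry the ``max_maf_C1D1`` column produced by
    :func:`ctdna_mr.tumor_load_response.call_cohort_responses`.
    """
    rows = []
    for t in thresholds:
        for name, mask in (("lt", calls["max_maf_C1D1"] < t),
                           ("ge", calls["max_maf_C1D1"] >= t)):
            stratum = calls[mask & calls["max_maf_C1D1"].notna()]
            table = build_concordance_table(stratum, patients, criterion)
            perf = concordance_performance(table, level)
            rows.append({
                "threshold": t, "stratum": name, "n": table.n,
                "sensitivity": perf["sensitivity"],
                "specificity": perf["specificity"],
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            })
    return pd.DataFrame(rows)


def min_responders_for_bound(assumed_rate: float, level: float = 0.90,
                             bound: float = 0.50,
                             max_n: int = 10_000) -> int:
    """Smallest number of responders guaranteeing the CI lower bound.

    For each n, take k as the smallest integer with k/n >= assumed_rate
    (the least favorable count consistent with the assumed sensitivity)
    and ask whether the exact two-sided CI's lower endpoint exceeds
    ``bound``.  Used for the design statement that 18 responders suffice
    when sensitivity is at least 70% and the bound is 50%.
    """
    if bound <= 0:
        return 1
    if not bound < assumed_rate <= 1:
        raise ValueError("assumed_rate must lie in (bound, 1]")
    for n in range(1, max_n + 1):
        k = int(np.ceil(assumed_rate * n - 1e-12))
        if clopper_pearson_interval(k, n, level).lower > bound:
            return n
    raise RuntimeError(f"no n <= {max_n} attains the bound")
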