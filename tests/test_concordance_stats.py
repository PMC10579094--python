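import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from ctdna_mr import (build_concordance_table, clopper_pearson_interval,
                      concordance_performance, exact_binomial_test,
                      min_responders_for_bound,
                      subgroup_concordance_by_baseline_maf)


def cp_lower_by_tail_root(k, n, level):
    """Independent oracle: lower endpoint solves P(Bin(n,p) >= k) = a/2
    by direct binomial tail summation and root finding."""
    alpha = (1 - level) / 2
    if k == 0:
        return 0.0

    def tail(p):
        ks = np.arange(k, n + 1)
        return stats.binom.pmf(ks, n, p).sum() - alpha

    return brentq(tail, 1e-12, 1 - 1e-12, xtol=1e-12)


def cp_upper_by_tail_root(k, n, level):
    alpha = (1 - level) / 2
    if k == n:
        return 1.0

    def tail(p):
        ks = np.arange(0, k + 1)
        return stats.binom.pmf(ks, n, p).sum() - alpha

    return brentq(tail, 1e-12, 1 - 1e-12, xtol=1e-12)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(15, 35), (9, 11), (0, 10), (10, 10),
                                     (1, 50), (18, 24), (13, 18)])
    def test_matches_binomial_tail_root_oracle(self, k, n):
        ci = clopper_pearson_interval(k, n, 0.90)
        assert ci.lower == pytest.approx(cp_lower_by_tail_root(k, n, 0.90),
                                         abs=1e-9)
        assert ci.upper == pytest.approx(cp_upper_by_tail_root(k, n, 0.90),
                                         abs=1e-9)

    def test_contains_point_estimate_and_clamps(self):
        for k, n in [(0, 10), (3, 7), (10, 10)]:
            ci = clopper_pearson_interval(k, n, 0.90)
            assert ci.lower <= k / n <= ci.upper
        assert clopper_pearson_interval(0, 10, 0.90).lower == 0.0
        assert clopper_pearson_interval(10, 10, 0.90).upper == 1.0

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = []
        for n in (10, 40, 160, 640):
            ci = clopper_pearson_interval(int(0.3 * n), n, 0.90)
            widths.append(ci.upper - ci.lower)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_empirical_coverage_is_conservative(self):
        # exact intervals cover at or above the nominal level
        n, level, reps = 40, 0.90, 10_000
        lowers = np.array([clopper_pearson_interval(k, n, level).lower
                           for k in range(n + 1)])
        uppers = np.array([clopper_pearson_interval(k, n, level).upper
                           for k in range(n + 1)])
        rng = np.random.default_rng(0)
        for p in np.arange(0.1, 0.95, 0.2):
            ks = rng.binomial(n, p, size=reps)
            coverage = np.mean((lowers[ks] <= p) & (p <= uppers[ks]))
            assert coverage >= level - 0.01

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clopper_pearson_interval(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson_interval(5, 3)


class TestExactBinomialTest:
    @staticmethod
    def enum_two_sided(k, n, p0):
        pm = stats.binom.pmf(np.arange(n + 1), n, p0)
        return float(pm[pm <= pm[k] * (1 + 1e-10)].sum())

    @pytest.mark.parametrize("k,n,p0", [(16, 50, 0.45), (10, 45, 0.20),
                                        (3, 10, 0.5), (0, 12, 0.3)])
    def test_two_sided_matches_enumeration_oracle(self, k, n, p0):
        assert exact_binomial_test(k, n, p0) == pytest.approx(
            self.enum_two_sided(k, n, p0), rel=1e-9)

    def test_lower_tail_matches_summation(self):
        expected = stats.binom.pmf(np.arange(17), 50, 0.45).sum()
        assert exact_binomial_test(16, 50, 0.45, "lower") == \
            pytest.approx(float(expected), rel=1e-12)

    def test_observed_at_the_null_mode_is_not_significant(self):
        assert exact_binomial_test(20, 100, 0.2) > 0.9
        # two-sided test at p0 = k/n never rejects at the 5% level
        for k, n in [(3, 10), (15, 35), (9, 11)]:
            assert exact_binomial_test(k, n, k / n) > 0.05

    def test_central_rule_doubles_the_smaller_tail(self):
        expected = 2 * min(stats.binom.cdf(10, 45, 0.2),
                           stats.binom.sf(9, 45, 0.2))
        assert exact_binomial_test(10, 45, 0.2, "central") == \
            pytest.approx(float(expected), rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            exact_binomial_test(5, 10, 0.0)
        with pytest.raises(ValueError):
            exact_binomial_test(5, 10, 0.5, "sideways")


def trial_like_calls_and_patients():
    """35 evaluable patients reproducing the trial's 2x2 tables:
    RECIST (9,2,6,18) and iRECIST (10,2,5,18) via one SD->iPR upgrade."""
    rows = []
    specs = (
        [("mR", "PR", "iPR")] * 9 + [("mPD", "PR", "iPR")] * 2
        + [("mR", "SD", "iPR")] * 1 + [("mR", "SD", "iSD")] * 1
        + [("mR", "PD", "iPD")] * 4 + [("mPD", "SD", "iSD")] * 8
        + [("mPD", "PD", "iPD")] * 10
    )
    for i, (status, recist, irecist) in enumerate(specs):
        rows.append({"patient_id": f"P{i}", "status": status,
                     "recist_bor": recist, "irecist_bor": irecist,
                     "max_maf_C1D1": 0.05 if i % 3 else 0.01})
    df = pd.DataFrame(rows)
    calls = df[["patient_id", "status", "max_maf_C1D1"]]
    patients = df[["patient_id", "recist_bor", "irecist_bor"]]
    return calls, patients


class TestConcordanceTables:
    def test_trial_counts_recist(self):
        calls, patients = trial_like_calls_and_patients()
        t = build_concordance_table(calls, patients, "RECIST")
        assert (t.a, t.b, t.c, t.d) == (9, 2, 6, 18)

    def test_trial_counts_irecist(self):
        calls, patients = trial_like_calls_and_patients()
        t = build_concordance_table(calls, patients, "iRECIST")
        assert (t.a, t.b, t.c, t.d) == (10, 2, 5, 18)

    def test_ne_and_non_evaluable_patients_are_excluded(self):
        calls, patients = trial_like_calls_and_patients()
        extra_c = pd.DataFrame([
            {"patient_id": "X1", "status": "undetectable",
             "max_maf_C1D1": 0.0},
            {"patient_id": "X2", "status": "mR", "max_maf_C1D1": 0.1}])
        extra_p = pd.DataFrame([
            {"patient_id": "X1", "recist_bor": "PR", "irecist_bor": "iPR"},
            {"patient_id": "X2", "recist_bor": "NE", "irecist_bor": "NE"}])
        t = build_concordance_table(
            pd.concat([calls, extra_c], ignore_index=True),
            pd.concat([patients, extra_p], ignore_index=True), "RECIST")
        assert t.n == 35

    def test_unknown_criterion(self):
        calls, patients = trial_like_calls_and_patients()
        with pytest.raises(ValueError):
            build_concordance_table(calls, patients, "WHO")

    def test_order_invariance(self):
        calls, patients = trial_like_calls_and_patients()
        shuffled = calls.sample(frac=1, random_state=3)
        t1 = build_concordance_table(calls, patients, "RECIST")
        t2 = build_concordance_table(shuffled, patients, "RECIST")
        assert (t1.a, t1.b, t1.c, t1.d) == (t2.a, t2.b, t2.c, t2.d)


class TestPerformance:
    def test_sensitivity_specificity_with_intervals(self):
        calls, patients = trial_like_calls_and_patients()
        table = build_concordance_table(calls, patients, "RECIST")
        perf = concordance_performance(table)
        assert perf["sensitivity"] * 100 == pytest.approx(81.8, abs=0.05)
        assert perf["specificity"] * 100 == pytest.approx(75.0, abs=0.05)
        # one-sided 95% lower bounds exceed the 50% success criterion
        assert perf["sensitivity_lower_bound"] > 0.50
        assert perf["specificity_lower_bound"] > 0.50

    def test_degenerate_table_is_perfect(self):
        from ctdna_mr.concordance_stats import ConcordanceTable
        perf = concordance_performance(ConcordanceTable(5, 0, 0, 7))
        assert perf["sensitivity"] == 1.0
        assert perf["specificity"] == 1.0

    def test_empty_margin_reports_absent(self):
        from ctdna_mr.concordance_stats import ConcordanceTable
        perf = concordance_performance(ConcordanceTable(0, 0, 3, 7))
        assert perf["sensitivity"] is None
        assert perf["specificity"] is not None


class TestSubgroups:
    def test_single_stratum_threshold_matches_unstratified(self):
        calls, patients = trial_like_calls_and_patients()
        table = build_concordance_table(calls, patients, "RECIST")
        perf = concordance_performance(table)
        strata = subgroup_concordance_by_baseline_maf(
            calls, patients, thresholds=(1e-9,))
        ge = strata[strata["stratum"] == "ge"].iloc[0]
        assert ge["sensitivity"] == pytest.approx(perf["sensitivity"])
        assert ge["specificity"] == pytest.approx(perf["specificity"])
        assert strata[strata["stratum"] == "lt"].iloc[0]["n"] == 0

    def test_two_known_strata(self):
        calls, patients = trial_like_calls_and_patients()
        strata = subgroup_concordance_by_baseline_maf(
            calls, patients, thresholds=(0.03,))
        lo = strata[strata["stratum"] == "lt"].iloc[0]
        hi = strata[strata["stratum"] == "ge"].iloc[0]
        # strata partition the evaluable set
        assert lo["n"] + hi["n"] == 35
        for row in (lo, hi):
            assert row["sensitivity"] == pytest.approx(
                row["a"] / (row["a"] + row["b"]))

    def test_default_threshold_list_yields_four_rows(self):
        calls, patients = trial_like_calls_and_patients()
        strata = subgroup_concordance_by_baseline_maf(calls, patients)
        assert len(strata) == 4


class TestDesignBound:
    def test_eighteen_responders_meet_the_design_claim(self):
        # 13/18 (the least favorable count at 70% sensitivity) has a
        # two-sided 90% CI lower bound above 50% ...
        assert clopper_pearson_interval(13, 18, 0.90).lower > 0.50
        # ... whereas 5 responders cannot reach it
        assert clopper_pearson_interval(4, 5, 0.90).lower < 0.50

    def test_smallest_sufficient_n_is_consistent(self):
        n_min = min_responders_for_bound(0.70, 0.90, 0.50)
        assert n_min <= 18
        k = int(np.ceil(0.70 * n_min))
        assert clopper_pearson_interval(k, n_min, 0.90).lower > 0.50

    def test_trivial_and_invalid_bounds(self):
        assert min_responders_for_bound(0.7, 0.9, 0.0) == 1
        with pytest.raises(ValueError):
            min_responders_for_bound(0.4, 0.9, 0.5)
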