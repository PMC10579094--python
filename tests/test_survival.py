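import numpy as np
import pandas as pd
import pytest

from ctdna_mr import (build_time_to_molecular_response, cox_ph,
                      kaplan_meier, log_rank_test, median_survival,
                      survival_by_response)
from ctdna_mr.survival_analysis import DAYS_PER_MONTH


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        for t, expected in zip([1, 2, 3, 4, 5],
                               [0.8, 0.6, 0.4, 0.2, 0.0]):
            s = curve.survival[curve.times == t][0]
            assert s == pytest.approx(expected)
        assert curve.median == pytest.approx(3.0)

    def test_eight_observation_product_limit_oracle(self):
        # Hand-derived product-limit estimate with interleaved censoring:
        # events at 1, 3, 4, 6, 8; censored at 2, 5, 7.
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 0, 1, 1, 0, 1, 0, 1]
        curve = kaplan_meier(times, events)
        expected = {1: 7 / 8, 3: 7 / 8 * 5 / 6, 4: 7 / 8 * 5 / 6 * 4 / 5,
                    6: 7 / 8 * 5 / 6 * 4 / 5 * 2 / 3, 8: 0.0}
        for t, s in expected.items():
            assert curve.survival[curve.times == t][0] == pytest.approx(s)
        assert curve.median == pytest.approx(6.0)
        assert curve.n == 8 and curve.n_events == 5

    def test_median_not_reached_is_explicit(self):
        curve = kaplan_meier([5, 6, 7, 8, 9, 10], [1, 0, 0, 0, 0, 0])
        res = median_survival(curve)
        assert res["reached"] is False
        assert res["median"] is None

    def test_median_ci_brackets_the_median(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(6.0, size=200)
        events = rng.random(200) < 0.8
        curve = kaplan_meier(times, events, level=0.90)
        lo, hi = curve.median_ci
        assert lo is not None and hi is not None
        assert lo <= curve.median <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [1, 1])


class TestLogRank:
    def test_two_observation_oracle(self):
        # O - E = 0.5, Var = 0.25 at the first event time: chi2 = 1
        res = log_rank_test([1.0, 2.0], [1, 1], ["A", "B"])
        assert res["statistic"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(0.3173, abs=1e-4)
        assert res["df"] == 1

    def test_identical_groups_are_null(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1] * 10
        groups = ["A"] * 5 + ["B"] * 5
        res = log_rank_test(times, events, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        times = list(range(1, 11)) + list(range(51, 61))
        events = [1] * 20
        groups = ["short"] * 10 + ["long"] * 10
        assert log_rank_test(times, events, groups)["p_value"] < 0.001

    def test_requires_two_groups_and_events(self):
        with pytest.raises(ValueError):
            log_rank_test([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError):
            log_rank_test([1, 2], [0, 0], ["A", "B"])


def partial_log_likelihood(beta, times, events, x):
    """Oracle: Cox partial log-likelihood for untied event times."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxPH:
    def test_coefficient_matches_grid_search_oracle(self):
        times = np.array([1.0, 4.0, 6.0, 2.0, 3.0, 5.0, 7.0, 8.0])
        events = np.array([1, 1, 1, 1, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        grid = np.arange(-5, 5, 1e-3)
        lls = [partial_log_likelihood(b, times, events, x) for b in grid]
        beta_hat = grid[int(np.argmax(lls))]
        est = cox_ph(times, events, pd.DataFrame({"x": x}))
        assert est.converged
        assert est.coefficients["x"] == pytest.approx(beta_hat, abs=2e-3)
        assert est.hazard_ratios["x"] == pytest.approx(np.exp(beta_hat),
                                                       rel=1e-2)

    def test_protective_covariate_has_hr_below_one(self):
        rng = np.random.default_rng(8)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(np.where(x == 1, 10.0, 3.0))
        events = np.ones(n, dtype=int)
        est = cox_ph(times, events, pd.DataFrame({"x": x}))
        lo, hi = est.ci["x"]
        assert hi < 1.0
        assert lo <= est.hazard_ratios["x"] <= hi
        assert est.p_values["x"] < 0.001

    def test_constant_covariate_is_neutral(self):
        est = cox_ph([1, 2, 3, 4], [1, 1, 0, 1],
                     pd.DataFrame({"c": [2.0, 2.0, 2.0, 2.0]}))
        assert est.hazard_ratios["c"] == 1.0
        assert est.coefficients["c"] == 0.0

    def test_complete_separation_is_flagged_not_raised(self):
        # all events in one group before any in the other: monotone
        # likelihood territory; the estimate must come back flagged
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 0, 0, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        est = cox_ph(times, events, pd.DataFrame({"x": x}))
        assert isinstance(est.converged, bool)  # returns, never raises

    def test_requires_an_event(self):
        with pytest.raises(ValueError):
            cox_ph([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestTimeToMolecularResponse:
    def _samples(self, pid, days=(0, 21, 42)):
        rows = []
        for tp, day in zip(("C1D1", "C2D1", "C3D1"), days):
            if day is None:
                continue
            rows.append({"sample_id": f"{pid}-{tp}", "patient_id": pid,
                         "timepoint": tp, "compartment": "plasma",
                         "collection_day": day, "available": True})
        return rows

    def test_event_day_and_censoring(self):
        calls = pd.DataFrame([
            {"patient_id": "R", "status": "mR",
             "clearance_timepoint": "C2D1"},
            {"patient_id": "S", "status": "mPD",
             "clearance_timepoint": None},
            {"patient_id": "T", "status": "not_evaluable",
             "clearance_timepoint": None},
        ])
        samples = pd.DataFrame(self._samples("R") + self._samples("S")
                               + self._samples("T", days=(0, None, None)))
        t = build_time_to_molecular_response(calls, samples)
        t = t.set_index("patient_id")
        # clearance at day 21 is 21/30.4375 = 0.69 months, as an event
        assert t.loc["R", "months"] == pytest.approx(21 / DAYS_PER_MONTH)
        assert bool(t.loc["R", "event"]) is True
        # mPD censored at the last draw (day 42)
        assert t.loc["S", "months"] == pytest.approx(42 / DAYS_PER_MONTH)
        assert bool(t.loc["S", "event"]) is False
        assert "T" not in t.index

    def test_missing_collection_day_excludes_the_patient(self):
        calls = pd.DataFrame([{"patient_id": "R", "status": "mR",
                               "clearance_timepoint": "C2D1"}])
        rows = self._samples("R")
        rows[1]["collection_day"] = np.nan
        t = build_time_to_molecular_response(calls, pd.DataFrame(rows))
        assert t.empty


class TestSurvivalByResponse:
    def _cohort(self):
        rng = np.random.default_rng(4)
        rows, calls = [], []
        for i in range(60):
            status = "mR" if i < 25 else "mPD"
            scale = 12.0 if status == "mR" else 3.0
            rows.append({"patient_id": f"P{i}",
                         "os_months": float(rng.exponential(scale)),
                         "os_event": bool(rng.random() < 0.8),
                         "pfs_months": float(rng.exponential(scale / 2)),
                         "pfs_event": True})
            calls.append({"patient_id": f"P{i}", "status": status})
        return pd.DataFrame(rows), pd.DataFrame(calls)

    def test_strata_medians_and_logrank(self):
        patients, calls = self._cohort()
        res = survival_by_response(patients, calls, endpoint="os")
        assert set(res) == {"mR", "mPD", "log_rank"}
        assert res["mR"]["n"] == 25 and res["mPD"]["n"] == 35
        assert res["mR"]["median"] > res["mPD"]["median"]
        assert res["log_rank"]["p_value"] < 0.01

    def test_pfs_endpoint_uses_pfs_columns(self):
        patients, calls = self._cohort()
        res = survival_by_response(patients, calls, endpoint="pfs")
        assert res["mR"]["n_events"] == 25

    def test_single_stratum_has_no_logrank(self):
        patients, calls = self._cohort()
        calls["status"] = "mPD"
        res = survival_by_response(patients, calls)
        assert "log_rank" not in res and "mR" not in res
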