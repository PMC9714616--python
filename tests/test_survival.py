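"""Kaplan–Meier and log-rank: hand values, oracle agreement, calibration."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

import riskscreen as rs
from conftest import make_records


class TestKM:
    def test_hand_product_limit_all_events(self):
        km = rs.km_estimator(make_records([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_hand_product_limit_with_censoring(self):
        km = rs.km_estimator(make_records([1, 2, 3], [0, 1, 1]))
        np.testing.assert_allclose(km.event_times, [2, 3])
        np.testing.assert_allclose(km.survival, [1 / 2, 0.0], atol=1e-12)

    def test_all_censored_curve_is_one(self):
        km = rs.km_estimator(make_records([1, 2, 3], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            rs.km_estimator([])

    def test_monotone_and_bounded(self, planted_world):
        km = rs.km_estimator(planted_world["survival"])
        assert np.all(np.diff(km.survival) <= 0)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) <= 0)
        assert km.survival_at(0.0) == 1.0

    def test_tie_convention_events_first(self):
        # subject censored at t=2 is still at risk for the t=2 event
        km = rs.km_estimator(make_records([2, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        times = rng.exponential(10, n).round(3) + 0.001
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        km = rs.km_estimator(make_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        ours = [km.survival_at(t) for t in km.event_times]
        ref = [float(kmf.survival_function_at_times(t).iloc[0])
               for t in km.event_times]
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        g = make_records([1, 2, 3, 4], [1, 1, 0, 1])
        res = rs.logrank_test(g, list(g))
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_toy_against_lifelines(self):
        high = make_records([1, 2, 3], [1, 1, 1])
        low = make_records([4, 5, 6], [1, 1, 1])
        res = rs.logrank_test(high, low)
        ref = lifelines_logrank([1, 2, 3], [4, 5, 6], [1, 1, 1], [1, 1, 1])
        assert abs(res.p_value - ref.p_value) < 1e-8
        assert abs(res.chi_square - ref.test_statistic) < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_random_against_lifelines(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ta, tb = rng.exponential(5, 30), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        ea[0] = 1
        res = rs.logrank_test(make_records(ta, ea), make_records(tb, eb))
        ref = lifelines_logrank(ta, tb, ea, eb)
        assert abs(res.p_value - ref.p_value) < 1e-8

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        a = make_records(rng.exponential(5, 20), rng.integers(0, 2, 20) | 1)
        b = make_records(rng.exponential(9, 20), np.ones(20, int))
        r1, r2 = rs.logrank_test(a, b), rs.logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_no_events_errors(self):
        a = make_records([1, 2], [0, 0])
        b = make_records([3, 4], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            rs.logrank_test(a, b)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rs.logrank_test([], make_records([1], [1]))

    def test_null_pvalues_uniform(self):
        # both groups exponential(1): p-values approximately uniform
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(400):
            a = make_records(rng.exponential(1, 50), np.ones(50, int))
            b = make_records(rng.exponential(1, 50), np.ones(50, int))
            pvals.append(rs.logrank_test(a, b).p_value)
        from scipy import stats
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.06


class TestDichotomize:
    def test_median_split(self):
        recs = make_records([1] * 4, [1] * 4,
                            [{"g": v} for v in [1.0, 2.0, 3.0, 4.0]])
        high, low, cut = rs.dichotomize_by_expression(recs, "g", "median")
        assert sorted(r.expression["g"] for r in high) == [3.0, 4.0]
        assert sorted(r.expression["g"] for r in low) == [1.0, 2.0]
        assert cut == 2.5

    def test_tied_values_split_two_two(self):
        recs = make_records([1] * 4, [1] * 4,
                            [{"g": v} for v in [1.0, 1.0, 2.0, 2.0]])
        high, low, cut = rs.dichotomize_by_expression(recs, "g", "median")
        assert len(high) == 2 and len(low) == 2

    def test_constant_values_error(self):
        recs = make_records([1] * 3, [1] * 3, [{"g": 2.0}] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            rs.dichotomize_by_expression(recs, "g", "median")

    def test_missing_gene_errors(self):
        recs = make_records([1], [1], [{"g": 1.0}])
        with pytest.raises(KeyError):
            rs.dichotomize_by_expression(recs, "other", "median")


class TestScreen:
    def test_planted_hazard_gene_detected(self, planted_world):
        truth = planted_world["truth"]
        records = planted_world["survival"]
        null_genes = [g for g in records[0].expression
                      if truth.direction_of(g) == "null"]
        screens = rs.screen_survival(truth.core_module + null_genes, records)
        by_gene = {s.gene: s for s in screens}
        # core genes carry correlated unit hazard coefficients: strong signal
        assert all(by_gene[g].significant for g in truth.core_module)

    def test_null_genes_reject_near_alpha(self):
        # per-gene rejection of no-hazard genes across seeds stays near alpha
        rng = np.random.default_rng(77)
        hits = total = 0
        for seed in range(40):
            p = rs.SimParams(seed=int(rng.integers(2 ** 31)), survival_n=100,
                             hazard_coef=0.0, n_null_survival=3)
            _, truth = rs.simulate_cohorts(p)
            truth.hazard_links = {g: 0.0 for g in truth.planted}
            records = rs.simulate_survival(truth, p)
            genes = list(records[0].expression)[:5]
            for s in rs.screen_survival(genes, records):
                hits += s.significant
                total += 1
        assert 0.01 < hits / total < 0.12

    def test_alpha_one_makes_everything_significant(self, planted_world):
        screens = rs.screen_survival(planted_world["truth"].core_module,
                                     planted_world["survival"], alpha=1.0)
        assert all(s.significant for s in screens)

    def test_scan_cutoff_never_less_significant_than_its_own_scan(self,
                                                                  planted_world):
        g = planted_world["truth"].core_module[0]
        records = planted_world["survival"]
        scan = rs.screen_survival([g], records, cutoff="scan")[0]
        median = rs.screen_survival([g], records, cutoff="median")[0]
        assert scan.logrank.p_value <= median.logrank.p_value + 1e-12

    def test_bad_endpoint_and_cutoff(self, planted_world):
        with pytest.raises(ValueError):
            rs.screen_survival(["g"], planted_world["survival"],
                               endpoint="PFS")
        with pytest.raises(ValueError):
            rs.screen_survival(["g"], planted_world["survival"],
                               cutoff="tertile")
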