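import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from coexsurv import (
    CoexsurvError,
    GeneProfile,
    ValidationError,
    compare_partition_survival,
    km_estimate,
    log_rank,
    split_by_expression,
)
from coexsurv.cohort import CohortPartition
from conftest import make_survival


def hand_km(times, events):
    """Manual product-limit table: independent oracle."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1 - d / n
        out.append((t, s, n, d))
    return out


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        s = make_survival([1, 2, 3, 4, 5], [0] * 5)
        km = km_estimate(s)
        assert len(km.event_times) == 0

    def test_single_event_among_five(self):
        s = make_survival([5, 6, 7, 8, 9], [1, 0, 0, 0, 0])
        km = km_estimate(s)
        assert list(km.event_times) == [5.0]
        assert km.survival[0] == pytest.approx(0.8)
        assert km.at_risk[0] == 5

    def test_worked_product_limit_example(self):
        # times 1+, 2, 3, 4+, 5: S = (1-1/4), *(1-1/3), *(1-1/1)
        s = make_survival([1, 2, 3, 4, 5], [0, 1, 1, 0, 1])
        km = km_estimate(s)
        assert list(km.event_times) == [2.0, 3.0, 5.0]
        assert km.survival == pytest.approx([0.75, 0.50, 0.0])
        assert list(km.at_risk) == [4, 3, 1]

    def test_matches_hand_product_limit_on_random_tables(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            times = rng.exponential(10, n).round(1) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            km = km_estimate(make_survival(times, events))
            expected = hand_km(times, events)
            assert len(km.event_times) == len(expected)
            for (t, s, n_at, d), kt, ks, kn, kd in zip(
                expected, km.event_times, km.survival, km.at_risk, km.n_events
            ):
                assert kt == t and kn == n_at and kd == d
                assert ks == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = rng.exponential(10, 50) + 0.01
        km = km_estimate(make_survival(times, [1] * 50))
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(1 - np.mean(times <= t), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            km_estimate(make_survival([], []))

    def test_late_censored_observation_adds_no_events_only_risk(self, rng):
        # a subject censored after the last event joins every risk set but
        # contributes no event: event times and event counts are unchanged,
        # every at-risk count grows by exactly one
        times = list(rng.exponential(10, 20) + 0.1)
        events = [1] * 15 + [0] * 5
        km1 = km_estimate(make_survival(times, events))
        km2 = km_estimate(
            make_survival(times + [max(times) + 100], events + [0],
                          ids=[f"S{i}" for i in range(21)])
        )
        assert np.array_equal(km1.event_times, km2.event_times)
        assert np.array_equal(km1.n_events, km2.n_events)
        assert np.array_equal(km1.at_risk + 1, km2.at_risk)


class TestLogRank:
    def test_duplicated_group_gives_zero_statistic(self):
        a = make_survival([3, 5, 7, 9], [1, 0, 1, 1])
        b = make_survival([3, 5, 7, 9], [1, 0, 1, 1], ids=list("WXYZ"))
        res = log_rank(a, b)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_oe_v_computation(self):
        # A: 3 (event), 5+ , 7 (event); B: 2 (event), 4 (event), 6+
        a = make_survival([3, 5, 7], [1, 0, 1], ids=["A1", "A2", "A3"])
        b = make_survival([2, 4, 6], [1, 1, 0], ids=["B1", "B2", "B3"])
        # event times 2,3,4,7: per-time (n1, n, d1)
        # t=2: n1=3, n=6, d=1(B) -> e1=0.5, v=(3/6)(3/6)(5/5)=0.25
        # t=3: n1=3, n=5, d=1(A) -> e1=0.6, v=0.6*0.4=0.24
        # t=4: n1=2, n=4, d=1(B) -> e1=0.5, v=0.25
        # t=7: n1=1, n=1, d=1(A) -> e1=1.0, v=0
        o1, e1, v = 2.0, 2.6, 0.74
        res = log_rank(a, b)
        assert res.statistic == pytest.approx((o1 - e1) ** 2 / v, abs=1e-12)

    def test_matches_lifelines_oracle_on_random_tables(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            ta = rng.exponential(10, n) + 0.01
            tb = rng.exponential(14, n) + 0.01
            ea = rng.integers(0, 2, n)
            eb = rng.integers(0, 2, n)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            a = make_survival(ta, ea, ids=[f"a{i}" for i in range(n)])
            b = make_survival(tb, eb, ids=[f"b{i}" for i in range(n)])
            res = log_rank(a, b)
            ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetric_in_group_order(self, rng):
        a = make_survival([1, 3, 5, 9], [1, 1, 0, 1])
        b = make_survival([2, 4, 6, 8], [1, 0, 1, 1], ids=list("WXYZ"))
        assert log_rank(a, b).statistic == pytest.approx(log_rank(b, a).statistic)

    def test_zero_events_rejected(self):
        a = make_survival([1, 2], [0, 0])
        b = make_survival([3, 4], [0, 0], ids=["X", "Y"])
        with pytest.raises(CoexsurvError, match="no events"):
            log_rank(a, b)


class TestSplitByExpression:
    def prof(self, values, ids=None):
        ids = ids or [f"S{i+1}" for i in range(len(values))]
        return GeneProfile("G", ids, np.asarray(values, float))

    def test_median_split_of_four_distinct_ranks(self):
        s = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        low, high = split_by_expression(self.prof([10, 20, 30, 40]), s)
        assert low.sample_ids == ["S1", "S2"]
        assert high.sample_ids == ["S3", "S4"]

    def test_constant_expression_errors(self):
        s = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(CoexsurvError, match="empty group"):
            split_by_expression(self.prof([5, 5, 5, 5]), s)

    def test_upper_quartile_cutoff_counts(self):
        s = make_survival([1] * 8, [1] * 8, ids=[f"S{i+1}" for i in range(8)])
        # distinct values, 0.75 quantile -> 6 low / 2 high
        low, high = split_by_expression(self.prof([1, 2, 3, 4, 5, 6, 7, 8]), s, cutoff=0.75)
        assert len(low) == 6 and len(high) == 2

    def test_too_few_shared_samples(self):
        s = make_survival([1, 2], [1, 1])
        with pytest.raises(CoexsurvError, match="4 shared"):
            split_by_expression(self.prof([1, 2]), s)


class TestComparePartitionSurvival:
    def test_empty_cohort2_rejected(self):
        p = CohortPartition(["S1", "S2", "S3", "S4"], [], [0.5])
        s = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(CoexsurvError, match="second cohort"):
            compare_partition_survival(p, s)

    def test_restricts_cohorts_to_survival_ids(self):
        p = CohortPartition(["S1", "S2", "S3"], ["S4", "S5", "S9"], [0.2, 0.3, 0.4, 0.5])
        s = make_survival([1, 2, 3, 4, 5], [1, 1, 1, 1, 0])
        res = compare_partition_survival(p, s)
        assert res.n_per_group == (3, 2)
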