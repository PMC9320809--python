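"""Initiation rules, latency, time budgets, mating index, progeny assay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from courtship_select.behavior import (
    ProgenyTrial,
    compare_initiation_methods,
    detect_initiation,
    impute_censored_window,
    mating_index,
    progeny_latency_test,
    summarize_trial,
)
from courtship_select.errors import (
    DegenerateStatisticsError,
    NoReferenceLatencyError,
    ValidationError,
)

sep, eng, sing, cop = "separate", "engaging", "singing", "copulating"

state_seqs = st.lists(
    st.sampled_from([sep, eng, sing, "scissoring", "circling"]),
    min_size=1,
    max_size=60,
)


class TestDetectInitiation:
    def test_first_vs_consecutive3(self, trial_factory):
        t = trial_factory([sep, sep, eng, sep, sing, sing, sing])
        assert detect_initiation(t, "first") == 2
        assert detect_initiation(t, "consecutive3") == 4

    def test_all_separate_gives_none(self, trial_factory):
        t = trial_factory([sep, sep, sep])
        assert detect_initiation(t, "first") is None
        assert detect_initiation(t, "consecutive3") is None

    def test_initiation_at_start(self, trial_factory):
        t = trial_factory([eng, eng, eng, eng])
        assert detect_initiation(t, "first") == 0
        assert detect_initiation(t, "consecutive3") == 0

    @given(states=state_seqs)
    @settings(max_examples=100, deadline=None)
    def test_consecutive3_never_earlier_than_first(self, states):
        from courtship_select.io import EthogramTrial

        t = EthogramTrial("T", states)
        a = detect_initiation(t, "first")
        b = detect_initiation(t, "consecutive3")
        if b is not None:
            assert a is not None and b >= a


class TestSummarizeTrial:
    def test_latency_and_budget(self, trial_factory):
        t = trial_factory([eng, sing, sing, sing, cop])
        s = summarize_trial(t, "consecutive3")
        assert s.initiation_index == 0
        assert s.copulation_latency_s == 40.0
        assert s.budget["engaging"] == pytest.approx(0.25)
        assert s.budget["singing"] == pytest.approx(0.75)
        assert not s.censored

    def test_all_separate_trial_is_censored_without_initiation(self, trial_factory):
        s = summarize_trial(trial_factory([sep, sep, sep]))
        assert s.initiation_index is None and s.censored and s.budget == {}

    def test_single_behavior_budget(self, trial_factory):
        s = summarize_trial(trial_factory([sing, cop]), "first")
        assert s.copulation_latency_s == 10.0
        assert s.budget["singing"] == 1.0

    def test_budget_includes_post_initiation_separate_in_denominator(self, trial_factory):
        t = trial_factory([sing, sing, sep, sing, cop])
        s = summarize_trial(t, "first")
        assert s.separate_fraction == pytest.approx(0.25)
        assert s.budget["singing"] == pytest.approx(0.75)

    def test_trailing_separate_padding_is_invariant_for_initiation(self, trial_factory):
        base = trial_factory([sep, sing, sing, sing])
        padded = trial_factory([sep, sing, sing, sing, sep, sep])
        a = summarize_trial(base, budget_window=3)
        b = summarize_trial(padded, budget_window=3)
        assert a.initiation_index == b.initiation_index
        assert a.budget == b.budget

    @given(states=state_seqs)
    @settings(max_examples=100, deadline=None)
    def test_budget_fractions_sum_to_one(self, states):
        from courtship_select.io import EthogramTrial

        s = summarize_trial(EthogramTrial("T", states))
        if s.initiation_index is not None:
            total = sum(s.budget.values()) + s.separate_fraction
            assert total == pytest.approx(1.0)


class TestCensoringWindow:
    def test_window_is_group_mean_latency(self, trial_factory):
        succ1 = trial_factory([sing] * 10 + [cop], trial_id="S1")   # 100 s
        succ2 = trial_factory([sing] * 20 + [cop], trial_id="S2")   # 200 s
        cens = trial_factory([sing] * 30, trial_id="C1")
        windows = impute_censored_window([succ1, succ2, cens])
        assert windows == {"C1": 15}  # mean 150 s = 15 timepoints

    def test_single_success(self, trial_factory):
        succ = trial_factory([sing] * 9 + [cop], trial_id="S1")  # 90 s
        cens = trial_factory([sing] * 30, trial_id="C1")
        assert impute_censored_window([succ, cens]) == {"C1": 9}

    def test_zero_successes_raise(self, trial_factory):
        with pytest.raises(NoReferenceLatencyError):
            impute_censored_window([trial_factory([sing] * 30)])

    def test_imputed_latency_flagged(self, trial_factory):
        s = summarize_trial(trial_factory([sing] * 30), budget_window=15)
        assert s.censored and s.latency_imputed
        assert s.copulation_latency_s == 150.0
        assert s.n_timepoints == 15


class TestMatingIndex:
    def test_all_mated_weight_one(self):
        assert mating_index([100, 200], 2, 2, 600) == pytest.approx(150)

    def test_censored_replaced_and_weighted(self):
        # mean(100, 600) / (1/2) = 700
        assert mating_index([100, None], 1, 2, 600) == pytest.approx(700)

    def test_zero_successes_flagged_infinite(self):
        assert math.isinf(mating_index([None] * 5, 0, 5, 600))

    def test_negative_latency_rejected(self):
        with pytest.raises(ValidationError):
            mating_index([-5], 1, 1, 600)


class TestProgenyLatency:
    @staticmethod
    def crosses(male, days, censored=False, female="Z53"):
        return [
            ProgenyTrial(f"{male}-{i}", female, male, d, censored=censored)
            for i, d in enumerate(days)
        ]

    def test_identical_groups_statistic_zero(self):
        trials = self.crosses("REF", [2, 4, 6, 8]) + self.crosses("A", [2, 4, 6, 8])
        res = progeny_latency_test(trials, "REF")
        assert res.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_logrank_matches_hand_computation(self):
        """Group A all events at day 1, group B all censored at 16 (n=5 each).

        One event time (day 1): 5 observed events in A, at-risk 5 vs 10.
        O−E = 5 − 5·(5/10) = 2.5; hypergeometric variance
        = (10·5·5·5·(10−5)) / (10²·9) = 25/36·… = 625·5/900 = 1.38889·…
        V = d·(n1/n)·(n2/n)·(n−d)/(n−1) = 5·0.5·0.5·(5/9) = 0.69444…
        Statistic = 2.5²/0.69444 = 9.0.
        """
        trials = self.crosses("REF", [1] * 5) + self.crosses("B", [16] * 5, censored=True)
        res = progeny_latency_test(trials, "REF")
        assert res.loc[0, "statistic"] == pytest.approx(9.0, rel=1e-9)

    def test_missing_group_is_error(self):
        with pytest.raises(ValidationError):
            progeny_latency_test(self.crosses("REF", [1, 2]), "REF", test_males=["B"])

    def test_all_censored_both_groups_degenerate(self):
        trials = self.crosses("REF", [16] * 3, censored=True) + self.crosses(
            "B", [16] * 3, censored=True
        )
        with pytest.raises(DegenerateStatisticsError):
            progeny_latency_test(trials, "REF")

    def test_days_out_of_window_rejected(self):
        with pytest.raises(ValidationError):
            ProgenyTrial("X", "Z53", "A", 17.0)


def test_initiation_method_discrepancy_diagnostic(trial_factory):
    # one trial with a 2-gridpoint (20 s) discrepancy, one with none
    t1 = trial_factory([sep, eng, sep, sing, sing, sing])
    t2 = trial_factory([sing, sing, sing])
    d = compare_initiation_methods([t1, t2])
    assert d["n"] == 2
    assert d["mean_abs_s"] == pytest.approx(10.0)
    assert d["max_abs_s"] == pytest.approx(20.0)
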