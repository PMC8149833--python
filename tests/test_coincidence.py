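"""Tests for coincidence matching, rate estimators and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copulse import coincidence as coin
from copulse.coincidence import (CellPulseSummary, classify_bimodal,
                                 classify_pulse_context,
                                 colocalization_snapshot, expected_by_chance,
                                 match_pulses,
                                 population_rate_chance_corrected,
                                 population_rate_frequency_controlled,
                                 single_cell_rates, summarize_cells)


class TestMatchPulses:
    def test_lag_two_is_coincident(self):
        pairs, lab2, lab4 = match_pulses([40.0], [42.0])
        assert pairs == [(0, 0)] and lab2[0] and lab4[0]

    def test_lag_above_tolerance_not_coincident(self):
        pairs, _, _ = match_pulses([40.0], [42.5])
        assert pairs == []

    def test_empty_train_zero_pairs(self):
        pairs, lab2, lab4 = match_pulses([], [10.0, 20.0])
        assert pairs == [] and lab4.sum() == 0

    def test_tiebreak_earlier_pair(self):
        # Msn2 {10, 14}, Msn4 {12}: both candidate lags are 2; the earlier
        # Msn2 pulse wins the single partner
        pairs, lab2, _ = match_pulses([10.0, 14.0], [12.0])
        assert pairs == [(0, 0)]
        assert lab2.tolist() == [True, False]

    def test_one_to_one(self):
        pairs, _, _ = match_pulses([10.0], [9.0, 11.0])
        assert len(pairs) == 1

    @given(st.lists(st.integers(0, 200), max_size=8),
           st.lists(st.integers(0, 200), max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_under_channel_swap(self, a, b):
        t2 = np.sort(np.array(a, dtype=float))
        t4 = np.sort(np.array(b, dtype=float))
        p_fwd, _, _ = match_pulses(t2, t4)
        p_rev, _, _ = match_pulses(t4, t2)
        assert {(i, j) for i, j in p_fwd} == {(j, i) for i, j in p_rev}

    def test_matched_count_bounded_by_min(self):
        pairs, _, _ = match_pulses([10.0, 12.0, 14.0], [11.0])
        assert len(pairs) <= 1


class TestSummaries:
    def test_sc_rate_formula(self):
        s = CellPulseSummary("c", n2=3, n4=1, n_coinc=1)
        assert s.sc_rate == pytest.approx(0.5)
        assert s.total == 4 and s.effective == 3

    def test_sc_rate_unit_cases(self):
        assert CellPulseSummary("c", 3, 3, 3).sc_rate == 1.0
        assert CellPulseSummary("c", 2, 2, 0).sc_rate == 0.0
        assert np.isnan(CellPulseSummary("c", 0, 0, 0).sc_rate)

    def test_single_cell_rates_excludes_empty(self):
        df = pd.DataFrame({"cell_id": ["a", "b"], "n2": [2, 0], "n4": [2, 0],
                           "n_coinc": [1, 0]})
        rates, n_excluded = single_cell_rates(df)
        assert n_excluded == 1
        assert rates.tolist() == [0.5]

    def test_summarize_cells_steady_state_filter(self):
        df = pd.DataFrame({
            "cell_id": ["a"] * 4,
            "channel": ["MSN2", "MSN4", "MSN2", "MSN4"],
            "peak_time_min": [5.0, 6.0, 100.0, 101.0],
        })
        full = summarize_cells(df)
        steady = summarize_cells(df, steady_start=50.0)
        assert full.loc[0, "n_coinc"] == 2
        assert steady.loc[0, "n_coinc"] == 1


class TestFrequencyControlled:
    def test_all_coincident(self):
        est = population_rate_frequency_controlled(
            np.ones(50, bool), np.ones(50, bool), 100, seed=1)
        assert est.mean_rate == 1.0 and (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_none_coincident(self):
        est = population_rate_frequency_controlled(
            np.zeros(50, bool), np.zeros(50, bool), 100, seed=1)
        assert est.mean_rate == 0.0

    def test_binomial_ci_width_oracle(self):
        # 50% labels, sample_size 200 per channel: CI half-width
        # ~= 1.96 * sqrt(0.25/400) ~= 0.049
        rng = np.random.default_rng(2)
        lab = rng.uniform(size=4000) < 0.5
        est = population_rate_frequency_controlled(lab, lab, 200, seed=3)
        half = (est.ci_high - est.ci_low) / 2
        assert est.mean_rate == pytest.approx(0.5, abs=0.03)
        assert half == pytest.approx(0.049, abs=0.012)

    def test_invariant_to_doubling_pool(self):
        rng = np.random.default_rng(4)
        lab2 = rng.uniform(size=500) < 0.3
        lab4 = rng.uniform(size=500) < 0.3
        e1 = population_rate_frequency_controlled(lab2, lab4, 200, seed=5)
        e2 = population_rate_frequency_controlled(np.tile(lab2, 2),
                                                  np.tile(lab4, 2), 200, seed=5)
        assert abs(e1.mean_rate - e2.mean_rate) < (e1.ci_high - e1.ci_low)

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            population_rate_frequency_controlled(np.ones(0, bool),
                                                 np.ones(5, bool), 10)


class TestChanceCorrected:
    def test_printed_formula_example(self):
        # 10 Msn4 pulses, 4-min window, 400 min total: expected 0.1
        assert expected_by_chance(10, 4.0, 400.0) == pytest.approx(0.1)

    def test_empty_msn4_train(self):
        cells = [{"t2": [10.0, 50.0], "t4": [], "obs_min": 200.0}]
        est = population_rate_chance_corrected(cells, seed=1)
        assert est.mean_rate == 0.0

    def test_zero_total_time_rejected(self):
        with pytest.raises(ValueError):
            population_rate_chance_corrected(
                [{"t2": [], "t4": [], "obs_min": 0.0}])

    def test_independent_trains_null(self):
        # independent Poisson trains: corrected rate within 2 bootstrap SE of 0
        rng = np.random.default_rng(6)
        cells = []
        T = 420.0
        for _ in range(300):
            cells.append({"t2": np.sort(rng.uniform(0, T, rng.poisson(8))),
                          "t4": np.sort(rng.uniform(0, T, rng.poisson(8))),
                          "obs_min": T})
        est = population_rate_chance_corrected(cells, seed=7)
        assert abs(est.mean_rate) <= 2 * est.se + 0.01


class TestBimodal:
    def test_mixture_recovered(self):
        rng = np.random.default_rng(8)
        rates = np.concatenate([rng.normal(0.2, 0.05, 250),
                                rng.normal(0.8, 0.05, 250)])
        thr, labels, flag = classify_bimodal(rates)
        assert flag
        assert 0.35 < thr < 0.65
        truth = np.concatenate([np.zeros(250, bool), np.ones(250, bool)])
        assert (labels == truth).mean() >= 0.95

    def test_constant_rates_unimodal(self):
        thr, labels, flag = classify_bimodal(np.full(100, 0.5))
        assert not flag and thr is None

    def test_unbalanced_mixture_weights(self):
        rng = np.random.default_rng(9)
        rates = np.concatenate([rng.normal(0.2, 0.05, 150),
                                rng.normal(0.8, 0.05, 350)])
        thr, labels, flag = classify_bimodal(rates)
        assert flag
        assert abs(labels.mean() - 0.7) <= 0.1


class TestPulseContext:
    def test_isolated_pulse_is_only(self):
        c2, c4 = classify_pulse_context([100.0], [120.0])
        assert c2[0] == "msn2_only" and c4[0] == "msn4_only"

    def test_matched_pair_is_co_pulse(self):
        c2, c4 = classify_pulse_context([100.0], [101.0])
        assert c2[0] == "co_pulse" and c4[0] == "co_pulse"

    def test_near_but_not_coincident_is_ambiguous(self):
        c2, c4 = classify_pulse_context([100.0], [105.0])
        assert c2[0] == "ambiguous" and c4[0] == "ambiguous"

    def test_boundary_of_only_window(self):
        c2, _ = classify_pulse_context([100.0], [108.0])
        assert c2[0] == "ambiguous"  # exactly 8 min away: not isolated
        c2, _ = classify_pulse_context([100.0], [108.1])
        assert c2[0] == "msn2_only"


class TestColocalization:
    def test_all_double_nuclear(self):
        est = colocalization_snapshot(40, 40, 40, sample_size=50, seed=1)
        assert est.mean_rate == 100.0

    def test_disjoint_sets(self):
        est = colocalization_snapshot(40, 40, 0, sample_size=50, seed=1)
        assert est.mean_rate == 0.0

    def test_half_overlap(self):
        est = colocalization_snapshot(100, 100, 50, sample_size=200, seed=2)
        assert est.mean_rate == pytest.approx(50.0, abs=3.0)

    def test_zero_channel_rejected(self):
        with pytest.raises(ValueError):
            colocalization_snapshot(0, 10, 0, 10)
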