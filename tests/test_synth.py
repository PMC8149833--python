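"""Tests for the ground-truthed synthetic data generator."""

import numpy as np
import pandas as pd
import pytest

from copulse import synth
from copulse.synth import (SynthConfig, generate_cell_image,
                           generate_foldchange_table, generate_pulse_trains,
                           generate_reporter, generate_survival, render_trace,
                           triangular_kernel)


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(rate_shared=-1.0)

    def test_duration_must_fit_grid(self):
        with pytest.raises(ValueError):
            SynthConfig(duration_min=421.0)  # not a multiple of 2 min

    def test_too_short_duration(self):
        with pytest.raises(ValueError):
            SynthConfig(duration_min=1.0)

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SynthConfig(mixture=[(0.5, (1, 0, 0)), (0.4, (2, 0, 0))])


class TestPulseTrains:
    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_cells=10, seed=7)
        _, t1 = generate_pulse_trains(cfg)
        _, t2 = generate_pulse_trains(cfg)
        pd.testing.assert_frame_equal(t1.events, t2.events)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_all_shared_gives_rate_one(self):
        cfg = SynthConfig(n_cells=20, rate_shared=2.0, rate_msn2_only=0.0,
                          rate_msn4_only=0.0, jitter_sd_min=0.0, seed=1)
        _, truth = generate_pulse_trains(cfg)
        pulsing = truth.cells[truth.cells["total"] > 0]
        assert (pulsing["sc_rate"] == 1.0).all()
        assert truth.events["shared"].all()

    def test_no_shared_events(self):
        cfg = SynthConfig(n_cells=20, rate_shared=0.0, seed=2)
        _, truth = generate_pulse_trains(cfg)
        assert truth.cells["n_shared"].sum() == 0
        assert not truth.events["shared"].any()

    def test_population_shared_fraction_matches_rates(self):
        # rates (3, 1.5, 1.5)/h: expected coincident fraction
        # 2*3/(2*3 + 1.5 + 1.5) = 2/3
        cfg = SynthConfig(n_cells=500, rate_shared=3.0, rate_msn2_only=1.5,
                          rate_msn4_only=1.5, seed=3)
        _, truth = generate_pulse_trains(cfg)
        frac = truth.events["shared"].mean()
        n = len(truth.events)
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(frac - 2 / 3) < 2 * se + 0.01

    def test_refractory_spacing_within_channel(self):
        cfg = SynthConfig(n_cells=30, rate_shared=3.0, rate_msn2_only=2.0,
                          rate_msn4_only=2.0, jitter_sd_min=0.0, seed=4)
        _, truth = generate_pulse_trains(cfg)
        for (_, _), grp in truth.events.groupby(["cell_id", "channel"]):
            t = np.sort(grp["time_min"].to_numpy())
            if t.size > 1:
                assert np.diff(t).min() >= cfg.refractory_min - 2 * 2.0  # jitter slack

    def test_shared_jitter_truncated_to_tolerance(self):
        cfg = SynthConfig(n_cells=50, rate_shared=2.0, rate_msn2_only=0.0,
                          rate_msn4_only=0.0, jitter_sd_min=1.5, seed=5)
        events, truth = generate_pulse_trains(cfg)
        for cid, per in events.items():
            df2 = per["MSN2"].set_index("event_id")
            df4 = per["MSN4"].set_index("event_id")
            common = df2.index.intersection(df4.index)
            lags = (df2.loc[common, "time_min"] - df4.loc[common, "time_min"]).abs()
            # each channel jittered by <=2 around the latent event
            assert (lags <= 4.0 + 1e-9).all()

    def test_mixture_components_have_distinct_rates(self):
        cfg = SynthConfig(n_cells=400, seed=6,
                          mixture=[(0.5, (0.3, 1.2, 1.2)), (0.5, (2.4, 0.3, 0.3))])
        _, truth = generate_pulse_trains(cfg)
        by_comp = truth.cells.groupby("component")["sc_rate"].mean()
        assert by_comp[0] < 0.4 < 0.6 < by_comp[1]


class TestRenderTrace:
    def test_no_events_zero_drift_zero_noise(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr = render_trace([], cfg)
        assert np.all(tr.values == 0)

    def test_kernel_definition(self):
        # one event amplitude 10, FWHM 10: max 10 at peak, 5 at +/-5 min
        cfg = SynthConfig(noise_sd=0.0, halfmax_width_min=10.0, seed=0)
        tr = render_trace([100.0], cfg, amplitudes=[10.0])
        i = np.argmax(tr.values)
        assert tr.times[i] == 100.0 and tr.values[i] == pytest.approx(10.0)
        t = np.array([95.0, 105.0])
        assert triangular_kernel(t, 100.0, 10.0, 10.0) == pytest.approx([5.0, 5.0])

    def test_superposition_of_two_events(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr = render_trace([100.0, 104.0], cfg, amplitudes=[10.0, 8.0])
        expected = (triangular_kernel(cfg.times, 100.0, 10.0, cfg.halfmax_width_min)
                    + triangular_kernel(cfg.times, 104.0, 8.0, cfg.halfmax_width_min))
        np.testing.assert_allclose(tr.values, expected)

    def test_event_outside_duration_rejected(self):
        cfg = SynthConfig(seed=0)
        with pytest.raises(ValueError):
            render_trace([1000.0], cfg)

    def test_cubic_drift_added(self):
        cfg = SynthConfig(noise_sd=0.0, drift_coeffs=(1.0, 0.01, 0.0, 0.0), seed=0)
        tr = render_trace([], cfg)
        np.testing.assert_allclose(tr.values, 1.0 + 0.01 * cfg.times)


class TestReporter:
    def _one_cell(self, cfg, kinds):
        """Construct a hand-built per-channel event dict."""
        rows2, rows4, eid = [], [], 0
        for t, kind in kinds:
            if kind in ("co", "msn2"):
                rows2.append((t, 10.0, kind == "co", eid))
            if kind in ("co", "msn4"):
                rows4.append((t, 10.0, kind == "co", eid))
            eid += 1
        cols = ["time_min", "amplitude", "shared", "event_id"]
        return {"MSN2": pd.DataFrame(rows2, columns=cols),
                "MSN4": pd.DataFrame(rows4, columns=cols)}

    def test_unknown_mode_rejected(self):
        cfg = SynthConfig(seed=0)
        with pytest.raises(ValueError):
            generate_reporter(self._one_cell(cfg, []), "bogus", cfg)

    def test_no_pulses_baseline_noise_only(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr = generate_reporter(self._one_cell(cfg, []), "saturated_or", cfg)
        assert np.all(tr.values == 0)

    def test_saturated_or_copulse_equals_only_pulse(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr_co = generate_reporter(self._one_cell(cfg, [(100.0, "co")]),
                                  "saturated_or", cfg)
        tr_only = generate_reporter(self._one_cell(cfg, [(100.0, "msn2")]),
                                    "saturated_or", cfg)
        np.testing.assert_allclose(tr_co.values, tr_only.values)

    def test_additive_copulse_doubles(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr_co = generate_reporter(self._one_cell(cfg, [(100.0, "co")]),
                                  "additive", cfg)
        tr_only = generate_reporter(self._one_cell(cfg, [(100.0, "msn4")]),
                                    "additive", cfg)
        np.testing.assert_allclose(tr_co.values, 2.0 * tr_only.values)

    def test_specific_mode_ignores_other_channel(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        tr = generate_reporter(self._one_cell(cfg, [(100.0, "msn4")]),
                               "msn2_specific", cfg)
        assert np.all(tr.values == 0)


class TestSurvival:
    def test_null_model_fraction(self):
        rng = np.random.default_rng(0)
        summaries = pd.DataFrame({"cell_id": [f"c{i}" for i in range(4000)],
                                  "effective": rng.poisson(8, 4000)})
        out = generate_survival(summaries, beta0=0.5, beta1=0.0, seed=1)
        expect = 1 / (1 + np.exp(-0.5))
        assert abs(out["survived_horizon"].mean() - expect) < 0.03

    def test_all_die_at_minus_inf(self):
        summaries = pd.DataFrame({"cell_id": ["a", "b"], "effective": [3, 5]})
        out = generate_survival(summaries, beta0=-1e9, beta1=0.0, seed=1)
        assert not out["survived_horizon"].any()
        assert out["death_time_h"].notna().all()

    def test_survival_increases_with_effective_pulses(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        eff = rng.poisson(8, 1676)
        summaries = pd.DataFrame({"cell_id": [f"c{i}" for i in range(1676)],
                                  "effective": eff})
        out = generate_survival(summaries, beta0=-1.0, beta1=0.5, seed=3)
        grouped = out.assign(eff=eff).groupby("eff")["survived_horizon"].mean()
        grouped = grouped[out.assign(eff=eff).groupby("eff").size() >= 10]
        rho, _ = spearmanr(grouped.index, grouped.values)
        assert rho > 0


class TestFoldChange:
    def test_zero_noise_redundant_triple(self):
        table, truth = generate_foldchange_table(5, 0, noise_cv=0.0, seed=1)
        vals = table[["fc_wt", "fc_msn2", "fc_msn4"]].to_numpy()
        np.testing.assert_allclose(vals[:, 0], vals[:, 1])
        np.testing.assert_allclose(vals[:, 0], vals[:, 2])
        assert (vals[:, 0] >= 1.2).all()

    def test_nonredundant_collapses_in_single_mutants(self):
        table, _ = generate_foldchange_table(0, 5, noise_cv=0.0, seed=1)
        assert (table["fc_wt"] >= 2.5).all()
        np.testing.assert_allclose(table["fc_msn2"], 1.0)
        np.testing.assert_allclose(table["fc_msn4"], 1.0)

    def test_labels_recorded(self):
        table, truth = generate_foldchange_table(3, 2, seed=2)
        assert (truth["true_label"] == "redundant").sum() == 3
        assert len(table) == 5


class TestCellImage:
    def test_zero_gain_zero_score(self):
        values, coords, score = generate_cell_image(nuclear_gain=0.0, seed=1)
        assert score == 0.0
        assert np.ptp(values) == 0

    def test_cluster_construction(self):
        values, coords, score = generate_cell_image(100, 0.1, 100.0, seed=1)
        assert score == 100.0
        assert (values > values.min()).sum() == 10

    def test_tiny_nucleus_flagged(self):
        with pytest.raises(ValueError):
            generate_cell_image(40, 0.05, 10.0, seed=1)
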