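"""Design construction, encoder fitting, nested tests, collinearity."""

import numpy as np
import pytest

import fearcond as fc
from fearcond.encoding import DesignMatrix, trial_flag_matrix


class TestBinActivity:
    def test_mean_binning(self):
        np.testing.assert_allclose(fc.bin_activity([1, 2, 3, 4], 2.0, 1.0), [1.5, 3.5])

    def test_constant_trace_unchanged(self):
        np.testing.assert_allclose(fc.bin_activity(np.full(20, 3.0), 0.5, 10.0), np.full(4, 3.0))

    def test_500ms_bins_at_10hz_pool_five_samples(self):
        out = fc.bin_activity(np.arange(50, dtype=float), 0.5, 10.0)
        assert out.size == 10
        assert out[0] == pytest.approx(np.mean(np.arange(5)))

    def test_bin_smaller_than_sample_interval_rejected(self):
        with pytest.raises(ValueError):
            fc.bin_activity([1.0, 2.0], 0.05, 10.0)


class TestDesignMatrix:
    def test_column_enumeration_six_trials(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        assert d.n_columns == 96  # 1 AR + 3 vars x 6 trials x 5 lags + 5 speed
        assert sum(lab[0] == "autoregressive" for lab in d.labels) == 1
        assert sum(lab[0] == "speed" for lab in d.labels) == 5
        for var in ("tone", "footshock", "iti"):
            assert sum(lab[0] == var for lab in d.labels) == 30

    def test_task_columns_binary_and_baseline_zero(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        n_base = int(schedule.baseline_duration / schedule.bin_width)
        for j, lab in enumerate(d.labels):
            if lab[0] in ("tone", "footshock", "iti"):
                col = d.X[:, j]
                assert set(np.unique(col)) <= {0.0, 1.0}
                assert col[: n_base].sum() == 0  # absence coded as 0 in baseline

    def test_lagged_column_shifts_indicator(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        base = schedule.indicator("footshock", trial=2)
        col = d.X[:, d.columns_of("footshock", trial=2)[3]]
        np.testing.assert_array_equal(col[3:], base[:-3])

    def test_speed_column_not_trial_split(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        assert all(lab[1] is None for lab in d.labels if lab[0] == "speed")


class TestFitEncoder:
    def test_noiseless_coefficients_recovered(self, schedule, behavior, speed_binned):
        tt = fc.GroundTruthTuning.null(5, ar_coef=0.3, noise_sd=0.0)
        tt.footshock[0] = 1.0
        tt.speed[1] = 0.5
        act = fc.simulate_population(schedule, [tt], behavior, seed=0)
        d = fc.build_design_matrix(schedule, speed_binned, act.values[0])
        fit = fc.fit_encoder(act.values[0], d)
        assert abs(fit.coefficient("autoregressive") - 0.3) < 1e-7
        assert abs(fit.coefficient("speed", lag=1) - 0.5) < 1e-7
        for n in range(1, 7):
            assert abs(fit.coefficient("footshock", trial=n, lag=0) - 1.0) < 1e-7

    def test_deterministic_shock_dependence_flagged(self, schedule, behavior, speed_binned):
        tt = fc.GroundTruthTuning.null(5, noise_sd=0.0)
        tt.footshock[0] = 1.0
        act = fc.simulate_population(schedule, [tt], behavior, seed=0)
        d = fc.build_design_matrix(schedule, speed_binned, act.values[0])
        t = fc.test_variable_encoding(act.values[0], d, "footshock")
        assert t.p_value == pytest.approx(0.0, abs=1e-12)
        assert t.significant

    def test_reduced_ev_never_exceeds_full(self, schedule, speed_binned, behavior, null_truth):
        act = fc.simulate_population(schedule, null_truth(10), behavior, seed=3)
        enc = fc.PopulationEncoder(schedule, speed_binned)
        for fit in enc.fit_matrix(act):
            assert 0.0 <= fit.r_squared <= 1.0
            for t in fit.variable_tests.values():
                assert t.ev_reduced <= t.ev_full + 1e-12

    def test_population_path_matches_single_fit(self, schedule, speed_binned, behavior, null_truth, encoder):
        act = fc.simulate_population(schedule, null_truth(3), behavior, seed=4)
        fits = encoder.fit_matrix(act)
        d = fc.build_design_matrix(schedule, speed_binned, act.values[1])
        single = fc.fit_encoder(act.values[1], d, trial_tests=True)
        for var in single.variable_tests:
            assert fits[1].variable_tests[var].p_value == pytest.approx(
                single.variable_tests[var].p_value, abs=1e-8)
        key = ("footshock", 4)
        assert fits[1].trial_tests[key].p_value == pytest.approx(
            single.trial_tests[key].p_value, abs=1e-8)

    def test_absent_variable_rejected(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        with pytest.raises(ValueError, match="not in design"):
            d.columns_of("licking")

    def test_permutation_method_agrees_on_strong_effect(self, schedule, behavior, speed_binned):
        tt = fc.GroundTruthTuning.null(5, noise_sd=0.3)
        tt.footshock[0] = 2.0
        act = fc.simulate_population(schedule, [tt], behavior, seed=0)
        d = fc.build_design_matrix(schedule, speed_binned, act.values[0])
        t = fc.test_variable_encoding(act.values[0], d, "footshock",
                                      method="permutation", n_shifts=99, seed=0)
        assert t.significant and t.p_value <= 0.05


class TestTrialEncoding:
    def test_trial_specific_tuning(self, schedule, speed_binned):
        rng = np.random.default_rng(0)
        trace = schedule.indicator("footshock", trial=1) * 3.0 + rng.normal(0, 0.1, schedule.n_bins)
        d = fc.build_design_matrix(schedule, speed_binned, trace)
        t1 = fc.test_trial_encoding(trace, d, "footshock", 1)
        t6 = fc.test_trial_encoding(trace, d, "footshock", 6)
        assert t1.significant and not t6.significant

    def test_trial_out_of_range(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.zeros(schedule.n_bins))
        with pytest.raises(ValueError, match="out of range"):
            fc.test_trial_encoding(np.zeros(schedule.n_bins), d, "footshock", 7)


class TestCollinearity:
    def _toy_design(self, X, labels):
        return DesignMatrix(X, labels, kernel_length=1, bin_width=0.5)

    def test_orthogonal_columns_unit_vif(self):
        # zero-mean sinusoids at distinct frequencies: exactly orthogonal
        t = np.arange(200)
        X = np.column_stack([np.sin(2 * np.pi * k * t / 200) for k in (1, 2, 3, 4)])
        d = self._toy_design(X, [("autoregressive", None, None), ("tone", 1, 0),
                                 ("footshock", 1, 0), ("speed", None, 0)])
        rep = fc.collinearity_diagnostics(d)
        np.testing.assert_allclose(rep.vif, 1.0, atol=1e-8)
        assert not rep.any_flag
        assert rep.condition_index >= 1.0

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        X = np.column_stack([x, x, rng.normal(size=300)])
        d = self._toy_design(X, [("autoregressive", None, None), ("tone", 1, 0), ("speed", None, 0)])
        rep = fc.collinearity_diagnostics(d)
        assert np.isinf(rep.vif[0]) and np.isinf(rep.vif[1])
        assert rep.vif_flags[0] and rep.vif_flags[1]
        assert np.isinf(rep.condition_index) and rep.condition_flag

    def test_freezing_predictor_triggers_vif_flags(self, schedule, behavior):
        # freezing coded as the complement of movement during the ITI is
        # near-collinear with the ITI indicators: the stated reason to
        # prefer speed as the continuous covariate
        iti = schedule.indicator("iti")
        rng = np.random.default_rng(3)
        freezing = iti.copy()
        flip = rng.random(iti.size) < 0.02
        freezing[flip] = 1 - freezing[flip]
        d = fc.build_design_matrix(schedule, freezing, rng.normal(size=schedule.n_bins),
                                   continuous_label="freezing")
        rep = fc.collinearity_diagnostics(d)
        freeze_cols = [j for j, lab in enumerate(d.labels) if lab[0] == "freezing"]
        assert all(rep.vif[j] > 10 or not np.isfinite(rep.vif[j]) for j in freeze_cols)
        assert rep.any_flag

    def test_eigenvalue_path_per_group(self, schedule, speed_binned):
        d = fc.build_design_matrix(schedule, speed_binned, np.arange(schedule.n_bins, dtype=float))
        rep = fc.collinearity_diagnostics(d)
        assert [g for g, _ in rep.min_eigenvalue_path] == [
            "autoregressive", "tone", "footshock", "iti", "speed"]


class TestPopulationSummaries:
    def test_reactivation_probability_cases(self):
        all_trials = np.ones((4, 6), dtype=bool)
        assert fc.reactivation_probability(all_trials) == 1.0
        only_first = np.zeros((4, 6), dtype=bool)
        only_first[:, 0] = True
        assert fc.reactivation_probability(only_first) == 0.0
        none_first = np.zeros((4, 6), dtype=bool)
        assert np.isnan(fc.reactivation_probability(none_first))

    def test_reactivation_under_independent_flags(self):
        rng = np.random.default_rng(0)
        alpha, n_trials = 0.3, 3
        flags = rng.random((20000, n_trials)) < alpha
        expect = alpha ** (n_trials - 1)
        assert fc.reactivation_probability(flags) == pytest.approx(expect, abs=0.02)

    def test_summarize_fractions_bounded(self, schedule, behavior, null_truth, encoder):
        act = fc.simulate_population(schedule, null_truth(20), behavior, seed=6)
        fits = encoder.fit_matrix(act)
        table = fc.summarize_encoders(fits, schedule, act)
        assert ((table.fraction >= 0) & (table.fraction <= 1)).all()
        assert set(table.loc[table.test == "variable", "variable"]) == {
            "tone", "footshock", "iti", "speed"}
        flags = trial_flag_matrix(fits, "footshock")
        assert flags.shape == (20, 6)

    def test_speed_tuning_monotone_neuron_prefers_top_bin(self, schedule, speed_binned):
        rng = np.random.default_rng(1)
        act = fc.ActivityMatrix(
            np.vstack([speed_binned, rng.normal(size=schedule.n_bins)]), schedule.bin_width)
        tuning = fc.speed_tuning(act, speed_binned, np.array([True, True]), n_speed_bins=5)
        assert tuning.preferred_bin[0] == tuning.curves.shape[1] - 1
        assert tuning.histogram.sum() == 2
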