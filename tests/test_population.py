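"""Baseline Z-scoring, PCC matrices, state space, classifier, KS comparisons."""

import numpy as np
import pytest

import fearcond as fc
from fearcond.population import mahalanobis_distance


class TestBaselineZscore:
    def test_standardized_neuron_unchanged(self, schedule):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, schedule.n_bins))
        n_base = int(300 / schedule.bin_width)
        x = (x - x[:, :n_base].mean()) / x[:, :n_base].std()
        z = fc.baseline_zscore(fc.ActivityMatrix(x, schedule.bin_width), 300.0)
        np.testing.assert_allclose(z.values, x, atol=1e-12)

    def test_constant_neuron_excluded(self, schedule):
        rng = np.random.default_rng(1)
        vals = np.vstack([np.ones(schedule.n_bins), rng.normal(size=schedule.n_bins)])
        z = fc.baseline_zscore(fc.ActivityMatrix(vals, schedule.bin_width, ["flat", "ok"]), 300.0)
        assert z.neuron_ids == ["ok"]

    def test_post_shock_gain_maps_to_mean_z(self, schedule):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, schedule.n_bins))
        onset = int(schedule.first_shock_onset / schedule.bin_width)
        vals[:, onset:] += 2.0  # +2 baseline-sd offset
        z = fc.baseline_zscore(fc.ActivityMatrix(vals, schedule.bin_width), 300.0)
        assert z.values[:, onset:].mean() == pytest.approx(2.0, abs=0.1)
        assert z.units_tag == "zscored"


class TestLabelEpochs:
    def test_baseline_post_dichotomy_at_first_shock(self, schedule):
        labels = fc.label_epochs(schedule)
        onset_bin = int(schedule.first_shock_onset / schedule.bin_width)
        assert labels.coarse[onset_bin] == "post"      # onset bin is post-baseline
        assert labels.coarse[onset_bin - 1] == "baseline"
        assert (labels.coarse[onset_bin:] == "post").all()

    def test_labels_partition_all_bins(self, schedule):
        labels = fc.label_epochs(schedule)
        counts = sum(np.sum(labels.fine == e) for e in
                     ("baseline", "tone", "shock", "post_shock_window", "iti"))
        assert counts == schedule.n_bins

    def test_shock_bins_inside_tone_window(self, schedule):
        labels = fc.label_epochs(schedule)
        tr = schedule.trials[0]
        shock_bins = labels.bins("shock")
        t = labels.time_axis[shock_bins[:4]]
        assert t[0] >= tr.shock_on - schedule.bin_width and t[-1] < tr.shock_off


class TestPopulationCorrelation:
    def test_symmetry_unit_diagonal_and_bounds(self):
        rng = np.random.default_rng(3)
        act = fc.ActivityMatrix(rng.normal(size=(20, 100)), 0.5, units_tag="zscored")
        M = fc.population_correlation_matrix(act).values
        np.testing.assert_array_equal(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert np.nanmax(np.abs(M)) <= 1.0 + 1e-12

    def test_duplicate_and_negated_vectors(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=10)
        act = fc.ActivityMatrix(np.column_stack([v, v, -v]), 0.5)
        M = fc.population_correlation_matrix(act).values
        assert M[0, 1] == pytest.approx(1.0)
        assert M[0, 2] == pytest.approx(-1.0)

    def test_constant_vector_masked(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 6))
        vals[:, 2] = 7.0
        M = fc.population_correlation_matrix(fc.ActivityMatrix(vals, 0.5)).values
        assert np.isnan(M[2]).all() and np.isnan(M[:, 2]).all()
        assert not np.isnan(np.delete(np.delete(M, 2, 0), 2, 1)).any()


class TestEpochMeanPcc:
    def test_identical_vectors_give_one(self):
        v = np.random.default_rng(6).normal(size=12)
        act = fc.ActivityMatrix(np.column_stack([v] * 5), 0.5)
        M = fc.population_correlation_matrix(act)
        assert fc.epoch_mean_pcc(M, np.arange(5)) == pytest.approx(1.0)

    def test_two_bin_window_uses_single_entry(self):
        rng = np.random.default_rng(7)
        act = fc.ActivityMatrix(rng.normal(size=(15, 4)), 0.5)
        M = fc.population_correlation_matrix(act)
        assert fc.epoch_mean_pcc(M, np.array([0, 1])) == pytest.approx(M.values[0, 1])

    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(8)
        act = fc.ActivityMatrix(rng.normal(size=(50, 200)), 0.5)
        M = fc.population_correlation_matrix(act)
        assert abs(fc.epoch_mean_pcc(M, np.arange(200))) < 0.02

    def test_cross_window_excludes_shared_diagonal(self):
        rng = np.random.default_rng(9)
        act = fc.ActivityMatrix(rng.normal(size=(15, 6)), 0.5)
        M = fc.population_correlation_matrix(act)
        # overlapping windows share bin 2; its unit self-correlation must not inflate the mean
        got = fc.epoch_mean_pcc(M, np.array([0, 1, 2]), np.array([2, 3]))
        manual = np.mean([M.values[i, j] for i in (0, 1, 2) for j in (2, 3) if i != j])
        assert got == pytest.approx(manual)

    def test_window_outside_session_rejected(self, schedule):
        rng = np.random.default_rng(10)
        act = fc.ActivityMatrix(rng.normal(size=(5, 20)), 0.5)
        M = fc.population_correlation_matrix(act)
        with pytest.raises(ValueError, match="outside"):
            fc.epoch_mean_pcc(M, (100.0, 200.0))


class TestCrossTrialSimilarity:
    def test_output_length(self, schedule):
        rng = np.random.default_rng(11)
        act = fc.ActivityMatrix(rng.normal(size=(20, schedule.n_bins)), schedule.bin_width)
        M = fc.population_correlation_matrix(act)
        sim = fc.cross_trial_similarity(M, schedule, epoch="shock")
        assert sim.size == schedule.n_trials - 1

    def test_trial1_transient_lowers_similarity_to_later_trials(self, schedule):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(30, schedule.n_bins))
        pattern = rng.normal(size=30) * 3
        for k, tr in enumerate(schedule.trials):
            i0 = int(tr.shock_on / schedule.bin_width)
            i1 = int(tr.shock_off / schedule.bin_width)
            add = pattern if k > 0 else -pattern  # trial 1 deviates
            vals[:, i0:i1] += add[:, None]
        M = fc.population_correlation_matrix(fc.ActivityMatrix(vals, schedule.bin_width))
        vs_first = fc.cross_trial_similarity(M, schedule, epoch="shock").mean()
        vs_second = fc.cross_trial_similarity(M, schedule, epoch="shock", reference_trial=2).mean()
        assert vs_first < vs_second


class TestStateSpace:
    def test_rank_one_data_pc1_explains_all(self):
        rng = np.random.default_rng(13)
        loading, score = rng.normal(size=30), rng.normal(size=100)
        act = fc.ActivityMatrix(np.outer(loading, score), 0.5)
        labels = fc.EpochLabels(np.arange(100) * 0.5,
                                np.array(["baseline"] * 100), np.array(["baseline"] * 100))
        res = fc.pca_state_space(act, labels)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert abs(res.pc_coordinates.mean(axis=0)).max() < 1e-10  # centered scores

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(14)
        act = fc.ActivityMatrix(rng.normal(size=(10, 50)), 0.5)
        labels = fc.EpochLabels(np.arange(50) * 0.5, np.array(["baseline"] * 50),
                                np.array(["baseline"] * 50))
        res = fc.pca_state_space(act, labels)
        for c in range(2):
            j = np.argmax(np.abs(res.loadings[:, c]))
            assert res.loadings[j, c] > 0


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self):
        assert mahalanobis_distance([0, 0], [3, 4], np.eye(2)) == pytest.approx(5.0, abs=1e-10)

    def test_diagonal_covariance_hand_case(self):
        assert mahalanobis_distance([2, 0], [0, 0], np.diag([4.0, 1.0])) == pytest.approx(1.0, abs=1e-10)

    def test_identical_centroids_give_zero(self):
        rng = np.random.default_rng(15)
        coords = rng.normal(size=(100, 2))
        labels = fc.EpochLabels(np.arange(100.0), np.array(["baseline"] * 100),
                                np.array(["baseline"] * 50 + ["post"] * 50))
        res = fc.StateSpaceResult(np.vstack([coords[:50], coords[:50]]),
                                  np.array([0.6, 0.4]), np.zeros((5, 2)), labels)
        assert fc.mahalanobis_shift(res) == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_invertible_linear_maps(self):
        rng = np.random.default_rng(16)
        coords = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(3, 2, (40, 2))])
        labels = fc.EpochLabels(np.arange(100.0), np.array(["baseline"] * 100),
                                np.array(["baseline"] * 60 + ["post"] * 40))
        base = fc.mahalanobis_shift(fc.StateSpaceResult(coords, np.ones(2) / 2, np.zeros((5, 2)), labels))
        for _ in range(5):
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(2, 2))
            d = fc.mahalanobis_shift(
                fc.StateSpaceResult(coords @ A.T, np.ones(2) / 2, np.zeros((5, 2)), labels))
            assert d == pytest.approx(base, abs=1e-8)


class TestClassifier:
    def _labels(self, n0, n1):
        return np.array(["baseline"] * n0 + ["post"] * n1)

    def test_separated_clusters_high_accuracy(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (120, 2))])
        res = fc.state_space_classifier(X, self._labels(100, 120), seed=0)
        assert res.mean_accuracy >= 0.95
        assert res.iterations == 10 and res.accuracies.size == 10
        assert ((res.accuracies >= 0) & (res.accuracies <= 1)).all()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (150, 2))])
        y = rng.permutation(self._labels(100, 150))
        res = fc.state_space_classifier(X, y, seed=1)
        assert abs(res.mean_accuracy - res.chance_level) <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fc.state_space_classifier(np.zeros((30, 2)), np.array(["baseline"] * 30))

    def test_kfold_mode(self):
        rng = np.random.default_rng(19)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(5, 1, (50, 2))])
        res = fc.state_space_classifier(X, self._labels(50, 50), mode="kfold", seed=0)
        assert res.mode == "kfold" and res.mean_accuracy > 0.9


class TestDistributionComparison:
    def test_identical_groups_zero_statistic(self):
        x = np.random.default_rng(20).normal(size=50)
        ks, p = fc.compare_distributions(x, x)
        assert ks == 0.0 and p == pytest.approx(1.0)

    def test_narrowed_distribution_detected(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            wide = rng.normal(0, 1, 200)
            narrow = rng.normal(0, 0.5, 200)  # variance 0.25: narrowed phenotype
            _, p = fc.compare_distributions(wide, narrow)
            rejections += p < 0.05
        assert rejections >= 95

    def test_statistic_bounded(self):
        rng = np.random.default_rng(21)
        ks, _ = fc.compare_distributions(rng.normal(size=30), rng.normal(3, 1, 40))
        assert 0.0 <= ks <= 1.0

    def test_epoch_means_per_cell(self, schedule):
        rng = np.random.default_rng(22)
        act = fc.ActivityMatrix(rng.normal(size=(8, schedule.n_bins)), schedule.bin_width,
                                units_tag="zscored")
        labels = fc.label_epochs(schedule)
        vals = fc.epoch_z_distribution(act, labels, "tone")
        assert vals.shape == (8,)
        with pytest.raises(ValueError):
            fc.epoch_z_distribution(act, labels, "nonexistent_epoch")
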