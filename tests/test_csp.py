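"""CSP filter extraction, log-variance features and Fisher LDA."""

import numpy as np
import pytest

from mipredict import (class_covariances, classify_accuracy, csp_features,
                       csp_filters, flda_train)
from mipredict.csp import (ClassCovariances, LDAModel, SpatialFilterBank,
                           classify, trial_covariances)
from mipredict.preprocess import EpochSet

from conftest import make_noise_epochs


def covs_from_diag(left, right):
    return ClassCovariances(cov_left=np.diag(left).astype(float),
                            cov_right=np.diag(right).astype(float),
                            n_trials_per_class={"left": 10, "right": 10})


class TestClassCovariances:
    def test_identical_trials_give_identical_covariances(self):
        ep = make_noise_epochs(n_trials=8, seed=1)
        ep.epochs[ep.labels == "right"] = ep.epochs[ep.labels == "left"]
        covs = class_covariances(ep)
        np.testing.assert_allclose(covs.cov_left, covs.cov_right, atol=1e-12)

    def test_white_noise_covariance_near_scaled_identity(self):
        # trace-normalized average of many iid white-noise trials -> I/n_ch
        ep = make_noise_epochs(n_trials=400, n_channels=4, n_samples=256,
                               seed=2)
        covs = class_covariances(ep)
        np.testing.assert_allclose(covs.cov_left, np.eye(4) / 4, atol=0.004)
        assert np.trace(covs.cov_left) == pytest.approx(1.0)

    def test_single_trial_class_rejected(self):
        ep = make_noise_epochs(n_trials=6, seed=3)
        ep = ep.select(np.array([0, 1, 2, 3, 4]))  # drops one 'right' trial->2
        ep.labels[:4] = "left"
        with pytest.raises(ValueError, match="right"):
            class_covariances(ep)

    def test_single_channel_rejected(self):
        ep = make_noise_epochs(n_trials=8, n_channels=1, seed=4)
        with pytest.raises(ValueError, match="channels"):
            class_covariances(ep)


class TestCspFilters:
    def test_closed_form_eigenvalues_on_diagonal_covariances(self):
        covs = covs_from_diag([4, 1, 1, 1], [1, 4, 1, 1])
        bank = csp_filters(covs, m=2)
        # lambda = 4/(4+1) and 1/(1+4)
        np.testing.assert_allclose(bank.eigenvalues, [0.8, 0.2], atol=1e-12)
        # the two filters select channels 1 and 2
        assert np.argmax(np.abs(bank.filters[0])) == 0
        assert np.argmax(np.abs(bank.filters[1])) == 1

    def test_equal_covariances_give_half_eigenvalues(self):
        covs = covs_from_diag([2, 1, 3, 1], [2, 1, 3, 1])
        bank = csp_filters(covs, m=4)
        np.testing.assert_allclose(bank.eigenvalues, 0.5, atol=1e-12)

    def test_composite_normalization_invariants(self):
        ep = make_noise_epochs(n_trials=60, n_channels=6, n_samples=128,
                               seed=5)
        covs = class_covariances(ep)
        bank = csp_filters(covs, m=4)
        W = bank.filters
        comp = covs.cov_left + covs.cov_right
        np.testing.assert_allclose(W @ comp @ W.T, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(np.diag(W @ covs.cov_left @ W.T),
                                   bank.eigenvalues, atol=1e-10)

    def test_swapping_classes_mirrors_eigenvalues(self):
        ep = make_noise_epochs(n_trials=60, n_channels=6, n_samples=128,
                               seed=6)
        covs = class_covariances(ep)
        swapped = ClassCovariances(cov_left=covs.cov_right,
                                   cov_right=covs.cov_left,
                                   n_trials_per_class=covs.n_trials_per_class)
        a = csp_filters(covs, m=4).eigenvalues
        b = csp_filters(swapped, m=4).eigenvalues
        np.testing.assert_allclose(np.sort(a), np.sort(1.0 - b), atol=1e-10)

    def test_invariance_to_common_linear_mixing(self):
        # remixing both classes by one invertible matrix must not change
        # eigenvalues nor the extracted features
        ep = make_noise_epochs(n_trials=40, n_channels=4, n_samples=128,
                               seed=7)
        ep.epochs[ep.labels == "left", 0] *= 2.0  # plant class structure
        rng = np.random.default_rng(8)
        A = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
        mixed = EpochSet(epochs=np.einsum("cd,idt->ict", A, ep.epochs),
                         labels=ep.labels, run_index=ep.run_index,
                         sampling_rate=ep.sampling_rate)
        # pooled covariances: the invariance is exact (per-trial trace
        # normalization transforms each trial differently under mixing)
        bank_orig = csp_filters(class_covariances(ep, "pooled"), m=2)
        bank_mix = csp_filters(class_covariances(mixed, "pooled"), m=2)
        np.testing.assert_allclose(bank_orig.eigenvalues,
                                   bank_mix.eigenvalues, atol=1e-8)
        f_orig = csp_features(ep, bank_orig)
        f_mix = csp_features(mixed, bank_mix)
        np.testing.assert_allclose(f_orig, f_mix, atol=1e-7)

    def test_recovers_planted_topography(self, strong_subject_epochs):
        # with spatially white background, the most discriminative filter
        # should align with the lateralized source topography
        from mipredict.simulate import default_topographies
        topo_l, topo_r = default_topographies(
            strong_subject_epochs.n_channels)
        bank = csp_filters(class_covariances(strong_subject_epochs), m=10)
        extremes = np.vstack([bank.filters[0], bank.filters[-1]])
        best = max(
            abs(np.corrcoef(w, t)[0, 1])
            for w in extremes for t in (topo_l, topo_r))
        assert best > 0.9

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError, match="even"):
            csp_filters(covs_from_diag([1, 2], [2, 1]), m=3)

    def test_m_larger_than_channels_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            csp_filters(covs_from_diag([1, 2], [2, 1]), m=4)

    def test_singular_composite_suggests_ridge(self):
        z = np.zeros((3, 3))
        z[0, 0] = 1.0
        covs = ClassCovariances(cov_left=z, cov_right=z,
                                n_trials_per_class={"left": 5, "right": 5})
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            csp_filters(covs, m=2)
        bank = csp_filters(covs, m=2, ridge=1e-6)  # regularized path works
        assert bank.filters.shape == (2, 3)

    def test_json_round_trip(self):
        bank = csp_filters(covs_from_diag([4, 1, 1, 1], [1, 4, 1, 1]), m=2)
        back = SpatialFilterBank.from_json_dict(bank.to_json_dict())
        np.testing.assert_allclose(back.filters, bank.filters)
        np.testing.assert_allclose(back.eigenvalues, bank.eigenvalues)


class TestCspFeatures:
    def test_scaling_shifts_log_variance(self):
        ep = make_noise_epochs(n_trials=12, seed=9)
        bank = csp_filters(class_covariances(ep), m=2)
        feats = csp_features(ep, bank)
        scaled = EpochSet(epochs=ep.epochs * 3.0, labels=ep.labels,
                          run_index=ep.run_index,
                          sampling_rate=ep.sampling_rate)
        np.testing.assert_allclose(csp_features(scaled, bank),
                                   feats + 2.0 * np.log(3.0), atol=1e-10)

    def test_feature_length_is_m(self):
        ep = make_noise_epochs(n_trials=12, n_channels=6, seed=10)
        bank = csp_filters(class_covariances(ep), m=4)
        assert csp_features(ep, bank).shape == (12, 4)

    def test_strong_erd_features_separate_classes(self, strong_subject_epochs):
        bank = csp_filters(class_covariances(strong_subject_epochs), m=10)
        feats = csp_features(strong_subject_epochs, bank)
        labels = strong_subject_epochs.labels
        for j in (0, -1):  # the two most discriminative filters
            a, b = feats[labels == "left", j], feats[labels == "right", j]
            pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            assert abs(a.mean() - b.mean()) > pooled_sd

    def test_channel_mismatch_rejected(self):
        ep = make_noise_epochs(n_trials=12, n_channels=6, seed=11)
        bank = csp_filters(class_covariances(
            make_noise_epochs(n_trials=12, n_channels=4, seed=11)), m=2)
        with pytest.raises(ValueError, match="channels"):
            csp_features(ep, bank)


class TestFlda:
    def test_separable_1d_perfect_training_accuracy(self):
        feats = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        labels = np.array(["left", "left", "right", "right"])
        model = flda_train(feats, labels)
        assert classify_accuracy(model, feats, labels) == 1.0

    def test_identical_class_means_flagged_degenerate(self):
        rng = np.random.default_rng(12)
        feats = rng.standard_normal((20, 2))
        labels = np.array(["left", "right"] * 10)
        feats[labels == "right"] = feats[labels == "left"]  # same means
        with pytest.raises(ValueError, match="degenerate"):
            flda_train(feats, labels)

    def test_weights_match_brute_force_scatter_solve(self):
        # independent oracle: explicit loops for scatter and matrix inverse
        rng = np.random.default_rng(13)
        feats = rng.standard_normal((30, 2))
        labels = np.array(["left"] * 15 + ["right"] * 15)
        feats[:15] += [1.0, 0.5]
        mu_l = feats[:15].mean(axis=0)
        mu_r = feats[15:].mean(axis=0)
        Sw = np.zeros((2, 2))
        for x, mu in [(x, mu_l) for x in feats[:15]] + \
                     [(x, mu_r) for x in feats[15:]]:
            d = (x - mu)[:, None]
            Sw += d @ d.T
        expected = np.linalg.inv(Sw) @ (mu_l - mu_r)
        model = flda_train(feats, labels)
        cos = model.weights @ expected / (
            np.linalg.norm(model.weights) * np.linalg.norm(expected))
        assert cos == pytest.approx(1.0, abs=1e-10)
        # midpoint threshold: projected class-mean midpoint scores zero
        mid = (mu_l + mu_r) / 2
        assert model.weights @ mid - model.bias == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_one_class_rejected(self):
        feats = np.zeros((4, 2))
        with pytest.raises(ValueError, match="left|right"):
            flda_train(feats, np.array(["left"] * 4))


class TestClassifyAccuracy:
    def test_printed_definition_three_of_four(self):
        model = LDAModel(weights=np.array([1.0]), bias=0.0)
        feats = np.array([[1.0], [2.0], [-1.0], [3.0]])
        # predictions: left, left, right, left -> 3 of 4 correct
        labels = np.array(["left", "left", "right", "right"])
        assert classify_accuracy(model, feats, labels) == 0.75

    def test_matches_per_trial_brute_force(self):
        rng = np.random.default_rng(14)
        for trial in range(10):
            m = rng.integers(1, 4)
            n = rng.integers(1, 17)
            model = LDAModel(weights=rng.standard_normal(m) + 0.1,
                             bias=float(rng.standard_normal()))
            feats = rng.standard_normal((n, m))
            labels = np.array([("left", "right")[i] for i in
                               rng.integers(0, 2, n)])
            correct = 0
            for x, lab in zip(feats, labels):
                score = float(np.dot(model.weights, x)) - model.bias
                pred = "left" if score >= 0 else "right"
                correct += pred == lab
            assert classify_accuracy(model, feats, labels) == correct / n

    def test_boundary_tie_goes_to_first_class(self):
        model = LDAModel(weights=np.array([1.0]), bias=0.0)
        assert classify(model, np.array([[0.0]]))[0] == "left"

    def test_empty_features_rejected(self):
        model = LDAModel(weights=np.array([1.0]), bias=0.0)
        with pytest.raises(ValueError, match="empty"):
            classify_accuracy(model, np.empty((0, 1)), np.array([]))
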