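"""RBF network components: k-means, sigma, activations, NLMS, threshold."""

import numpy as np
import pytest

from veinflow.features import build_features, feature_matrix, fit_standardizer
from veinflow.rbfnn import (RBFNNModel, compute_sigma, fit, forward,
                            kmeans_centers, nlms_update, rbf_activations,
                            select_threshold, train_weights_nlms)


class TestKMeans:
    def test_k1_center_is_mean(self, rng):
        X = rng.normal(size=(25, 4))
        c = kmeans_centers(X, 1, seed=0)
        assert np.allclose(c[0], X.mean(axis=0))

    def test_k_equals_n_fixed_point(self, rng):
        X = rng.normal(size=(6, 3))
        c = kmeans_centers(X, 6, seed=1)
        assert np.allclose(np.sort(c, axis=0), np.sort(X, axis=0))

    def test_two_blobs_recovered(self, rng):
        a = rng.normal([0, 0], 0.3, size=(60, 2))
        b = rng.normal([5, 5], 0.3, size=(60, 2))
        X = np.vstack([a, b])
        c = np.sort(kmeans_centers(X, 2, seed=3), axis=0)
        se = 0.3 / np.sqrt(60)
        assert np.all(np.abs(c[0] - a.mean(axis=0)) < 3 * se + 1e-9)
        assert np.all(np.abs(c[1] - b.mean(axis=0)) < 3 * se + 1e-9)

    def test_matches_reference_implementation_on_blobs(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        a = rng.normal([0, 0, 0], 0.5, size=(40, 3))
        b = rng.normal([4, 4, 4], 0.5, size=(40, 3))
        X = np.vstack([a, b])
        ours = np.sort(kmeans_centers(X, 2, seed=0), axis=0)
        ref = sklearn.KMeans(2, n_init=10, random_state=0).fit(X)
        theirs = np.sort(ref.cluster_centers_, axis=0)
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_k_above_distinct_points_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_centers(X, 2, seed=0)

    def test_centers_within_bounding_box(self, rng):
        X = rng.normal(size=(40, 5))
        c = kmeans_centers(X, 7, seed=2)
        assert np.all(c >= X.min(axis=0) - 1e-12)
        assert np.all(c <= X.max(axis=0) + 1e-12)


class TestSigma:
    def test_standardized_features_give_unit_sigma(self, rng):
        X = rng.normal(size=(30, 6))
        Z = fit_standardizer(X).transform(X)
        assert compute_sigma(Z) == pytest.approx(1.0, rel=1e-9)

    def test_one_dimensional_pair(self):
        assert compute_sigma(np.array([[-1.0], [1.0]])) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(2.0, 3.0, size=(17, 4))
        expected = np.sqrt(np.mean(
            np.linalg.norm(X - X.mean(axis=0), axis=1) ** 2) / 4)
        assert compute_sigma(X) == pytest.approx(expected, rel=1e-12)

    def test_identical_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_sigma(np.ones((5, 3)))


class TestActivations:
    def test_unity_at_center(self):
        mu = np.array([[1.0, 2.0]])
        phi = rbf_activations(np.array([1.0, 2.0]), mu, sigma=0.7)
        assert phi[0] == pytest.approx(1.0)

    def test_e_minus_one_at_sigma_sqrt2(self):
        sigma = 1.3
        mu = np.zeros((1, 3))
        x = np.array([sigma * np.sqrt(2), 0.0, 0.0])
        phi = rbf_activations(x, mu, sigma)
        assert phi[0] == pytest.approx(np.exp(-1), rel=1e-12)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(9, 4))
        mu = rng.normal(size=(5, 4))
        sigma = 0.9
        phi = rbf_activations(X, mu, sigma)
        for i in range(9):
            for j in range(5):
                d2 = np.sum((X[i] - mu[j]) ** 2)
                assert phi[i, j] == pytest.approx(
                    np.exp(-d2 / (2 * sigma ** 2)), rel=1e-12)

    def test_bounds_and_monotonicity(self):
        mu = np.zeros((1, 1))
        dists = np.linspace(0, 10, 50)[:, None]
        phi = rbf_activations(dists, mu, sigma=1.0)[:, 0]
        assert np.all(phi > 0) and np.all(phi <= 1)
        assert np.all(np.diff(phi) < 0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            rbf_activations(np.array([np.nan, 0.0]), np.zeros((1, 2)), 1.0)


class TestNLMS:
    def test_zero_targets_keep_zero_weights(self, rng):
        Phi = rng.random((10, 4))
        w, trace = train_weights_nlms(Phi, np.zeros(10), seed=0)
        assert np.all(w == 0.0)
        assert trace[-1] == 0.0

    def test_single_step_algebra(self):
        w, _ = train_weights_nlms(np.array([[1.0]]), np.array([1.0]),
                                  eta=1.0, epochs=1, seed=0)
        assert w[0] == pytest.approx(1.0 / (1.0 + 1e-6), rel=1e-12)

    def test_eta_out_of_stability_region_rejected(self):
        Phi = np.ones((3, 2))
        for eta in (0.0, 2.0, -0.5, 2.5):
            with pytest.raises(ValueError):
                train_weights_nlms(Phi, np.ones(3), eta=eta)

    def test_a_posteriori_error_never_exceeds_a_priori(self, rng):
        """NLMS contraction property for eta in (0, 2)."""
        for eta in (0.1, 0.5, 1.0, 1.9):
            w = rng.normal(size=6)
            for _ in range(50):
                phi = rng.normal(size=6)
                d = rng.normal()
                before = abs(d - w @ phi)
                w2 = nlms_update(w, phi, d, eta)
                after = abs(d - w2 @ phi)
                assert after <= before + 1e-12
                w = w2

    def test_converges_to_least_squares_optimum(self, rng):
        """Cycling NLMS approaches the normal-equations MSE on 41 x 16."""
        Phi = rng.random((41, 16))
        d = rng.random(41)
        w, trace = train_weights_nlms(Phi, d, eta=0.5, epochs=500, seed=7)
        w_ls, *_ = np.linalg.lstsq(Phi, d, rcond=None)
        mse_ls = np.mean((d - Phi @ w_ls) ** 2)
        assert trace[-1] <= 1.05 * mse_ls

    def test_mse_trend_non_increasing_on_separable_data(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, size=(20, 1)),
                       rng.normal(2, 0.3, size=(20, 1))])
        d = np.repeat([0.0, 1.0], 20)
        Phi = rbf_activations(X, np.array([[-2.0], [2.0]]), 1.0)
        _, trace = train_weights_nlms(Phi, d, eta=0.5, epochs=50, seed=0)
        assert trace[-1] <= trace[0]


class TestThreshold:
    def test_separable_scores(self):
        thr, f = select_threshold(np.array([0.1, 0.2, 0.8, 0.9]),
                                  np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.20)
        assert f == pytest.approx(1.0)

    def test_identical_scores_degenerate_case(self):
        labels = np.array([1, 1, 1, 0, 0])
        thr, f = select_threshold(np.full(5, 0.4), labels)
        prevalence = 3 / 5
        assert f == pytest.approx(2 * prevalence / (1 + prevalence))
        assert thr == 0.0

    def test_matches_exhaustive_sweep_oracle(self, rng):
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            thr, f = select_threshold(scores, labels)
            best = -1.0
            for g in np.round(np.arange(101) / 100, 2):
                pred = scores > g
                tp = np.sum(pred & (labels == 1))
                fp = np.sum(pred & (labels == 0))
                fn = np.sum(~pred & (labels == 1))
                fg = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
                best = max(best, fg)
            assert f == pytest.approx(best, rel=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestFit:
    def test_forward_trivial_cases(self):
        model = RBFNNModel(centers=np.zeros((1, 2)), sigma=1.0,
                           weights=np.array([2.0]), threshold=0.5)
        assert forward(model, np.zeros((1, 2)))[0] == pytest.approx(2.0)
        model.weights = np.array([0.0])
        assert np.all(forward(model, np.ones((3, 2))) == 0.0)

    def test_forward_matches_summation_oracle(self, rng):
        model = RBFNNModel(centers=rng.normal(size=(4, 3)), sigma=1.2,
                           weights=rng.normal(size=4), threshold=0.5)
        X = rng.normal(size=(6, 3))
        phi = rbf_activations(X, model.centers, model.sigma)
        assert np.allclose(forward(model, X), phi @ model.weights)

    def test_fit_on_default_cohort_reaches_high_f(self, truth_cohort):
        feats, _ = build_features(truth_cohort.truth_table(),
                                  truth_cohort.labels())
        X, d = feature_matrix(feats)
        Z = fit_standardizer(X).transform(X)
        model = fit(Z, d, k=16, seed=0)
        assert model.metadata["train_f_measure"] >= 0.9

    def test_interpolation_regime(self, rng):
        """k = n centers can drive the training error to ~0, F to 1."""
        X = np.vstack([rng.normal(-1, 0.5, size=(20, 2)),
                       rng.normal(1, 0.5, size=(21, 2))])
        d = np.r_[np.zeros(20, int), np.ones(21, int)]
        model = fit(X, d, k=41, epochs=2000, seed=0, threshold="sweep")
        assert model.metadata["final_mse"] < 0.01
        assert model.metadata["train_f_measure"] == pytest.approx(1.0)

    def test_fit_determinism(self, truth_cohort):
        feats, _ = build_features(truth_cohort.truth_table(),
                                  truth_cohort.labels())
        X, d = feature_matrix(feats)
        Z = fit_standardizer(X).transform(X)
        m1 = fit(Z, d, k=16, seed=5)
        m2 = fit(Z, d, k=16, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(30, 6))
        d = (X[:, 0] > 0).astype(int)
        model = fit(X, d, k=4, seed=1, threshold=0.5)
        clone = RBFNNModel.from_json(model.to_json())
        assert np.allclose(clone.predict(X), model.predict(X))
        assert clone.threshold == model.threshold

    def test_per_center_sigma_option(self, rng):
        X = rng.normal(size=(30, 2))
        d = (X[:, 0] > 0).astype(int)
        model = fit(X, d, k=4, seed=1, per_center_sigma=True)
        assert np.ndim(model.sigma) == 1
        assert np.all(np.asarray(model.sigma) > 0)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit(X, np.ones(10, int), k=2)
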