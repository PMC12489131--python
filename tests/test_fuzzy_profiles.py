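import numpy as np
import pandas as pd
import pytest

import fuzzyprofiles as fp
from fuzzyprofiles.fuzzy_profiles import mahalanobis_distances


def brute_force_memberships(X, centroids, covariances, m):
    """Direct per-element evaluation of u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))."""
    X = np.atleast_2d(X)
    k = len(centroids)
    u = np.zeros((len(X), k))
    for a, x in enumerate(X):
        d = np.array([
            np.sqrt((x - c) @ np.linalg.inv(S) @ (x - c))
            for c, S in zip(centroids, covariances)
        ])
        if np.any(d == 0):
            u[a] = (d == 0) / (d == 0).sum()
            continue
        for i in range(k):
            u[a, i] = 1.0 / np.sum((d[i] / d) ** (2.0 / (m - 1.0)))
    return u


class TestFitFCM:
    def test_k1_centroid_is_sample_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        model, U = fp.fit_fcm(X, 1, seed=0, n_init=2)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(U.u, 1.0)

    def test_mirrored_data_gives_mirrored_centroids(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(100, 6)) + np.r_[5, np.zeros(5)]
        X = np.vstack([half, -half])
        model, _ = fp.fit_fcm(X, 2, seed=1, n_init=4, tol=1e-10)
        assert np.linalg.norm(model.centroids[0] + model.centroids[1]) < 1e-5

    def test_two_tight_clusters_recovered(self):
        """Centroids land within 0.05 of the cluster means (reference AO run)."""
        rng = np.random.default_rng(2)
        a = rng.normal(scale=0.1, size=(100, 6)) + np.r_[5.0, np.zeros(5)]
        b = rng.normal(scale=0.1, size=(100, 6)) - np.r_[5.0, np.zeros(5)]
        X = np.vstack([a, b])
        model, _ = fp.fit_fcm(X, 2, m=2.0, seed=2, tol=1e-12, n_init=4)
        means = np.vstack([a.mean(axis=0), b.mean(axis=0)])
        d = min(np.linalg.norm(model.centroids - means),
                np.linalg.norm(model.centroids[::-1] - means))
        assert d < 0.05

    def test_k_not_smaller_than_n_rejected(self):
        X = np.random.default_rng(3).normal(size=(5, 6))
        with pytest.raises(ValueError, match="smaller"):
            fp.fit_fcm(X, 5, seed=0)

    def test_identical_points_rejected(self):
        X = np.ones((20, 6))
        with pytest.raises(ValueError, match="identical"):
            fp.fit_fcm(X, 2, seed=0)

    def test_membership_rows_sum_to_one(self, fitted_model):
        _, U = fitted_model
        np.testing.assert_allclose(U.u.sum(axis=1), 1.0, atol=1e-9)

    def test_hard_assignment_limit_small_m(self):
        """As m -> 1+ on well-separated data, memberships approach hard labels."""
        rng = np.random.default_rng(4)
        C = np.zeros((4, 6))
        C[0, 0] = C[1, 1] = C[2, 2] = 6.0
        lab = rng.choice(4, 400)
        X = C[lab] + rng.normal(size=(400, 6))
        _, U = fp.fit_fcm(X, 4, m=1.05, seed=4, n_init=4)
        assert np.median(U.u.max(axis=1)) >= 0.99


class TestFuzzyCovariance:
    def test_uniform_weights_give_mle_covariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6))
        c = X.mean(axis=0, keepdims=True)
        U = np.ones((200, 1))
        (cov,) = fp.fuzzy_covariance(X, U, c, m=2.0)
        expected = np.cov(X.T, bias=True)
        np.testing.assert_allclose(cov, expected, atol=1e-4)

    def test_two_point_hand_example(self):
        X = np.zeros((2, 6))
        X[0, 0], X[1, 0] = 1.0, -1.0
        c = np.zeros((1, 6))
        U = np.ones((2, 1))
        (cov,) = fp.fuzzy_covariance(X, U, c, m=2.0)
        expected = np.diag([1.0, 0, 0, 0, 0, 0])
        eps = 1e-6 * 1.0 / 6
        np.testing.assert_allclose(cov, expected + eps * np.eye(6), atol=1e-12)

    def test_always_positive_definite(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 6))
        X[:, 3] = 0.0  # rank-deficient direction
        U = rng.dirichlet(np.ones(3), size=30)
        covs = fp.fuzzy_covariance(X, U, rng.normal(size=(3, 6)), m=2.0)
        for cov in covs:
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_vanishing_weight_rejected(self):
        X = np.random.default_rng(7).normal(size=(10, 6))
        U = np.ones((10, 2))
        U[:, 1] = 0.0
        with pytest.raises(ValueError, match="weight"):
            fp.fuzzy_covariance(X, U / U.sum(1, keepdims=True), np.zeros((2, 6)), 2.0)


def toy_model(k=4, p=6, m=2.0, seed=8):
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(k, p)) * 2
    covs = []
    for _ in range(k):
        A = rng.normal(size=(p, p)) * 0.3
        covs.append(A @ A.T + np.eye(p))
    return fp.ProfileModel(centroids=centroids, covariances=covs, fuzzifier=m)


class TestMemberships:
    def test_point_at_centroid_gets_indicator_row(self):
        model = toy_model()
        U = fp.compute_memberships(model.centroids[[1]], model)
        np.testing.assert_allclose(U.u[0], [0, 1, 0, 0], atol=0)

    def test_equidistant_point_gets_uniform_row(self):
        # identity covariances, centroids at unit vectors: origin is equidistant
        centroids = np.eye(4, 6) * 3.0
        covs = [np.eye(6)] * 4
        model = fp.ProfileModel(centroids=centroids, covariances=covs, fuzzifier=2.0)
        U = fp.compute_memberships(np.zeros((1, 6)), model)
        np.testing.assert_allclose(U.u[0], 0.25, atol=1e-12)

    def test_hand_computed_two_profile_example(self):
        """d = (1, 3), m = 2 -> u = (1/(1+(1/3)^2) = 0.9, 0.1)."""
        centroids = np.zeros((2, 6))
        centroids[1, 0] = 4.0
        covs = [np.eye(6)] * 2
        model = fp.ProfileModel(centroids=centroids, covariances=covs, fuzzifier=2.0)
        x = np.zeros((1, 6))
        x[0, 0] = 1.0
        U = fp.compute_memberships(x, model)
        np.testing.assert_allclose(U.u[0], [0.9, 0.1], atol=1e-12)

    def test_matches_brute_force_on_random_probes(self):
        model = toy_model(seed=9)
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 6)) * 3
        U = fp.compute_memberships(X, model)
        expected = brute_force_memberships(X, model.centroids, model.covariances,
                                           model.fuzzifier)
        np.testing.assert_allclose(U.u, expected, atol=1e-10)

    def test_non_finite_feature_rejected(self):
        model = toy_model()
        X = np.zeros((2, 6))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="row"):
            fp.compute_memberships(X, model)


class TestPredict:
    def test_training_set_prediction_is_idempotent(self, fitted_model,
                                                   standardized_features):
        model, U = fitted_model
        U2 = fp.predict_memberships(standardized_features, model)
        np.testing.assert_array_equal(U.u, U2.u)

    def test_single_row_valid(self, fitted_model, standardized_features):
        model, _ = fitted_model
        U = fp.predict_memberships(standardized_features.iloc[[0]], model)
        assert U.u.shape == (1, 4)
        assert U.u.sum() == pytest.approx(1.0, abs=1e-9)

    def test_feature_name_mismatch_reported(self, fitted_model,
                                            standardized_features):
        model, _ = fitted_model
        bad = standardized_features.rename(columns={"stress": "STRESS"})
        with pytest.raises(ValueError, match="STRESS"):
            fp.predict_memberships(bad, model)

    def test_held_out_subjects_map_to_their_planted_profile(self):
        spec = fp.SyntheticSpec(n_per_cohort={"DISC": 800}, seed=21)
        tables, truth = fp.generate(spec)
        X = tables[0].features
        mu, sd = X.mean(), X.std(ddof=0)
        Xs = (X - mu) / sd
        model, _ = fp.fit_fcm(Xs.iloc[:600], 4, seed=3, n_init=4)
        held = Xs.iloc[600:]
        held_truth = truth.labels["profile"].to_numpy()[600:]
        U = fp.predict_memberships(held, model)
        res = fp.truth_compare(model.centroids, None, truth,
                               true_centroids=spec.standardized_centroids())
        mapping = res["mapping"]  # fitted profile -> planted profile
        for planted in range(4):
            rows = held_truth == planted
            mean_u = U.u[rows].mean(axis=0)
            assert mapping[int(mean_u.argmax())] == planted


class TestSelectK:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 6))
        k, table = fp.select_k(X, [2], seed=0, n_init=2)
        assert k == 2
        assert len(table) == 1 and np.isfinite(table["silhouette"]).all()

    def test_planted_four_clusters_selected(self):
        rng = np.random.default_rng(12)
        C = np.zeros((4, 6))
        C[0, 0] = C[1, 1] = C[2, 2] = 6.0
        lab = rng.choice(4, 600)
        X = C[lab] + rng.normal(size=(600, 6))
        k, _ = fp.select_k(X, range(2, 7), seed=1, n_init=2, tol=1e-4)
        assert k == 4


class TestLabelProfiles:
    def make_model(self, centroid):
        other = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])  # filler: MC/HSIE, never collides
        centroids = np.vstack([centroid, other])
        return fp.ProfileModel(centroids=centroids, covariances=[np.eye(6)] * 2,
                               fuzzifier=2.0)

    @pytest.mark.parametrize("centroid,expected", [
        ([0.8, 0.9, 0.7, -0.2, -0.3, -0.1], "HC/LB"),
        ([-0.8, -0.9, -0.7, -0.2, -0.3, -0.1], "LC/LB"),
        ([0, 0, 0, 0, 0, 0], "MC/LB"),
        ([0, 0, 0, 1.2, 0, 1.0], "MC/HSI"),
        ([0, 0, 0, 0.2, 1.2, 0.1], "MC/HE"),
    ])
    def test_labeling_rules(self, centroid, expected):
        model = self.make_model(np.asarray(centroid, dtype=float))
        fp.label_profiles(model, score_threshold=0.5)
        assert model.labels[0] == expected

    def test_duplicate_labels_disambiguated(self):
        centroids = np.zeros((2, 6))
        centroids[1, 0] = 0.1
        model = fp.ProfileModel(centroids=centroids, covariances=[np.eye(6)] * 2,
                                fuzzifier=2.0)
        fp.label_profiles(model)
        assert model.labels == ("MC/LB#1", "MC/LB#2")


class TestRecovery:
    def test_planted_centroids_and_labels_recovered(self, default_cohort,
                                                    standardized_features,
                                                    fitted_model):
        spec, _, truth = default_cohort
        model, U = fitted_model
        res = fp.truth_compare(model.centroids, U.hard_labels(), truth,
                               true_centroids=spec.standardized_centroids())
        assert res["centroid_error_mean"] < 0.15
        assert res["label_agreement"] >= 0.9
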