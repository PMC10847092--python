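"""Gaussian-mixture tests: EM correctness, criteria, model selection,
confidence ellipses, and cross-checks against an independent implementation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from limbkin import gmm, synth


def two_blobs(n=100, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 0.5, size=(n, 2))
    b = rng.normal([sep, sep], 0.5, size=(n, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n)
    return X, labels


class TestFitEm:
    def test_k1_closed_form(self, rng):
        """K=1 collapses to the sample mean and ML covariance (divisor n)."""
        X = rng.normal(size=(60, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
        model = gmm.fit_em(X, K=1, seed=0, n_restarts=1)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(model.covariances[0],
                                   np.cov(X.T, bias=True), atol=1e-5)
        expect_ll = multivariate_normal(X.mean(axis=0),
                                        np.cov(X.T, bias=True)).logpdf(X).sum()
        assert model.log_likelihood == pytest.approx(expect_ll, abs=1e-3)

    def test_separated_blobs_exact_labels(self):
        X, labels = two_blobs()
        model = gmm.fit_em(X, K=2, seed=1)
        hard = model.hard_labels
        agree = max(np.mean(hard == labels), np.mean(hard != labels))
        assert agree == 1.0  # ARI = 1 up to permutation

    def test_log_likelihood_monotone(self, rng):
        for i in range(10):
            X = rng.normal(size=(rng.integers(20, 60), 2)) * rng.uniform(0.5, 3)
            model = gmm.fit_em(X, K=3, seed=i, n_restarts=1)
            path = model.log_likelihood_path
            assert np.all(np.diff(path) >= -1e-7 * np.abs(path[:-1]))

    def test_responsibilities_rows_sum_to_one(self):
        X, _ = two_blobs(n=40)
        model = gmm.fit_em(X, K=2, seed=0)
        np.testing.assert_allclose(model.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert model.weights.sum() == pytest.approx(1.0)

    def test_n_less_than_k_raises(self, rng):
        with pytest.raises(ValueError, match="cannot support"):
            gmm.fit_em(rng.normal(size=(3, 2)), K=5)

    def test_nonfinite_features_raise(self):
        X = np.array([[0.0, 1.0], [np.nan, 2.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            gmm.fit_em(X, K=1)

    def test_seeded_determinism(self):
        X, _ = two_blobs(n=50, sep=3.0, seed=4)
        m1 = gmm.fit_em(X, K=2, seed=9)
        m2 = gmm.fit_em(X, K=2, seed=9)
        np.testing.assert_array_equal(m1.means, m2.means)
        assert m1.log_likelihood == m2.log_likelihood


class TestCriteria:
    def test_bic_formula(self):
        model = gmm.MixtureModel(
            K=1, weights=np.array([1.0]), means=np.zeros((1, 2)),
            covariances=np.eye(2)[None], responsibilities=np.ones((5, 1)),
            log_likelihood=0.0, n_iter=1)
        # n_params = 5 for K=1 in 2-D; at n = e, BIC = 0 + 5 * 1
        assert gmm.bic(model, int(np.e)) != 5  # ln(2) != 1; use exact n
        assert gmm.bic(model, 1) == pytest.approx(0.0)  # ln 1 = 0
        assert gmm.bic(model, 10) == pytest.approx(5 * np.log(10))

    def test_bic_penalizes_parameters(self):
        X, _ = two_blobs(n=30, sep=0.0, seed=2)  # a single blob
        m1 = gmm.fit_em(X, K=1, seed=0)
        m2 = gmm.fit_em(X, K=2, seed=0)
        # likelihood can only improve, but the penalty grows faster on noise
        assert m2.n_params > m1.n_params

    def test_bic_hand_computed_k1(self):
        """Ten fixed points: BIC matches a hand computation from the
        closed-form Gaussian likelihood."""
        X = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.0], [3.0, 0.0],
                      [4.0, 1.5], [0.5, 2.0], [1.5, 2.5], [2.5, 3.0],
                      [3.5, 2.0], [4.5, 3.5]])
        model = gmm.fit_em(X, K=1, seed=0, n_restarts=1)
        mu = X.mean(axis=0)
        S = np.cov(X.T, bias=True)
        ll = multivariate_normal(mu, S).logpdf(X).sum()
        expected = -2 * ll + 5 * np.log(10)
        assert gmm.bic(model, 10) == pytest.approx(expected, abs=1e-3)

    def test_icl_equals_bic_for_hard_partition(self):
        X, _ = two_blobs()  # perfectly separated -> responsibilities ~0/1
        model = gmm.fit_em(X, K=2, seed=0)
        assert gmm.icl(model, len(X)) == pytest.approx(gmm.bic(model, len(X)),
                                                       abs=1e-6)

    def test_icl_uniform_responsibilities(self):
        model = gmm.MixtureModel(
            K=2, weights=np.array([0.5, 0.5]), means=np.zeros((2, 2)),
            covariances=np.stack([np.eye(2)] * 2),
            responsibilities=np.full((10, 2), 0.5),
            log_likelihood=-12.0, n_iter=1)
        assert gmm.icl(model, 10) == pytest.approx(
            gmm.bic(model, 10) + 2 * 10 * np.log(2))

    def test_icl_at_least_bic(self, rng):
        X = rng.normal(size=(80, 2))
        model = gmm.fit_em(X, K=3, seed=0)
        assert gmm.icl(model, 80) >= gmm.bic(model, 80) - 1e-9

    def test_label_permutation_invariance(self):
        X, _ = two_blobs(n=60, sep=4.0, seed=5)
        model = gmm.fit_em(X, K=2, seed=3)
        perm = [1, 0]
        permuted = gmm.MixtureModel(
            K=2, weights=model.weights[perm], means=model.means[perm],
            covariances=model.covariances[perm],
            responsibilities=model.responsibilities[:, perm],
            log_likelihood=model.log_likelihood, n_iter=model.n_iter)
        n = len(X)
        assert gmm.bic(permuted, n) == pytest.approx(gmm.bic(model, n))
        assert gmm.icl(permuted, n) == pytest.approx(gmm.icl(model, n))

    def test_nonpositive_n_raises(self):
        model = gmm.MixtureModel(
            K=1, weights=np.array([1.0]), means=np.zeros((1, 2)),
            covariances=np.eye(2)[None], responsibilities=np.ones((5, 1)),
            log_likelihood=0.0, n_iter=1)
        with pytest.raises(ValueError):
            gmm.bic(model, 0)


class TestSelectModel:
    def test_recovers_planted_k5(self):
        sc = synth.well_separated_scenario(n_participants=300, seed=0)
        X = synth.sample_features(sc)[
            ["limb_angle_ext", "limb_length"]].to_numpy()
        model, table = gmm.select_model(X, K_range=range(4, 8), seed=0)
        assert model.K == 5
        assert list(table["K"]) == [4, 5, 6, 7]

    def test_single_blob_table_complete(self, rng):
        X = rng.normal(size=(120, 2))
        model, table = gmm.select_model(X, K_range=range(4, 8), seed=1)
        assert len(table) == 4
        assert table["BIC"].notna().all()

    def test_empty_range_raises(self, rng):
        with pytest.raises(ValueError, match="empty"):
            gmm.select_model(rng.normal(size=(50, 2)), K_range=[])


class TestConfidenceEllipse:
    def test_identity_covariance_circle(self):
        e = gmm.confidence_ellipse(np.zeros(2), np.eye(2), level=0.95)
        np.testing.assert_allclose(e.axes, np.sqrt(5.991465), atol=1e-4)

    def test_diagonal_axis_ratio(self):
        e = gmm.confidence_ellipse(np.zeros(2), np.diag([4.0, 1.0]))
        assert e.axes[0] / e.axes[1] == pytest.approx(2.0)
        assert e.rotation % 180 == pytest.approx(0.0, abs=1e-8)

    def test_level_to_zero_shrinks(self):
        e = gmm.confidence_ellipse(np.zeros(2), np.eye(2), level=1e-9)
        assert np.all(e.axes < 1e-3)

    def test_non_pd_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            gmm.confidence_ellipse(np.zeros(2), np.diag([1.0, 0.0]))


class TestAgainstReferenceImplementation:
    def test_loglik_matches_sklearn(self):
        """On 20 random small datasets our EM's best log-likelihood matches
        scikit-learn's GaussianMixture within 1e-3 (both with restarts), and
        hard labels agree up to permutation when components are separated."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n = int(rng.integers(60, 200))
            sep = rng.uniform(4.0, 8.0)
            centers = np.array([[0, 0], [sep, 0], [0, sep]])
            k = int(rng.integers(2, 4))
            X = np.vstack([
                rng.normal(centers[j], 0.6, size=(n // k, 2))
                for j in range(k)])
            ours = gmm.fit_em(X, K=k, seed=trial, n_restarts=10)
            ref = sklearn.GaussianMixture(
                n_components=k, covariance_type="full", n_init=10,
                reg_covar=1e-6, random_state=trial, tol=1e-8,
                max_iter=500).fit(X)
            ll_ref = ref.score(X) * len(X)
            assert ours.log_likelihood == pytest.approx(ll_ref, abs=1e-3), \
                f"trial {trial}"
            # label agreement up to permutation
            ref_labels = ref.predict(X)
            table = np.zeros((k, k))
            for a, b in zip(ours.hard_labels, ref_labels):
                table[a, b] += 1
            assert table.max(axis=1).sum() == len(X)
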