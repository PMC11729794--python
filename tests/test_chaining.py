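import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infmix.chaining import (
    ChainingConfig,
    ChainingModel,
    argument_scores,
    fit_beta,
    head_scores,
    infer_centroids,
    similarity,
)
from infmix.embeddings import fit_projection


class TestSimilarity:
    def test_query_at_single_centroid(self):
        assert similarity(np.zeros(3), np.zeros((1, 3)), beta=1.0) == 1.0

    def test_mean_kernel_hand_value(self):
        # q=(0,0), centroids {(1,0),(0,2)}, beta=1 -> (e^-1 + e^-4)/2
        q = np.zeros(2)
        M = np.array([[1.0, 0.0], [0.0, 2.0]])
        expected = (np.exp(-1) + np.exp(-4)) / 2
        assert similarity(q, M, 1.0) == pytest.approx(expected, abs=1e-12)
        assert similarity(q, M, 1.0) == pytest.approx(0.19310, abs=1e-5)

    def test_onenn_kernel_takes_max_term(self):
        q = np.zeros(2)
        M = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert similarity(q, M, 1.0, kind="onenn") == pytest.approx(
            np.exp(-1), abs=1e-12
        )

    def test_single_centroid_reduces_to_prototype_kernel(self, rng):
        q, mu = rng.normal(size=4), rng.normal(size=(1, 4))
        mean_form = similarity(q, mu, 0.7)
        proto_form = np.exp(-((q - mu[0]) ** 2).sum() / 0.7)
        assert mean_form == pytest.approx(proto_form, abs=1e-15)

    @given(shift=st.floats(0.1, 5.0), beta=st.floats(0.05, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_decreases_with_distance_increases_with_beta(self, shift, beta):
        q = np.zeros(2)
        near, far = np.array([[1.0, 0.0]]), np.array([[1.0 + shift, 0.0]])
        assert similarity(q, near, beta) > similarity(q, far, beta)
        assert similarity(q, near, beta + 0.1) > similarity(q, near, beta)

    def test_errors(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(2), np.zeros((1, 3)), 1.0)
        with pytest.raises(ValueError):
            similarity(np.zeros(2), np.zeros((1, 2)), 0.0)
        with pytest.raises(ValueError):
            similarity(np.zeros(2), np.empty((0, 2)), 1.0)


class TestCentroids:
    def test_prototype_is_mean(self):
        M = infer_centroids(np.array([[0.0, 0.0], [2.0, 0.0]]),
                            ChainingConfig(kind="prototype"))
        np.testing.assert_allclose(M, [[1.0, 0.0]])

    def test_exemplar_keeps_every_vector(self, rng):
        X = rng.normal(size=(8, 3))
        M = infer_centroids(X, ChainingConfig(kind="exemplar"))
        np.testing.assert_array_equal(M, X)

    def test_infmix_lambda_zero_equals_exemplar(self, rng):
        X = rng.normal(size=(10, 3))
        M = infer_centroids(X, ChainingConfig(kind="infmix", lam=0.0))
        # same centroid set (DP-means may reorder)
        assert sorted(map(tuple, M)) == sorted(map(tuple, X))

    def test_infmix_large_lambda_equals_prototype(self, rng):
        X = rng.normal(size=(10, 3))
        lam = ((X[:, None] - X[None]) ** 2).sum(-1).max() + 1.0
        M = infer_centroids(X, ChainingConfig(kind="infmix", lam=lam))
        np.testing.assert_allclose(M, X.mean(0, keepdims=True), atol=1e-12)

    def test_infmix_clusters_in_projected_space(self, rng):
        # full-space centroids from labels computed in the PCA subspace
        X = np.vstack([rng.normal(size=(6, 5)),
                       rng.normal(size=(6, 5)) + 20.0])
        proj = fit_projection(X, k=2)
        M = infer_centroids(X, ChainingConfig(kind="infmix", lam=30.0),
                            projection=proj)
        assert M.shape == (2, 5)  # full-space dimensionality, 2 clusters
        np.testing.assert_allclose(
            sorted(map(tuple, M)),
            sorted(map(tuple, [X[:6].mean(0), X[6:].mean(0)])),
            atol=1e-9,
        )

    def test_empty_support_raises(self):
        with pytest.raises(ValueError):
            ChainingModel(kind="prototype").fit(np.empty((0, 2)))


class TestScores:
    def test_head_scores_hand_normalization(self):
        # similarities e^-1 and e^-4 -> softmax-like shares 0.9526/0.0474
        q = np.zeros(1)
        cands = [np.array([[1.0]]), np.array([[2.0]])]
        s = head_scores(q, cands, beta=1.0, kind="prototype")
        expected = np.exp(-1) / (np.exp(-1) + np.exp(-4))
        np.testing.assert_allclose(s, [expected, 1 - expected], atol=1e-12)
        np.testing.assert_allclose(s, [0.9526, 0.0474], atol=1e-4)

    def test_head_scores_uniform_under_symmetry(self):
        q = np.zeros(2)
        cands = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]),
                 np.array([[-1.0, 0.0]])]
        np.testing.assert_allclose(
            head_scores(q, cands, 0.5), np.ones(3) / 3, atol=1e-12
        )

    @pytest.mark.parametrize("kind", ["exemplar", "onenn", "prototype", "infmix"])
    def test_scores_sum_to_one(self, rng, kind):
        q = rng.normal(size=4)
        cands = [rng.normal(size=(rng.integers(1, 6), 4)) for _ in range(10)]
        assert head_scores(q, cands, 0.8, kind=kind).sum() == pytest.approx(
            1.0, abs=1e-12
        )
        args = rng.normal(size=(10, 4))
        assert argument_scores(args, cands[0], 0.8, kind=kind).sum() == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_argument_prior_cancels(self, rng):
        args = rng.normal(size=(5, 3))
        M = rng.normal(size=(2, 3))
        s1 = argument_scores(args, M, 0.5, prior=100.0)
        s2 = argument_scores(args, M, 0.5, prior=200.0)
        np.testing.assert_allclose(s1, s2, atol=1e-15)
        # ranking equals the raw similarity ranking
        sims = similarity(args, M, 0.5)
        np.testing.assert_array_equal(np.argsort(s1), np.argsort(sims))

    def test_equal_similarities_split_evenly(self):
        args = np.array([[1.0, 0.0], [-1.0, 0.0]])
        s = argument_scores(args, np.zeros((1, 2)), 1.0, prior=7.0)
        np.testing.assert_allclose(s, [0.5, 0.5])


def _geometry_trials():
    """Deterministic trials whose mean-truth-probability objective has an
    interior optimum in beta: in half the trials the truth is nearest, in
    the other half a decoy is nearer, so neither beta -> 0 nor beta -> inf
    is optimal."""
    trials = []
    for d_truth, d_decoy in [(0.5, 1.5), (1.0, 0.8)] * 3:
        q = np.zeros(2)
        truth = np.array([[d_truth, 0.0]])
        decoy = np.array([[0.0, d_decoy]])
        far = np.array([[3.0, 3.0]])
        trials.append((q, [truth, decoy, far], 0))
    return trials


class TestFitBeta:
    def test_matches_dense_grid_oracle(self):
        trials = _geometry_trials()
        res = fit_beta(trials, kind="prototype")
        # independent oracle: dense grid over the same objective
        grid = np.geomspace(0.01, 10, 400)
        obj = [
            np.mean([head_scores(q, cands, b, kind="prototype")[t]
                     for q, cands, t in trials])
            for b in grid
        ]
        oracle_beta = grid[int(np.argmax(obj))]
        assert 0.5 * oracle_beta <= res.beta <= 2.0 * oracle_beta
        assert res.objective >= max(obj) - 1e-9

    def test_sgd_agrees_with_deterministic(self):
        trials = _geometry_trials()
        det = fit_beta(trials, kind="prototype", mode="grid")
        sgd = fit_beta(trials, kind="prototype", mode="sgd", seed=3)
        assert abs(det.objective - sgd.objective) <= 1e-3

    def test_flat_optimum_still_reports_objective(self):
        # truth is the nearest candidate at every beta
        q = np.zeros(2)
        trials = [(q, [np.array([[0.1, 0.0]]), np.array([[5.0, 0.0]])], 0)]
        res = fit_beta(trials, kind="prototype")
        assert np.isfinite(res.objective) and res.objective > 0.5

    def test_no_trials_raises(self):
        with pytest.raises(ValueError):
            fit_beta([])


class TestFamilyEquivalences:
    """The unifying claim: the infinite mixture family contains the
    exemplar and prototype models as its lambda limits."""

    @pytest.mark.parametrize("seed", range(5))
    def test_limits_match_in_similarity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 4))
        q = rng.normal(size=4)
        beta = 0.9
        lam_big = ((X[:, None] - X[None]) ** 2).sum(-1).max() + 1e-6

        ex = infer_centroids(X, ChainingConfig(kind="exemplar"))
        pr = infer_centroids(X, ChainingConfig(kind="prototype"))
        inf0 = infer_centroids(X, ChainingConfig(kind="infmix", lam=0.0))
        infL = infer_centroids(X, ChainingConfig(kind="infmix", lam=lam_big))

        assert similarity(q, inf0, beta) == pytest.approx(
            similarity(q, ex, beta), abs=1e-12
        )
        assert similarity(q, infL, beta) == pytest.approx(
            similarity(q, pr, beta), abs=1e-12
        )
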