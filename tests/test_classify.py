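"""KNN and LDA against brute-force oracles and closed-form limits."""

import numpy as np
import pytest

from odorid import KNNConfig, LDAConfig, fit, predict

# ---------------------------------------------------------------------------
# independent oracles: direct enumeration of distances / the discriminant


def knn_oracle(train_x, train_y, queries, k):
    """Literal KNN: sort distances (ties by row index), majority vote, vote
    ties to the nearest neighbour in a tied class."""
    out = []
    for q in np.atleast_2d(queries):
        d = np.sqrt(((train_x - q) ** 2).sum(axis=1))
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        votes = {}
        for i in order:
            votes[train_y[i]] = votes.get(train_y[i], 0) + 1
        top = max(votes.values())
        tied = {lab for lab, v in votes.items() if v == top}
        for i in order:
            if train_y[i] in tied:
                out.append(train_y[i])
                break
    return np.array(out, dtype=object)


def lda_oracle(train_x, train_y, queries, gamma=1e-6):
    """Literal LDA: pooled covariance with divisor N-C plus diagonal ridge,
    argmax of x'S^-1 mu - mu'S^-1 mu/2 + log pi."""
    classes = sorted(set(train_y))
    n, d = train_x.shape
    means = {c: train_x[np.array(train_y) == c].mean(axis=0) for c in classes}
    cov = np.zeros((d, d))
    for xi, yi in zip(train_x, train_y):
        r = xi - means[yi]
        cov += np.outer(r, r)
    cov /= n - len(classes)
    if gamma > 0:
        cov += gamma * np.mean(np.diag(cov)) * np.eye(d)
    inv = np.linalg.inv(cov)
    out = []
    for q in np.atleast_2d(queries):
        best, best_score = None, -np.inf
        for c in classes:
            mu = means[c]
            pi = np.mean(np.array(train_y) == c)
            score = q @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
            if score > best_score:
                best, best_score = c, score
        out.append(best)
    return np.array(out, dtype=object)


def random_instance(rng, n_max=30, d_max=5, n_classes_max=5):
    n_classes = rng.integers(2, n_classes_max + 1)
    d = rng.integers(1, d_max + 1)
    per_class = rng.integers(2, max(3, n_max // n_classes) + 1)
    labels = np.repeat([f"c{i}" for i in range(n_classes)], per_class)
    centers = rng.normal(0, 2, size=(n_classes, d))
    x = centers[np.repeat(np.arange(n_classes), per_class)] + rng.normal(
        0, 1.0, size=(len(labels), d))
    queries = rng.normal(0, 2, size=(rng.integers(1, 8), d))
    return x, labels.astype(object), queries


# ---------------------------------------------------------------------------


class TestKNN:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_oracle(self, rng, k):
        for _ in range(60):
            x, y, q = random_instance(rng)
            model = fit(x, y, KNNConfig(k=k))
            assert np.array_equal(predict(model, q), knn_oracle(x, y, q, k))

    def test_query_on_training_point_k1(self, rng):
        x, y, _ = random_instance(rng)
        model = fit(x, y, KNNConfig(k=1))
        assert np.array_equal(predict(model, x), y)  # 100% self-prediction

    def test_single_point_per_class_is_nearest_centroid(self):
        x = np.array([[0.0, 0.0], [10.0, 0.0]])
        y = np.array(["a", "b"], dtype=object)
        model = fit(x, y, KNNConfig(k=1))
        assert predict(model, [[1.0, 1.0]])[0] == "a"
        assert predict(model, [[9.0, -1.0]])[0] == "b"

    def test_k2_vote_tie_goes_to_nearer_neighbour(self):
        x = np.array([[0.0], [3.0], [10.0]])
        y = np.array(["a", "b", "b"], dtype=object)
        model = fit(x, y, KNNConfig(k=2))
        # query at 1: neighbours are a (d=1) and b (d=2) -> nearer wins
        assert predict(model, [[1.0]])[0] == "a"
        assert predict(model, [[2.5]])[0] == "b"

    def test_equidistant_tie_breaks_by_row_index(self):
        x = np.array([[-1.0], [1.0], [9.0]])
        y = np.array(["b", "a", "c"], dtype=object)
        model = fit(x, y, KNNConfig(k=2))
        assert predict(model, [[0.0]])[0] == "b"  # row 0 wins the exact tie
        model2 = fit(x[[1, 0, 2]], y[[1, 0, 2]], KNNConfig(k=2))
        assert predict(model2, [[0.0]])[0] == "a"

    def test_training_row_order_invariance(self, rng):
        for _ in range(20):
            x, y, q = random_instance(rng)
            perm = rng.permutation(len(y))
            m1 = fit(x, y, KNNConfig(k=2))
            m2 = fit(x[perm], y[perm], KNNConfig(k=2))
            assert np.array_equal(predict(m1, q), predict(m2, q))

    def test_k_must_be_below_training_size(self):
        x = np.eye(3)
        y = np.array(["a", "b", "c"], dtype=object)
        with pytest.raises(ValueError, match="k=3"):
            fit(x, y, KNNConfig(k=3))

    def test_dimension_mismatch(self, rng):
        x, y, _ = random_instance(rng)
        model = fit(x, y, KNNConfig(k=1))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((1, x.shape[1] + 1)))


class TestLDA:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            x, y, q = random_instance(rng)
            model = fit(x, y, LDAConfig())
            assert np.array_equal(predict(model, q), lda_oracle(x, y, q))

    def test_spherical_covariance_boundary_is_perpendicular_bisector(self):
        # deviations +-e_j around each mean give an exactly spherical pooled
        # covariance, so the decision boundary is the bisector of mu1 mu2
        mu1, mu2 = np.array([0.0, 0.0]), np.array([4.0, 2.0])
        devs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        x = np.vstack([mu1 + devs, mu2 + devs])
        y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        model = fit(x, y, LDAConfig(gamma=0.0))
        rng = np.random.default_rng(0)
        queries = rng.normal(0, 3, size=(200, 2)) + (mu1 + mu2) / 2
        expected = np.where(
            np.linalg.norm(queries - mu1, axis=1) < np.linalg.norm(queries - mu2, axis=1),
            "a", "b",
        ).astype(object)
        assert np.array_equal(predict(model, queries), expected)

    def test_affine_invariance(self, rng):
        for _ in range(10):
            x, y, q = random_instance(rng)
            d = x.shape[1]
            a = rng.normal(0, 1, size=(d, d)) + 3 * np.eye(d)  # well-conditioned
            b = rng.normal(0, 1, size=d)
            m1 = fit(x, y, LDAConfig(gamma=0.0))
            m2 = fit(x @ a + b, y, LDAConfig(gamma=0.0))
            assert np.array_equal(predict(m1, q), predict(m2, q @ a + b))

    def test_needs_two_classes(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit(np.eye(3), np.array(["a", "a", "a"]), LDAConfig())

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            LDAConfig(gamma=-1.0)


class TestSklearnCrossCheck:
    """Independent library cross-check on well-separated, tie-free data."""

    def test_knn_k1_matches_sklearn(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        for _ in range(10):
            x, y, q = random_instance(rng)
            ours = predict(fit(x, y, KNNConfig(k=1)), q)
            theirs = KNeighborsClassifier(n_neighbors=1).fit(x, y).predict(q)
            assert np.array_equal(ours, theirs.astype(object))

    def test_lda_matches_sklearn_on_separated_blobs(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for _ in range(10):
            x, y, _ = random_instance(rng)
            x = x + 8.0 * (np.array([int(c[1:]) for c in y])[:, None])  # separate
            q = x + rng.normal(0, 0.1, x.shape)
            ours = predict(fit(x, y, LDAConfig()), q)
            theirs = LinearDiscriminantAnalysis().fit(x, y).predict(q)
            assert np.array_equal(ours, theirs.astype(object))


def test_standardize_option_scales_features(rng):
    x, y, q = random_instance(rng)
    scales = np.full(x.shape[1], 100.0)
    m1 = predict(fit(x, y, KNNConfig(k=1, standardize=True)), q)
    m2 = predict(fit(x * scales, y, KNNConfig(k=1, standardize=True)), q * scales)
    assert np.array_equal(m1, m2)
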