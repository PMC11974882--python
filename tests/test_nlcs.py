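import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier

from mdmri import NLCSClassifier, hull_distance

from conftest import brute_force_hull_distance


class TestHullDistance:
    def test_interior_point_is_zero(self):
        r = hull_distance([0.0, 0.0], [[1, 0], [-1, 1], [-1, -1]])
        assert r.distance == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(r.witness, [0, 0], atol=1e-6)

    def test_single_point_hull(self):
        r = hull_distance([3.0, 4.0], [[0.0, 0.0]])
        assert r.distance == pytest.approx(5.0)
        np.testing.assert_array_equal(r.weights, [1.0])

    def test_projection_onto_triangle_edge(self):
        """x*=(2,0) against triangle {(0,1),(0,-1),(-1,0)}: the nearest
        hull point is the edge midpoint (0,0) at distance 2."""
        r = hull_distance([2.0, 0.0], [[0, 1], [0, -1], [-1, 0]])
        assert r.distance == pytest.approx(2.0, abs=1e-7)
        np.testing.assert_allclose(r.witness, [0, 0], atol=1e-7)
        np.testing.assert_allclose(r.weights, [0.5, 0.5, 0.0], atol=1e-7)

    def test_projection_onto_segment(self):
        r = hull_distance([0.5, 1.0], [[0, 0], [1, 0]])
        assert r.distance == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(r.witness, [0.5, 0.0], atol=1e-9)

    def test_vertex_solution(self):
        r = hull_distance([2.0, 2.0], [[0, 0], [1, 0], [0, 1]])
        # nearest point is the vertex... actually the midpoint of the
        # hypotenuse (0.5, 0.5)
        np.testing.assert_allclose(r.witness, [0.5, 0.5], atol=1e-7)
        assert r.distance == pytest.approx(np.sqrt(2 * 1.5**2), abs=1e-7)

    def test_weights_form_certificate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Z = rng.normal(size=(rng.integers(1, 7), 3))
            x = rng.normal(size=3)
            r = hull_distance(x, Z)
            assert np.all(r.weights >= -1e-12)
            assert r.weights.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(r.witness, r.weights @ Z, atol=1e-9)
            assert np.linalg.norm(x - r.witness) == pytest.approx(
                r.distance, abs=1e-7)

    def test_matches_brute_force_oracle(self):
        """QP distances agree with a shrinking dense simplex-grid search
        on random instances (the oracle shares no solver code)."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            dim = int(rng.integers(2, 6))
            m = int(rng.integers(1, 7))
            Z = rng.uniform(-1, 1, size=(m, dim))
            x = rng.uniform(-2, 2, size=dim)
            qp = hull_distance(x, Z).distance
            ref = brute_force_hull_distance(x, Z)
            assert qp <= ref + 1e-9  # grid search can only overestimate
            assert abs(qp - ref) < 1e-2

    def test_non_euclidean_norm_unimplemented(self):
        with pytest.raises(NotImplementedError):
            hull_distance([0.0], [[1.0]], p=1)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            hull_distance([0.0, 1.0], [[1.0, 2.0, 3.0]])


class TestNeighborhoods:
    def setup_method(self):
        self.X = np.array([[0.0, 0], [1, 0], [5, 5], [9, 9], [8, 8]])
        self.y = np.array([0, 0, 0, 1, 1])

    def test_k_at_least_class_size_returns_all(self):
        model = NLCSClassifier(k=10).fit(self.X, self.y)
        assert model.class_neighborhood([0, 0], 0).shape == (3, 2)

    def test_k1_single_nearest(self):
        model = NLCSClassifier(k=1).fit(self.X, self.y)
        np.testing.assert_array_equal(
            model.class_neighborhood([0.9, 0], 0), [[1, 0]])

    def test_two_nearest_by_exhaustive_comparison(self):
        model = NLCSClassifier(k=2).fit(self.X, self.y)
        np.testing.assert_array_equal(
            model.class_neighborhood([0.4, 0], 0), [[0, 0], [1, 0]])

    def test_neighbor_ties_break_by_insertion_order(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 3]])
        model = NLCSClassifier(k=1).fit(X, [0, 0, 0])
        np.testing.assert_array_equal(
            model.class_neighborhood([0, 0], 0), [[1, 0]])


class TestClassifier:
    def test_training_point_classified_to_its_class(self):
        X = np.array([[0.0, 0], [1, 1], [5, 5], [6, 6]])
        y = np.array(["a", "a", "b", "b"])
        model = NLCSClassifier(k=1).fit(X, y)
        assert model.predict([[1, 1]])[0] == "a"
        dists = model.decision_distances([[1, 1]])
        assert dists[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_interior_of_local_hull_wins(self):
        # class B surrounds the query; class A is far away
        X = np.array([[10.0, 10], [11, 10],
                      [1, 0], [-1, 1], [-1, -1]])
        y = np.array([0, 0, 1, 1, 1])
        model = NLCSClassifier(k=3).fit(X, y)
        assert model.predict([[0, 0]])[0] == 1

    def test_k1_reduces_to_one_nearest_neighbor(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            X = rng.normal(size=(40, 3))
            y = rng.integers(0, 3, size=40)
            Xq = rng.normal(size=(25, 3))
            ours = NLCSClassifier(k=1).fit(X, y).predict(Xq)
            ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(Xq)
            np.testing.assert_array_equal(ours, ref)

    def test_concentric_rings_beat_linear_model(self):
        """Two concentric rings: the local convex hulls track the ring
        curvature (>= 98/100 correct) while LDA, a linear boundary,
        cannot (<= 60/100)."""
        rng = np.random.default_rng(12)
        n = 100
        theta = rng.uniform(0, 2 * np.pi, size=(2, n))
        radii = np.array([[1.0], [3.0]])
        X = np.concatenate([
            np.column_stack([r * np.cos(t), r * np.sin(t)])
            for r, t in zip(radii, theta)])
        y = np.repeat([0, 1], n)
        t_test = rng.uniform(0, 2 * np.pi, size=(2, 50))
        Xq = np.concatenate([
            np.column_stack([r * np.cos(t), r * np.sin(t)])
            for r, t in zip(radii, t_test)])
        yq = np.repeat([0, 1], 50)
        nlcs_acc = np.sum(NLCSClassifier(k=5).fit(X, y).predict(Xq) == yq)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        lda_acc = np.sum(lda.predict(Xq) == yq)
        assert nlcs_acc >= 98
        assert lda_acc <= 60

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, size=30)
        Xq = rng.normal(size=(10, 4))
        model = NLCSClassifier(k=4).fit(X, y)
        scaled = NLCSClassifier(k=4).fit(3.5 * X, y)
        np.testing.assert_allclose(
            scaled.decision_distances(3.5 * Xq),
            3.5 * model.decision_distances(Xq), rtol=1e-6, atol=1e-9)
        np.testing.assert_array_equal(
            scaled.predict(3.5 * Xq), model.predict(Xq))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        Xq = rng.normal(size=(20, 3))
        base = NLCSClassifier(k=5).fit(X, y).predict(Xq)
        perm = rng.permutation(50)
        shuffled = NLCSClassifier(k=5).fit(X[perm], y[perm]).predict(Xq)
        np.testing.assert_array_equal(base, shuffled)

    def test_fit_contract(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        y = np.array([3, 3, 3, 3, 7, 7, 7, 7, 7, 7])
        model = NLCSClassifier(k=2).fit(X, y)
        np.testing.assert_array_equal(model.classes_, [3, 7])
        sizes = [p.shape[0] for p in model._partitions]
        assert sum(sizes) == 10 and sizes == [4, 6]
        # duplicate rows are preserved
        X2 = np.vstack([X, X[:1]])
        y2 = np.append(y, 3)
        model2 = NLCSClassifier(k=2).fit(X2, y2)
        assert model2._partitions[0].shape[0] == 5
        # original label values come back from predict
        assert set(np.unique(model2.predict(X))) <= {3, 7}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            NLCSClassifier(k=0)
        with pytest.raises(ValueError):
            NLCSClassifier().fit(np.zeros((3, 2)), [0, 1])
        with pytest.raises(RuntimeError, match="not fitted"):
            NLCSClassifier().predict([[0.0, 0.0]])
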