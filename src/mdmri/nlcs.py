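"""K-Nearest Local Convex Set (NLCS) classification.

For a query x*, each class i contributes its k training points nearest
to x*; the class score is the distance from x* to the convex hull of
that neighborhood,

    h(x*) = argmin_i  min_{w in simplex} || x* - Z_i^T w ||_p,

and the smallest hull distance wins.  The local hull interpolates
between 1-nearest-neighbor (k = 1: the hull of one point is the point)
and a piecewise-linear class model, which handles strongly non-linear
class geometries without iterative training.

The hull distance for p = 2 is a convex quadratic program over the
probability simplex.  It is solved by non-negative least squares on an
equality-penalised system (the classic Lawson-Hanson trick for the
sum-to-one constraint), then polished to full accuracy by an active-set
loop on the exact KKT system, with the projection's variational
inequality <x* - witness, z_j - witness> <= 0 verified for every
neighborhood point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["NLCSClassifier", "HullDistanceResult", "hull_distance"]


@dataclasses.dataclass
class HullDistanceResult:
    """Distance from a query to conv(points), with certificate.

    ``weights`` are barycentric coordinates over the points (>= 0, sum
    to 1) and ``witness`` = weights @ points is the projection achieving
    the distance.
    """

    distance: float
    weights: np.ndarray
    witness: np.ndarray


def _polish_on_support(x: np.ndarray, Z: np.ndarray,
                       support: np.ndarray) -> np.ndarray:
    """Solve min ||x - Z_S^T w||^2 s.t. sum w = 1 on a support set,
    dropping negative coordinates until feasible (w >= 0)."""
    support = list(support)
    while True:
        S = Z[support]                      # (m_s, dim)
        m_s = len(support)
        G = S @ S.T
        kkt = np.zeros((m_s + 1, m_s + 1))
        kkt[:m_s, :m_s] = G
        kkt[:m_s, m_s] = 1.0
        kkt[m_s, :m_s] = 1.0
        rhs = np.concatenate([S @ x, [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        w_s = sol[:m_s]
        if m_s == 1 or w_s.min() >= -1e-12:
            w = np.zeros(Z.shape[0])
            w[support] = np.clip(w_s, 0.0, None)
            total = w.sum()
            if total > 0:
                w /= total
            return w
        support.pop(int(np.argmin(w_s)))


def hull_distance(x_star: np.ndarray, points: np.ndarray,
                  p: float = 2) -> HullDistanceResult:
    """Euclidean distance from ``x_star`` to the convex hull of ``points``.

    Solves the simplex-constrained least-squares problem to ~1e-8 and
    returns distance, barycentric weights and the witness projection.
    Only p = 2 is implemented (the problem is then a standard QP); other
    norms raise ``NotImplementedError``.
    """
    if p != 2:
        raise NotImplementedError(
            f"hull distance implemented for p=2 only (got p={p})"
        )
    x = np.asarray(x_star, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(points, dtype=float))
    if Z.size == 0:
        raise ValueError("need at least one point")
    if Z.shape[1] != x.size:
        raise ValueError(
            f"dimension mismatch: query has {x.size}, points have {Z.shape[1]}"
        )
    m = Z.shape[0]
    if m == 1:
        w = np.ones(1)
        witness = Z[0].copy()
        return HullDistanceResult(float(np.linalg.norm(x - witness)), w, witness)

    scale = max(1.0, float(np.abs(Z).max()), float(np.abs(x).max()))
    rho = 1e4 * scale  # penalty weight enforcing sum(w) = 1
    A = np.vstack([Z.T, rho * np.ones((1, m))])
    b = np.concatenate([x, [rho]])
    w0, _ = _scipy_nnls(A, b)
    support = np.flatnonzero(w0 > 1e-9 * max(w0.max(initial=0.0), 1.0))
    if support.size == 0:
        support = np.array([int(np.argmax(w0))])

    tol = 1e-10 * scale * scale
    for _ in range(10 * m):
        w = _polish_on_support(x, Z, support)
        witness = w @ Z
        gap = x - witness
        # projection optimality: no hull point improves the witness
        slack = Z @ gap - witness @ gap
        worst = int(np.argmax(slack))
        if slack[worst] <= tol:
            return HullDistanceResult(float(np.linalg.norm(gap)), w, witness)
        support = np.union1d(support, [worst])
    raise RuntimeError(
        "hull_distance active-set loop failed to converge; instance: "
        f"x={x.tolist()}, points={Z.tolist()}"
    )


class NLCSClassifier:
    """Nearest-local-convex-set classifier (estimator-style API).

    Lazy learner: ``fit`` only partitions the training data by class.
    ``k`` is the per-class neighborhood size (capped at the class size);
    ``p`` the norm order (2 by default; neighborhoods support any p >= 1,
    hull distances only p = 2).  Neighbor ties break by training-set
    insertion order; class-distance ties by smallest class index.
    """

    def __init__(self, k: int = 5, p: float = 2):
        if k < 1:
            raise ValueError("k must be >= 1")
        if p < 1:
            raise ValueError("p must be >= 1")
        self.k = int(k)
        self.p = p
        self.classes_ = None
        self._partitions: list[np.ndarray] | None = None

    def fit(self, features, labels) -> "NLCSClassifier":
        X = np.atleast_2d(np.asarray(features, dtype=float))
        y = np.asarray(labels)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels must have equal length")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)  # canonical sorted label order
        self._partitions = [X[y == c] for c in self.classes_]
        return self

    def _check_fitted(self) -> None:
        if self._partitions is None:
            raise RuntimeError("classifier is not fitted")

    def _dist(self, X: np.ndarray, x: np.ndarray) -> np.ndarray:
        diff = X - x
        if self.p == 2:
            return np.sqrt(np.sum(diff * diff, axis=1))
        return np.sum(np.abs(diff) ** self.p, axis=1) ** (1.0 / self.p)

    def class_neighborhood(self, x_star, class_index: int) -> np.ndarray:
        """The min(k, |C_i|) class-i training points nearest to x*,
        ordered by distance (stable: index order breaks ties)."""
        self._check_fitted()
        pts = self._partitions[class_index]
        if pts.shape[0] == 0:
            raise ValueError(f"class {class_index} has no training points")
        x = np.asarray(x_star, dtype=float).ravel()
        if x.size != pts.shape[1]:
            raise ValueError("query dimension does not match training data")
        order = np.argsort(self._dist(pts, x), kind="stable")
        return pts[order[: min(self.k, pts.shape[0])]]

    def decision_distances(self, features) -> np.ndarray:
        """(n_queries, n_classes) matrix of local hull distances."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(features, dtype=float))
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, x in enumerate(X):
            for ci in range(len(self.classes_)):
                Z = self.class_neighborhood(x, ci)
                out[i, ci] = hull_distance(x, Z, self.p).distance
        return out

    def predict(self, features) -> np.ndarray:
        """argmin over classes of the local hull distance; ties go to
        the smallest class index."""
        dists = self.decision_distances(features)
        return self.classes_[np.argmin(dists, axis=1)]
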