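"""Regularized non-negative inversion of the discretized Fredholm system.

The spectrum estimate solves

    f_hat = argmin_{f >= 0}  ||s - K f||_2^2 + lambda ||f||_2^2,

a Tikhonov-regularized non-negative least-squares problem.  The solver
is Lawson-Hanson active-set NNLS specialised to this setting: gradients
are computed from the cached Gram matrix K^T K (so repeated inversions
against one kernel pay the large matrix product once).  Inner solves
use plain least squares on the passive kernel columns when lambda = 0,
and the ridge-stabilised normal equations on the cached Gram blocks
when lambda > 0; the ridge term never materialises as an (n + d) x n
augmented matrix.

Also provided: L-curve selection of lambda, marginalization of 3-D
spectra onto the three 2-D correlation planes (T1-T2, T1-D, T2-D), and
deterministic feature (de)vectorization for feeding classifiers.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forward import KernelMatrix, SignalVector, Spectrum

__all__ = [
    "InversionConfig",
    "Spectrum2D",
    "InversionError",
    "invert_signal",
    "choose_lambda",
    "marginalize",
    "vectorize_features",
    "devectorize",
    "PAIRS",
]

PAIRS = ("T1-T2", "T1-D", "T2-D")

# axis dropped when marginalizing, and the two retained grid axes
_PAIR_LAYOUT = {
    "T1-T2": (2, ("t1", "t2")),
    "T1-D": (1, ("t1", "d")),
    "T2-D": (0, ("t2", "d")),
}


class InversionError(RuntimeError):
    """Solver failed to converge; carries diagnostics, never silent."""


@dataclasses.dataclass(frozen=True)
class InversionConfig:
    """Settings for the regularized inversion.

    lam is the Tikhonov weight on ||f||_2^2 (0 disables regularization);
    tol is the dual-feasibility threshold relative to the gradient scale
    (None picks a machine-precision default); max_iter bounds active-set
    iterations (None -> 3 * n_nodes).  The residual norm is the 2-norm,
    the only choice with a standard NNLS solver.
    """

    lam: float = 0.0
    regularizer: str = "tikhonov_identity"
    tol: float | None = None
    max_iter: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.regularizer not in ("tikhonov_identity", "none"):
            raise ValueError("regularizer must be tikhonov_identity or none")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def effective_lam(self) -> float:
        return 0.0 if self.regularizer == "none" else float(self.lam)


def _nnls_gram(K: np.ndarray, s: np.ndarray, lam: float,
               gram: np.ndarray, tol: float | None,
               max_iter: int | None) -> tuple[np.ndarray, dict]:
    """Lawson-Hanson NNLS for min ||s - K f||^2 + lam ||f||^2, f >= 0.

    Gradient bookkeeping uses the precomputed Gram matrix restricted to
    the current passive set (cheap for sparse solutions).
    """
    d, n = K.shape
    atb = K.T @ s
    if tol is None:
        tol = 10 * np.finfo(float).eps * max(1.0, float(np.abs(atb).max(initial=0.0)))
    if max_iter is None:
        max_iter = max(3 * n, 30)

    x = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    iterations = 0

    def grad() -> np.ndarray:
        # w = K^T(s - K x) - lam x; x is nonzero only on the passive set
        if passive.any():
            w = atb - gram[:, passive] @ x[passive]
            if lam:
                w = w - lam * x
            return w
        return atb.copy()

    def solve_passive(idx: np.ndarray) -> np.ndarray:
        if lam:
            # ridge makes the normal equations well-conditioned; solving
            # them on the cached Gram blocks avoids re-factorizing the
            # (d + m) x m augmented system every active-set step
            g_pp = gram[np.ix_(idx, idx)] + lam * np.eye(idx.size)
            try:
                return np.linalg.solve(g_pp, atb[idx])
            except np.linalg.LinAlgError:
                return np.linalg.lstsq(g_pp, atb[idx], rcond=None)[0]
        return np.linalg.lstsq(K[:, idx], s, rcond=None)[0]

    while True:
        w = grad()
        w[passive] = -np.inf
        j = int(np.argmax(w))
        if w[j] <= tol:
            break
        passive[j] = True
        while True:
            iterations += 1
            if iterations > max_iter:
                raise InversionError(
                    f"NNLS failed to converge after {iterations} iterations "
                    f"(n={n}, lam={lam:g}, passive={int(passive.sum())})"
                )
            idx = np.flatnonzero(passive)
            z = solve_passive(idx)
            if z.min(initial=np.inf) > 0:
                x[:] = 0.0
                x[idx] = z
                break
            # step toward z until the first passive coordinate hits zero
            mask = z <= 0
            alpha = np.min(x[idx][mask] / (x[idx][mask] - z[mask]))
            x[idx] = x[idx] + alpha * (z - x[idx])
            drop = idx[x[idx] <= tol * max(1.0, np.abs(x[idx]).max())]
            x[drop] = 0.0
            passive[drop] = False
            if not passive.any():
                break
        if not passive.any():
            break

    x[x < 0] = 0.0
    return x, {"iterations": iterations, "support": int(np.count_nonzero(x))}


def invert_signal(signal: SignalVector, kernel: KernelMatrix,
                  config: InversionConfig | None = None) -> Spectrum:
    """Estimate the spectrum behind one signal vector.

    Returns a non-negative ``Spectrum`` whose ``meta`` records the
    residual norm, regularization weight and active-set diagnostics.
    Deterministic for fixed inputs; raises ``InversionError`` on
    non-convergence.
    """
    config = config or InversionConfig()
    K = kernel.values
    s = signal.values
    if s.size != K.shape[0]:
        raise ValueError(
            f"signal length {s.size} != kernel rows {K.shape[0]}"
        )
    lam = config.effective_lam
    f, info = _nnls_gram(K, s, lam, kernel.gram(), config.tol, config.max_iter)
    residual = float(np.linalg.norm(s - K @ f))
    meta = {"residual": residual, "lam": lam, **info}
    return Spectrum(kernel.grid, f, normalized=False, meta=meta)


@dataclasses.dataclass
class LambdaChoice:
    """Outcome of L-curve selection, with the full candidate table."""

    lam: float
    table: "np.ndarray"  # columns: lam, residual_norm, solution_norm, curvature
    degenerate: bool = False


def _menger_curvature(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Curvature of a discrete planar curve at each interior point."""
    curv = np.full(x.size, -np.inf)
    for i in range(1, x.size - 1):
        p0 = np.array([x[i - 1], y[i - 1]])
        p1 = np.array([x[i], y[i]])
        p2 = np.array([x[i + 1], y[i + 1]])
        a = np.linalg.norm(p1 - p0)
        b = np.linalg.norm(p2 - p1)
        c = np.linalg.norm(p2 - p0)
        u, v = p1 - p0, p2 - p0
        area2 = abs(u[0] * v[1] - u[1] * v[0])  # twice triangle area
        if a * b * c > 0:
            curv[i] = 2.0 * area2 / (a * b * c)
    return curv


def choose_lambda(signal: SignalVector, kernel: KernelMatrix,
                  lambda_grid, config: InversionConfig | None = None
                  ) -> LambdaChoice:
    """Pick lambda at the L-curve corner (maximum Menger curvature of
    log residual norm vs log solution norm).

    A consistent system (smallest-lambda residual numerically zero) has
    its corner at the minimum, so the smallest lambda is returned.  A
    degenerate L-curve — all residuals equal — returns the smallest
    lambda with ``degenerate=True``.  Curvature ties break toward the
    larger lambda.  The full candidate table is returned for audit.
    """
    lams = np.sort(np.asarray(lambda_grid, dtype=float))
    if lams.size == 0 or np.any(lams <= 0):
        raise ValueError("lambda_grid must be non-empty and positive")
    base = config or InversionConfig()
    residuals = np.empty(lams.size)
    norms = np.empty(lams.size)
    for i, lam in enumerate(lams):
        spec = invert_signal(signal, kernel,
                             dataclasses.replace(base, lam=float(lam)))
        residuals[i] = spec.meta["residual"]
        norms[i] = np.linalg.norm(spec.weights)

    scale = max(residuals.max(), 1e-300)
    table = np.column_stack([lams, residuals, norms,
                             np.full(lams.size, np.nan)])
    if residuals.max() - residuals.min() <= 1e-12 * max(scale, 1.0):
        return LambdaChoice(float(lams[0]), table, degenerate=True)
    # probe for a consistent system: if the data can be fit exactly, the
    # L-curve corner sits at its minimum and the smallest lambda wins
    probe = invert_signal(signal, kernel, dataclasses.replace(base, lam=0.0))
    if probe.meta["residual"] <= 1e-8 * max(
            1.0, float(np.linalg.norm(signal.values))):
        return LambdaChoice(float(lams[0]), table)
    if lams.size < 3:
        return LambdaChoice(float(lams[0]), table)
    floor = 1e-15 * scale
    curv = _menger_curvature(np.log(np.maximum(residuals, floor)),
                             np.log(np.maximum(norms, floor)))
    table[:, 3] = curv
    best = curv.max()
    chosen = np.flatnonzero(curv >= best - 1e-12 * max(abs(best), 1.0))[-1]
    return LambdaChoice(float(lams[chosen]), table)


@dataclasses.dataclass
class Spectrum2D:
    """2-D correlation map: a 3-D spectrum summed over one axis."""

    pair: str
    axis1_nodes: np.ndarray
    axis2_nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}; expected one of {PAIRS}")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.axis1_nodes), len(self.axis2_nodes)):
            raise ValueError("weights shape does not match axis nodes")
        if np.any(w < 0):
            raise ValueError("2-D spectrum weights must be non-negative")
        self.weights = w

    def total(self) -> float:
        return float(self.weights.sum())


def marginalize(spectrum: Spectrum, pair: str) -> Spectrum2D:
    """Sum the 3-D spectrum over the axis absent from ``pair``.

    Mass is conserved exactly: the 2-D total equals the 3-D total.
    """
    if pair not in _PAIR_LAYOUT:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    drop_axis, (ax1, ax2) = _PAIR_LAYOUT[pair]
    cube = spectrum.as_cube()
    weights = cube.sum(axis=drop_axis)
    return Spectrum2D(pair,
                      getattr(spectrum.grid, ax1),
                      getattr(spectrum.grid, ax2),
                      weights)


def vectorize_features(obj) -> np.ndarray:
    """Flatten a signal or spectrum into a classifier feature vector.

    Signals map to themselves; 3-D spectra use the grid's flat order;
    2-D maps are row-major over (axis1, axis2).  Deterministic, and
    invertible for spectra via :func:`devectorize`.
    """
    if isinstance(obj, SignalVector):
        return obj.values.copy()
    if isinstance(obj, Spectrum):
        return obj.weights.copy()
    if isinstance(obj, Spectrum2D):
        return obj.weights.ravel(order="C").copy()
    raise TypeError(f"cannot vectorize {type(obj).__name__}")


def devectorize(vector: np.ndarray, like) -> "Spectrum | Spectrum2D":
    """Inverse of :func:`vectorize_features` for spectrum objects."""
    vector = np.asarray(vector, dtype=float)
    if isinstance(like, Spectrum):
        return Spectrum(like.grid, vector, normalized=False)
    if isinstance(like, Spectrum2D):
        shape = (len(like.axis1_nodes), len(like.axis2_nodes))
        return Spectrum2D(like.pair, like.axis1_nodes, like.axis2_nodes,
                          vector.reshape(shape, order="C"))
    raise TypeError(f"cannot devectorize into {type(like).__name__}")
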