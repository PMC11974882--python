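import itertools

import numpy as np
import pytest

from mdmri import (AcquisitionScheme, ParameterGrid, build_kernel,
                   default_scheme)


@pytest.fixture(scope="session")
def tiny_grid() -> ParameterGrid:
    """3 x 3 x 3 grid: with the d=100 default scheme the linear system
    is overdetermined and exactly solvable."""
    return ParameterGrid(
        t1=np.array([0.1, 0.5, 2.0]),
        t2=np.array([0.01, 0.05, 0.2]),
        d=np.array([0.1, 0.5, 2.0]),
    )


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    return default_scheme()


@pytest.fixture(scope="session")
def tiny_kernel(tiny_grid, scheme):
    return build_kernel(tiny_grid, scheme)


def simplex_grid(n_points: int, steps: int) -> np.ndarray:
    """All barycentric weight vectors with coordinates k/steps."""
    rows = []
    for bars in itertools.combinations(range(steps + n_points - 1),
                                       n_points - 1):
        prev, counts = -1, []
        for b in bars:
            counts.append(b - prev - 1)
            prev = b
        counts.append(steps + n_points - 1 - prev - 1)
        rows.append(counts)
    return np.asarray(rows, dtype=float) / steps


def brute_force_hull_distance(x: np.ndarray, Z: np.ndarray,
                              steps: int = 20, rounds: int = 7) -> float:
    """Shrinking dense-grid search over the simplex: an oracle for the
    QP hull distance that shares no code with it."""
    x = np.asarray(x, dtype=float)
    Z = np.asarray(Z, dtype=float)
    W = simplex_grid(Z.shape[0], steps)
    center = np.full(Z.shape[0], 1.0 / Z.shape[0])
    best = np.inf
    for r in range(rounds):
        scale = 0.5 ** r
        Wr = (1.0 - scale) * center + scale * W
        d = np.linalg.norm(Wr @ Z - x, axis=1)
        i = int(np.argmin(d))
        if d[i] < best:
            best = float(d[i])
        center = Wr[i]
    return best
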