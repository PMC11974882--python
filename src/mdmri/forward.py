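"""Forward model for multidimensional relaxation-diffusion MRI.

A T1-T2-D acquisition varies inversion time, echo time and diffusion
weighting jointly.  Each voxel holds a non-negative joint distribution
("spectrum") f(T1, T2, D) of relaxation and diffusion values, and the
measured signal is the spectrum seen through a separable exponential
kernel — a discretized Fredholm integral equation of the first kind:

    s_i = sum_j k(alpha_j; beta_i) f_j + noise,

with acquisition tuple beta_i = (tau_i, tau_e, b) and grid node
alpha_j = (T1, T2, D).  The kernel is the standard inversion-recovery x
spin-echo x isotropic-Gaussian-diffusion product

    k(alpha; beta) = (1 - 2 exp(-tau_i/T1)) exp(-tau_e/T2) exp(-b D).

Internal units are seconds for times (T1, T2, tau_i, tau_e) and
um^2/ms for diffusivity, with b in ms/um^2, so that b*D is order one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionScheme",
    "ParameterGrid",
    "Spectrum",
    "KernelMatrix",
    "SignalVector",
    "UnitSanityWarning",
    "build_kernel",
    "simulate_signal",
    "default_grid",
    "default_scheme",
]

#: CSV column names for acquisition schemes (times in seconds, b in ms/um^2).
SCHEME_COLUMNS = ("ti_s", "te_s", "b_ms_per_um2")


class UnitSanityWarning(UserWarning):
    """Raised when b*D is so large that a unit mix-up is likely."""


@dataclasses.dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered list of acquisition tuples (tau_i, tau_e, b).

    Parameters
    ----------
    entries
        Array of shape (d, 3) with columns inversion time [s], echo
        time [s] and b-value [ms/um^2].
    allow_duplicates
        Duplicate acquisition tuples are rejected unless this is set.
    """

    entries: np.ndarray
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if entries.size == 0 or entries.shape[1] != 3:
            raise ValueError("scheme requires a non-empty (d, 3) array")
        if np.any(entries < 0) or not np.all(np.isfinite(entries)):
            raise ValueError("acquisition parameters must be finite and >= 0")
        if not self.allow_duplicates:
            if len(np.unique(entries, axis=0)) != len(entries):
                raise ValueError(
                    "duplicate acquisition tuples; pass allow_duplicates=True "
                    "to keep them"
                )
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    @property
    def d(self) -> int:
        """Number of acquisitions."""
        return self.entries.shape[0]

    @property
    def inversion_times(self) -> np.ndarray:
        return self.entries[:, 0]

    @property
    def echo_times(self) -> np.ndarray:
        return self.entries[:, 1]

    @property
    def b_values(self) -> np.ndarray:
        return self.entries[:, 2]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=list(SCHEME_COLUMNS)).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, allow_duplicates: bool = False) -> "AcquisitionScheme":
        frame = pd.read_csv(path)
        missing = set(SCHEME_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"scheme CSV missing columns: {sorted(missing)}")
        return cls(frame[list(SCHEME_COLUMNS)].to_numpy(), allow_duplicates)


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """Discretized T1 x T2 x D domain.

    Nodes are strictly increasing along each axis.  The flat index runs
    T1 slowest, T2 in the middle, D fastest:

        flat = (i1 * len(t2) + i2) * len(d) + i_d
    """

    t1: np.ndarray  # seconds
    t2: np.ndarray  # seconds
    d: np.ndarray   # um^2/ms

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "d"):
            axis = np.asarray(getattr(self, name), dtype=float)
            if axis.ndim != 1 or axis.size == 0:
                raise ValueError(f"{name} nodes must form a non-empty 1-D array")
            if np.any(axis <= 0) or not np.all(np.isfinite(axis)):
                raise ValueError(f"{name} nodes must be finite and > 0")
            if axis.size > 1 and np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} nodes must be strictly increasing")
            axis.setflags(write=False)
            object.__setattr__(self, name, axis)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.t1.size, self.t2.size, self.d.size)

    @property
    def n_nodes(self) -> int:
        n1, n2, nd = self.shape
        return n1 * n2 * nd

    def flat_index(self, i1: int, i2: int, i_d: int) -> int:
        return int(np.ravel_multi_index((i1, i2, i_d), self.shape))

    def unflatten_index(self, flat: int) -> tuple[int, int, int]:
        i1, i2, i_d = np.unravel_index(flat, self.shape)
        return int(i1), int(i2), int(i_d)

    def nodes(self) -> np.ndarray:
        """All grid nodes as an (n_nodes, 3) array in flat order."""
        g1, g2, gd = np.meshgrid(self.t1, self.t2, self.d, indexing="ij")
        return np.column_stack([g1.ravel(), g2.ravel(), gd.ravel()])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterGrid):
            return NotImplemented
        return (
            np.array_equal(self.t1, other.t1)
            and np.array_equal(self.t2, other.t2)
            and np.array_equal(self.d, other.d)
        )

    __hash__ = None  # type: ignore[assignment]


def default_grid(points_per_axis: int = 20) -> ParameterGrid:
    """Log-spaced grid spanning ex vivo tissue values.

    T1 in [0.05, 5] s, T2 in [0.005, 0.5] s, D in [0.01, 3] um^2/ms.
    """
    n = int(points_per_axis)
    return ParameterGrid(
        t1=np.geomspace(0.05, 5.0, n),
        t2=np.geomspace(0.005, 0.5, n),
        d=np.geomspace(0.01, 3.0, n),
    )


def default_scheme() -> AcquisitionScheme:
    """Factorial 5 tau_i x 5 tau_e x 4 b scheme (d = 100).

    Times are log-spaced across the sensitive ranges of the default
    grid; b-values are linearly spaced, starting at zero.
    """
    ti = np.geomspace(0.025, 7.5, 5)
    te = np.geomspace(0.0025, 0.4, 5)
    b = np.linspace(0.0, 4.5, 4)
    g_ti, g_te, g_b = np.meshgrid(ti, te, b, indexing="ij")
    return AcquisitionScheme(
        np.column_stack([g_ti.ravel(), g_te.ravel(), g_b.ravel()])
    )


@dataclasses.dataclass
class Spectrum:
    """Non-negative weights on a parameter grid (flat order).

    ``normalized=True`` asserts the weights sum to one (a probability
    distribution over water pools); raw amplitudes are also allowed.
    """

    grid: ParameterGrid
    weights: np.ndarray
    normalized: bool = False
    meta: dict | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if w.size != self.grid.n_nodes:
            raise ValueError(
                f"weights length {w.size} != grid size {self.grid.n_nodes}"
            )
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        if self.normalized and abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1 within 1e-9")
        self.weights = w

    def total(self) -> float:
        return float(self.weights.sum())

    def as_cube(self) -> np.ndarray:
        return self.weights.reshape(self.grid.shape)

    def normalize(self) -> "Spectrum":
        total = self.total()
        if total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.grid, self.weights / total, normalized=True,
                        meta=self.meta)

    def argmax_node(self) -> tuple[int, int, int]:
        return self.grid.unflatten_index(int(np.argmax(self.weights)))

    @classmethod
    def delta(cls, grid: ParameterGrid, i1: int, i2: int, i_d: int,
              weight: float = 1.0) -> "Spectrum":
        w = np.zeros(grid.n_nodes)
        w[grid.flat_index(i1, i2, i_d)] = weight
        return cls(grid, w, normalized=(weight == 1.0))


class KernelMatrix:
    """d x n_nodes discretized Fredholm kernel.

    In ``magnitude`` mode entries are absolute values (magnitude MRI
    reconstruction); ``signed`` keeps the inversion-recovery sign.  The
    Gram matrix K^T K is computed lazily and cached — it is reused by
    every inversion against the same kernel.
    """

    def __init__(self, values: np.ndarray, scheme: AcquisitionScheme,
                 grid: ParameterGrid, sign_mode: str = "magnitude") -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (scheme.d, grid.n_nodes):
            raise ValueError("kernel shape does not match scheme/grid")
        if sign_mode not in ("signed", "magnitude"):
            raise ValueError("sign_mode must be 'signed' or 'magnitude'")
        if np.any(np.abs(values) > 1.0 + 1e-12):
            raise ValueError("kernel entries must satisfy |k| <= 1")
        if sign_mode == "magnitude" and np.any(values < 0):
            raise ValueError("magnitude-mode kernel must be non-negative")
        self.values = values
        self.scheme = scheme
        self.grid = grid
        self.sign_mode = sign_mode
        self._gram: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.values.T @ self.values
        return self._gram


def build_kernel(grid: ParameterGrid, scheme: AcquisitionScheme,
                 sign_mode: str = "magnitude") -> KernelMatrix:
    """Evaluate k(alpha; beta) on every (acquisition, grid node) pair.

    Entry (i, j) is (1 - 2 exp(-ti/T1)) exp(-te/T2) exp(-b D) at
    acquisition i and node j, absolute-valued in magnitude mode.
    Deterministic; warns if max(b) * max(D) exceeds 1e3, which almost
    always indicates inconsistent units.
    """
    max_bd = float(scheme.b_values.max() * grid.d.max())
    if max_bd > 1e3:
        warnings.warn(
            f"max(b)*max(D) = {max_bd:.3g}; expected order 1-10 in "
            "ms/um^2 x um^2/ms — check units",
            UnitSanityWarning,
            stacklevel=2,
        )
    ti = scheme.inversion_times[:, None]
    te = scheme.echo_times[:, None]
    b = scheme.b_values[:, None]
    nodes = grid.nodes()
    t1, t2, diff = nodes[:, 0][None, :], nodes[:, 1][None, :], nodes[:, 2][None, :]
    values = (1.0 - 2.0 * np.exp(-ti / t1)) * np.exp(-te / t2) * np.exp(-b * diff)
    if sign_mode == "magnitude":
        values = np.abs(values)
    return KernelMatrix(values, scheme, grid, sign_mode)


@dataclasses.dataclass
class SignalVector:
    """One voxel's measurement vector, with noise provenance."""

    values: np.ndarray
    scheme: AcquisitionScheme
    noise_model: str = "none"
    snr: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.scheme.d:
            raise ValueError(
                f"signal length {v.size} != scheme.d {self.scheme.d}"
            )
        self.values = v


def simulate_signal(spectrum: Spectrum, kernel: KernelMatrix,
                    snr: float | None = None, noise_model: str = "none",
                    seed: int | None = None) -> SignalVector:
    """Project a spectrum through the kernel and add measurement noise.

    SNR is defined as (max noiseless signal) / (noise standard
    deviation).  ``rician`` forms the magnitude of a complex Gaussian
    perturbation, the standard model for magnitude-reconstructed MRI;
    ``gaussian`` adds real noise and may go negative.  Fixed seeds give
    bit-identical output.
    """
    if spectrum.grid != kernel.grid:
        raise ValueError("spectrum and kernel are on different grids")
    if noise_model not in ("none", "gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    noiseless = kernel.values @ spectrum.weights
    if noise_model == "none":
        return SignalVector(noiseless, kernel.scheme, "none", None, seed)
    if snr is None or snr <= 0:
        raise ValueError("noisy simulation requires snr > 0")
    peak = float(np.max(np.abs(noiseless)))
    if peak == 0.0:
        raise ValueError("cannot set noise level: noiseless signal is zero")
    sigma = peak / snr
    rng = np.random.default_rng(seed)
    if noise_model == "gaussian":
        values = noiseless + rng.normal(0.0, sigma, size=noiseless.size)
    else:  # rician
        real = noiseless + rng.normal(0.0, sigma, size=noiseless.size)
        imag = rng.normal(0.0, sigma, size=noiseless.size)
        values = np.hypot(real, imag)
    return SignalVector(values, kernel.scheme, noise_model, float(snr), seed)
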