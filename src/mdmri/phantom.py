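"""Synthetic two-class voxel phantoms with multi-compartment spectra.

Each voxel is a mixture of a few water compartments (e.g. a myelin-like
short-T2 pool, an intra/extracellular pool, a free-water-like pool),
each sitting at one node of the T1-T2-D grid.  The two classes — a
"lesion-like" class emulating interface astrogliosis and a matched
control — share compartment locations but differ in mean compartment
fractions by a configurable effect size.  Per-voxel biological
variability jitters the fractions on the logit scale.

``realize_dataset`` observes the truth spectra through the Fredholm
kernel with noise (the raw-signal representation Y), then inverts and
marginalizes each voxel's signal into the three 2-D correlation maps
(the processed representations Y').  Because Y' is a deterministic
function of Y and a fixed inversion configuration, the Markov chain
X -> Y -> Y' holds in the phantom by construction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit, logit

from .forward import (AcquisitionScheme, ParameterGrid, Spectrum,
                      build_kernel, default_grid, default_scheme,
                      simulate_signal)
from .inversion import (PAIRS, InversionConfig, InversionError, invert_signal,
                        marginalize, vectorize_features)

__all__ = [
    "CompartmentSpec",
    "PhantomConfig",
    "VoxelDataset",
    "astrogliosis_config",
    "make_truth_spectra",
    "realize_dataset",
    "generate_dataset",
    "make_chain_fixture",
]


@dataclasses.dataclass(frozen=True)
class CompartmentSpec:
    """One water pool: location in (T1 [s], T2 [s], D [um^2/ms]) —
    snapped to the nearest grid node in log coordinates — plus its mean
    volume fraction and a logit-scale jitter standard deviation."""

    t1: float
    t2: float
    d: float
    fraction: float
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("compartment fraction must be in (0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if min(self.t1, self.t2, self.d) <= 0:
            raise ValueError("compartment location must be positive")


def _snap(axis: np.ndarray, value: float) -> int:
    """Nearest node index in log space (the grids are log-spaced)."""
    return int(np.argmin(np.abs(np.log(axis) - np.log(value))))


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Full recipe for a phantom: class compartment lists, voxel counts,
    grid, scheme, noise and inversion settings, master seed."""

    class_specs: tuple[tuple[CompartmentSpec, ...], ...]
    voxels_per_class: int = 100
    grid: ParameterGrid = dataclasses.field(default_factory=lambda: default_grid(12))
    scheme: AcquisitionScheme = dataclasses.field(default_factory=default_scheme)
    snr: float | None = 30.0
    noise_model: str = "rician"
    inversion: InversionConfig = dataclasses.field(
        default_factory=lambda: InversionConfig(lam=1e-2))
    seed: int = 0
    n_subjects_per_class: int = 7

    def __post_init__(self) -> None:
        if len(self.class_specs) < 2:
            raise ValueError("need at least 2 classes")
        if any(len(specs) == 0 for specs in self.class_specs):
            raise ValueError("every class needs at least one compartment")
        if self.voxels_per_class < 1:
            raise ValueError("voxels_per_class must be >= 1")
        for specs in self.class_specs:
            total = sum(c.fraction for c in specs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("class compartment fractions must sum to 1")


# Shared compartment locations: myelin-like, intra/extracellular,
# free-water-like pools (T1 s, T2 s, D um^2/ms).
_POOLS = ((0.3, 0.02, 0.3), (1.0, 0.08, 0.8), (3.0, 0.3, 2.0))


def astrogliosis_config(effect_size: float = 0.15,
                        jitter: float = 0.3,
                        voxels_per_class: int = 100,
                        snr: float | None = 30.0,
                        noise_model: str = "rician",
                        seed: int = 0,
                        grid: ParameterGrid | None = None,
                        scheme: AcquisitionScheme | None = None,
                        inversion: InversionConfig | None = None,
                        ) -> PhantomConfig:
    """Default two-class phantom: control vs lesion-like tissue.

    Both classes share three pools; the lesion class moves
    ``effect_size`` of volume fraction from the intra/extracellular
    pool to the free-water-like pool, mimicking gliosis-driven
    expansion of the fast-diffusing compartment.
    """
    if not (0.0 <= effect_size < 0.55):
        raise ValueError("effect_size must be in [0, 0.55)")
    control_fracs = (0.30, 0.55, 0.15)
    lesion_fracs = (0.30, 0.55 - effect_size, 0.15 + effect_size)
    classes = tuple(
        tuple(CompartmentSpec(*loc, fraction=f, jitter=jitter)
              for loc, f in zip(_POOLS, fracs))
        for fracs in (control_fracs, lesion_fracs)
    )
    kwargs = {}
    if grid is not None:
        kwargs["grid"] = grid
    if scheme is not None:
        kwargs["scheme"] = scheme
    if inversion is not None:
        kwargs["inversion"] = inversion
    return PhantomConfig(classes, voxels_per_class=voxels_per_class,
                         snr=snr, noise_model=noise_model, seed=seed,
                         **kwargs)


def make_truth_spectra(config: PhantomConfig) -> tuple[list[Spectrum], np.ndarray]:
    """Draw per-voxel ground-truth spectra and integer class labels.

    Each voxel perturbs its class's mean fractions on the logit scale
    (logit-normal jitter), renormalizes to sum to one, and places the
    mass on the snapped grid nodes.  Two compartments snapping to the
    same node are merged with a warning.  Fully seeded.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    spectra: list[Spectrum] = []
    labels = np.repeat(np.arange(len(config.class_specs)),
                       config.voxels_per_class)
    for class_idx, specs in enumerate(config.class_specs):
        flat_nodes = []
        for c in specs:
            idx = grid.flat_index(_snap(grid.t1, c.t1),
                                  _snap(grid.t2, c.t2),
                                  _snap(grid.d, c.d))
            flat_nodes.append(idx)
        if len(set(flat_nodes)) != len(flat_nodes):
            warnings.warn(
                f"class {class_idx}: compartments snapped to the same grid "
                "node; their masses are merged", stacklevel=2)
        mean_fracs = np.array([c.fraction for c in specs])
        jitters = np.array([c.jitter for c in specs])
        for _ in range(config.voxels_per_class):
            z = rng.normal(0.0, 1.0, size=len(specs))
            fracs = expit(logit(mean_fracs) + jitters * z)
            fracs = fracs / fracs.sum()
            w = np.zeros(grid.n_nodes)
            for idx, f in zip(flat_nodes, fracs):
                w[idx] += f
            spectra.append(Spectrum(grid, w, normalized=True))
    return spectra, labels


@dataclasses.dataclass
class VoxelDataset:
    """Row-aligned feature blocks for one phantom realization.

    ``signals`` is n x d (representation Y); ``spectra2d`` maps each
    axis pair to an n x m block of vectorized 2-D correlation maps
    (representations Y'); ``labels`` are the class codes X.  Voxels
    whose inversion failed are recorded in ``failed_voxels`` and carry
    NaN rows, never silently imputed values.
    """

    signals: np.ndarray
    spectra2d: dict[str, np.ndarray]
    labels: np.ndarray
    truth: np.ndarray
    subjects: np.ndarray
    config: PhantomConfig
    failed_voxels: list[int] = dataclasses.field(default_factory=list)

    REPRESENTATIONS = ("signal",) + PAIRS

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]

    def features(self, representation: str) -> np.ndarray:
        """Feature block for 'signal', 'T1-T2', 'T1-D' or 'T2-D'."""
        if representation == "signal":
            return self.signals
        if representation in self.spectra2d:
            return self.spectra2d[representation]
        raise KeyError(
            f"unknown representation {representation!r}; "
            f"available: {self.REPRESENTATIONS}"
        )


def realize_dataset(spectra: list[Spectrum], labels: np.ndarray,
                    config: PhantomConfig) -> VoxelDataset:
    """Observe truth spectra as noisy signals, then invert and
    marginalize each voxel.

    Per-voxel noise streams derive from the master seed as
    ``seed + voxel_index`` for reproducible parallelism; identical
    configs give bit-identical datasets.  Y' is computed from Y alone,
    so X -> Y -> Y' is Markov by construction.
    """
    kernel = build_kernel(config.grid, config.scheme)
    n = len(spectra)
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels and spectra must align")
    signals = np.empty((n, config.scheme.d))
    blocks: dict[str, np.ndarray] = {}
    failed: list[int] = []
    for i, spec in enumerate(spectra):
        sig = simulate_signal(spec, kernel, snr=config.snr,
                              noise_model=config.noise_model,
                              seed=config.seed + i)
        signals[i] = sig.values
        try:
            est = invert_signal(sig, kernel, config.inversion)
        except InversionError:
            failed.append(i)
            est = None
        for pair in PAIRS:
            if pair not in blocks:
                m = marginalize(spectra[0], pair).weights.size
                blocks[pair] = np.full((n, m), np.nan)
            if est is not None:
                blocks[pair][i] = vectorize_features(marginalize(est, pair))
    truth = np.vstack([s.weights for s in spectra])
    subjects = _pseudo_subjects(labels, config.n_subjects_per_class)
    return VoxelDataset(signals, blocks, labels, truth, subjects, config,
                        failed)


def _pseudo_subjects(labels: np.ndarray, per_class: int) -> np.ndarray:
    """Deterministic round-robin grouping of voxels into pseudo-subjects
    (metadata only; mirrors a 7 + 7 subject layout by default)."""
    subjects = np.empty(labels.shape[0], dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        subjects[idx] = int(c) * per_class + (np.arange(idx.size) % per_class)
    return subjects


def generate_dataset(config: PhantomConfig) -> VoxelDataset:
    """Convenience: truth spectra + realization in one seeded call."""
    spectra, labels = make_truth_spectra(config)
    return realize_dataset(spectra, labels, config)


def make_chain_fixture(sizes: tuple[int, int, int] = (2, 2, 2),
                       seed: int = 0,
                       deterministic: bool = False,
                       concentration: float = 1.0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random discrete Markov chain X -> Y -> Y' for bound demos.

    Returns (p_x, channel X->Y, channel Y->Y').  Rows are Dirichlet
    draws (valid stochastic matrices); ``deterministic=True`` yields
    permutation-matrix channels instead (square sizes required).
    """
    nx, ny, nyp = sizes
    if min(sizes) < 2:
        raise ValueError("all support sizes must be >= 2")
    rng = np.random.default_rng(seed)
    if deterministic:
        if not (nx == ny == nyp):
            raise ValueError("deterministic channels require equal sizes")
        p_x = rng.dirichlet(np.full(nx, concentration))
        ch_xy = np.eye(ny)[rng.permutation(ny)]
        ch_yyp = np.eye(nyp)[rng.permutation(nyp)]
        return p_x, ch_xy, ch_yyp
    p_x = rng.dirichlet(np.full(nx, concentration))
    ch_xy = rng.dirichlet(np.full(ny, concentration), size=nx)
    ch_yyp = rng.dirichlet(np.full(nyp, concentration), size=ny)
    return p_x, ch_xy, ch_yyp
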