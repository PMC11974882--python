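"""Paired-bootstrap benchmark of classifiers across data representations.

Protocol: n_boot (default 30) seeded repetitions; in each repetition the
voxel pool is split 50/50 into training and testing sets, and the same
split indices are reused for every (method, representation) cell — the
pairing that licenses within-repetition comparison.  Methods are 2-NN,
MLP, LDA and the nearest-local-convex-set classifier; representations
are the raw signal Y and the three vectorized 2-D correlation maps
T1-D, T2-D, T1-T2.  Each cell is scored by Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),

the observed test-set agreement p_o corrected for the chance agreement
p_e implied by the label marginals.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier

from .nlcs import NLCSClassifier
from .phantom import VoxelDataset

__all__ = [
    "BenchmarkConfig",
    "KappaResult",
    "KappaReport",
    "cohen_kappa",
    "paired_bootstrap_splits",
    "baseline_classifier",
    "make_classifier",
    "run_benchmark",
    "METHODS",
    "REPRESENTATIONS",
]

METHODS = ("2-NN", "MLP", "LDA", "NLCS")
REPRESENTATIONS = ("T1-D", "T2-D", "T1-T2", "signal")


class KappaResult(NamedTuple):
    kappa: float
    p_o: float
    p_e: float


def cohen_kappa(true_labels, predicted_labels) -> KappaResult:
    """Chance-corrected agreement between two label sequences.

    p_e comes from the product of the two sequences' marginal label
    frequencies.  The degenerate case p_e = 1 (both sequences constant
    on the same class) is defined as kappa = 1 when agreement is
    perfect and raises otherwise.
    """
    y_true = np.asarray(true_labels).ravel()
    y_pred = np.asarray(predicted_labels).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label sequences must be non-empty and equal length")
    n = y_true.size
    labels = np.unique(np.concatenate([y_true, y_pred]))
    p_o = float(np.mean(y_true == y_pred))
    p_e = 0.0
    for lab in labels:
        p_e += np.mean(y_true == lab) * np.mean(y_pred == lab)
    p_e = float(p_e)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0:
            return KappaResult(1.0, p_o, p_e)
        raise ValueError(
            "kappa undefined: chance agreement is 1 but observed "
            f"agreement is {p_o:.3f}"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(float(np.clip(kappa, -1.0, 1.0)), p_o, p_e)


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    """Protocol settings.  Defaults reproduce the 4 methods x 4
    representations grid with 30 paired 50/50 resamples."""

    n_boot: int = 30
    split: float = 0.5
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    representations: tuple[str, ...] = REPRESENTATIONS
    nlcs_k: int = 5
    nlcs_p: float = 2
    knn_neighbors: int = 2
    mlp_hidden: int = 64
    mlp_max_iter: int = 500
    with_replacement: bool = False
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.split < 1.0):
            raise ValueError("split fraction must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not self.methods or not self.representations:
            raise ValueError("method and representation lists must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def paired_bootstrap_splits(n_samples: int, labels=None,
                            config: BenchmarkConfig | None = None
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """The shared train/test index lists, one pair per repetition.

    Repetition b uses rng seed ``config.seed + b``; train and test are
    disjoint with sizes floor(n * split) and the remainder.  When
    labels are given, draws leaving any class absent from the training
    set are redrawn (at most ``max_redraws`` times, then error).  With
    ``with_replacement=True`` the training indices are a bootstrap
    resample of the training half instead of the half itself.
    """
    config = config or BenchmarkConfig()
    if n_samples < 4:
        raise ValueError("need at least 4 samples to split")
    labels = None if labels is None else np.asarray(labels)
    n_train = int(np.floor(n_samples * config.split))
    classes = None if labels is None else np.unique(labels)
    splits = []
    for b in range(config.n_boot):
        rng = np.random.default_rng(config.seed + b)
        for attempt in range(config.max_redraws + 1):
            perm = rng.permutation(n_samples)
            train, test = perm[:n_train], perm[n_train:]
            if config.with_replacement:
                train = train[rng.integers(0, n_train, size=n_train)]
            if classes is None or np.all(
                    np.isin(classes, labels[train])):
                break
        else:
            raise RuntimeError(
                f"bootstrap {b}: no split kept every class in training "
                f"after {config.max_redraws} redraws"
            )
        splits.append((train, test))
    return splits


def baseline_classifier(name: str, seed: int = 0,
                        config: BenchmarkConfig | None = None):
    """Standard classifiers behind the shared fit/predict contract.

    2-NN: Euclidean 2-nearest-neighbor vote.  MLP: one hidden layer
    (64 units), max 500 iterations, no early stopping, seeded.  LDA:
    eigen solver with automatic Ledoit-Wolf shrinkage (handles singular
    within-class covariance).
    """
    config = config or BenchmarkConfig()
    if name == "2-NN":
        return KNeighborsClassifier(n_neighbors=config.knn_neighbors)
    if name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(config.mlp_hidden,),
                             max_iter=config.mlp_max_iter,
                             early_stopping=False,
                             random_state=int(seed) % (2**32))
    if name == "LDA":
        return ShrinkageLDA()
    raise ValueError(f"unknown baseline {name!r}")


class ShrinkageLDA:
    """LDA with automatic Ledoit-Wolf shrinkage (eigen solver) and a
    nearest-centroid fallback — the identity-covariance limit of LDA —
    for the degenerate case of exactly zero within-class scatter, where
    shrinkage cannot rescue the eigendecomposition.  ``fallback_used``
    records when the fallback fired."""

    def __init__(self) -> None:
        self._model = None
        self.fallback_used = False

    def fit(self, X, y) -> "ShrinkageLDA":
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
        try:
            lda.fit(X, y)
            self._model = lda
        except (np.linalg.LinAlgError, ValueError):
            self.fallback_used = True
            self._model = NearestCentroid().fit(X, y)
        return self

    def predict(self, X):
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        return self._model.predict(X)


def make_classifier(name: str, seed: int = 0,
                    config: BenchmarkConfig | None = None):
    """Any benchmark method (baselines or NLCS) as a fresh estimator."""
    config = config or BenchmarkConfig()
    if name == "NLCS":
        return NLCSClassifier(k=config.nlcs_k, p=config.nlcs_p)
    return baseline_classifier(name, seed=seed, config=config)


@dataclasses.dataclass
class KappaReport:
    """Bootstrap kappa distributions for every (method, representation).

    ``kappas[(method, rep)]`` holds one kappa per successful bootstrap;
    ``failures`` counts bootstraps where the method errored (scored as
    missing, never imputed).  ``split_tests`` records the shared test
    index lists so the pairing invariant can be audited byte-exactly.
    """

    config: BenchmarkConfig
    kappas: dict[tuple[str, str], np.ndarray]
    failures: dict[tuple[str, str], int]
    split_tests: list[np.ndarray]

    def mean(self, method: str, representation: str) -> float:
        return float(np.mean(self.kappas[(method, representation)]))

    def std(self, method: str, representation: str) -> float:
        return float(np.std(self.kappas[(method, representation)], ddof=1))

    def mean_table(self) -> "np.ndarray":
        """Means arranged methods x representations (the Table-style grid)."""
        return np.array([[self.mean(m, r) for r in self.config.representations]
                         for m in self.config.methods])

    def annotations(self) -> dict[str, list[str]]:
        """Row-wise and column-wise argmax cells of the mean grid."""
        grid = self.mean_table()
        rows = [f"{m}:{self.config.representations[int(np.argmax(grid[i]))]}"
                for i, m in enumerate(self.config.methods)]
        cols = [f"{r}:{self.config.methods[int(np.argmax(grid[:, j]))]}"
                for j, r in enumerate(self.config.representations)]
        return {"row_max": rows, "col_max": cols}

    def to_frame(self):
        """Long-format pandas frame: one row per bootstrap x cell."""
        import pandas as pd

        records = []
        for (m, r), vals in self.kappas.items():
            for b, v in enumerate(vals):
                records.append({"method": m, "representation": r,
                                "bootstrap": b, "kappa": v})
        return pd.DataFrame.from_records(records)


def run_benchmark(dataset: VoxelDataset,
                  config: BenchmarkConfig | None = None) -> KappaReport:
    """Execute the full paired protocol on one phantom dataset.

    For each bootstrap split, every method is fit on the training rows
    of every representation and scored by Cohen's kappa on the shared
    test rows.  The pairing invariant — identical split indices across
    all cells of a bootstrap — is asserted, not assumed.  Fully seeded.
    """
    config = config or BenchmarkConfig()
    for rep in config.representations:
        dataset.features(rep)  # raises early on a missing representation
    labels = dataset.labels
    splits = paired_bootstrap_splits(dataset.n_voxels, labels, config)

    kappas = {(m, r): [] for m in config.methods
              for r in config.representations}
    failures = {key: 0 for key in kappas}
    split_tests = [test.copy() for _, test in splits]

    for b, (train, test) in enumerate(splits):
        assert np.array_equal(test, split_tests[b]), "pairing invariant broken"
        for rep in config.representations:
            X = dataset.features(rep)
            x_tr, x_te = X[train], X[test]
            y_tr, y_te = labels[train], labels[test]
            for method in config.methods:
                clf = make_classifier(method, seed=config.seed + b,
                                      config=config)
                try:
                    clf.fit(x_tr, y_tr)
                    pred = clf.predict(x_te)
                    kappas[(method, rep)].append(
                        cohen_kappa(y_te, pred).kappa)
                except Exception:
                    failures[(method, rep)] += 1
    report = KappaReport(
        config=config,
        kappas={k: np.asarray(v, dtype=float) for k, v in kappas.items()},
        failures=failures,
        split_tests=split_tests,
    )
    for key, vals in report.kappas.items():
        if vals.size == 0:
            raise RuntimeError(f"every bootstrap failed for cell {key}")
    return report
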