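import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from mdmri import (BenchmarkConfig, astrogliosis_config, baseline_classifier,
                   bounds_report, cohen_kappa, default_grid, dpi_audit,
                   generate_dataset, make_chain_fixture, make_classifier,
                   paired_bootstrap_splits, run_benchmark)


def labels_from_confusion(table):
    """Expand a confusion matrix into (true, predicted) sequences."""
    y_true, y_pred = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            y_true += [i] * count
            y_pred += [j] * count
    return np.array(y_true), np.array(y_pred)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]).kappa == 1.0

    def test_hand_computed_confusion_table(self):
        """[[20, 5], [10, 15]] (n=50): p_o = 0.7, p_e = 0.5, kappa = 0.4."""
        y_true, y_pred = labels_from_confusion([[20, 5], [10, 15]])
        result = cohen_kappa(y_true, y_pred)
        assert result.p_o == pytest.approx(0.7)
        assert result.p_e == pytest.approx(0.5)
        assert result.kappa == pytest.approx(0.4)

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=10_000)
        assert abs(cohen_kappa(y, rng.permutation(y)).kappa) < 0.05

    def test_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(2, 5))
            y1 = rng.integers(0, k, size=n)
            y2 = rng.integers(0, k, size=n)
            assert cohen_kappa(y1, y2).kappa == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12)

    def test_degenerate_chance_agreement(self):
        # both sequences constant on the same class: p_e = 1 with
        # perfect agreement, defined as kappa = 1
        assert cohen_kappa([1, 1, 1], [1, 1, 1]).kappa == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cohen_kappa([], [])
        with pytest.raises(ValueError):
            cohen_kappa([0, 1], [0])


class TestPairedSplits:
    def test_minimal_balanced_split(self):
        splits = paired_bootstrap_splits(
            4, labels=[0, 0, 1, 1], config=BenchmarkConfig(n_boot=1, seed=0))
        train, test = splits[0]
        assert len(train) == 2 and len(test) == 2
        assert not set(train) & set(test)

    def test_determinism(self):
        cfg = BenchmarkConfig(n_boot=5, seed=3)
        a = paired_bootstrap_splits(30, config=cfg)
        b = paired_bootstrap_splits(30, config=cfg)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_every_train_set_contains_every_class(self):
        labels = np.repeat([0, 1], 100)
        splits = paired_bootstrap_splits(
            200, labels=labels, config=BenchmarkConfig(n_boot=30, seed=0))
        assert len(splits) == 30
        for train, test in splits:
            assert set(labels[train]) == {0, 1}
            assert len(train) == 100 and len(test) == 100
            assert not set(train) & set(test)

    def test_with_replacement_mode(self):
        cfg = BenchmarkConfig(n_boot=3, seed=0, with_replacement=True)
        for train, test in paired_bootstrap_splits(40, config=cfg):
            assert len(train) == 20
            assert not set(train) & set(test)  # test stays held out

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            paired_bootstrap_splits(3)


class TestBaselines:
    def test_2nn_predicts_duplicated_training_point(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        y = np.array([0, 0, 1, 1])
        clf = baseline_classifier("2-NN").fit(X, y)
        assert clf.predict([[0, 0]])[0] == 0

    def test_lda_separates_well_separated_gaussians(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-2, 1, size=(100, 2)),
                            rng.normal(2, 1, size=(100, 2))])
        y = np.repeat([0, 1], 100)
        idx = rng.permutation(200)
        clf = baseline_classifier("LDA").fit(X[idx[:100]], y[idx[:100]])
        acc = np.mean(clf.predict(X[idx[100:]]) == y[idx[100:]])
        assert acc > 0.95

    def test_mlp_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        Xq = rng.normal(size=(20, 4))
        a = baseline_classifier("MLP", seed=7).fit(X, y).predict(Xq)
        b = baseline_classifier("MLP", seed=7).fit(X, y).predict(Xq)
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            baseline_classifier("SVM")


@pytest.fixture(scope="module")
def separable_dataset():
    """Zero jitter, no noise: classes are two distinct points in every
    representation."""
    config = astrogliosis_config(jitter=0.0, snr=None, noise_model="none",
                                 voxels_per_class=20, grid=default_grid(6),
                                 seed=0)
    return generate_dataset(config)


class TestRunBenchmark:
    def test_separable_smoke_all_cells_perfect(self, separable_dataset):
        report = run_benchmark(separable_dataset,
                               BenchmarkConfig(n_boot=3, seed=0))
        for vals in report.kappas.values():
            np.testing.assert_array_equal(vals, 1.0)
        assert all(v == 0 for v in report.failures.values())

    def test_report_grid_shape_and_annotations(self, separable_dataset):
        report = run_benchmark(separable_dataset,
                               BenchmarkConfig(n_boot=2, seed=0))
        assert report.mean_table().shape == (4, 4)
        ann = report.annotations()
        assert len(ann["row_max"]) == 4 and len(ann["col_max"]) == 4
        frame = report.to_frame()
        assert len(frame) == 4 * 4 * 2

    def test_single_cell_reduces_to_direct_fit_predict(self, separable_dataset):
        cfg = BenchmarkConfig(n_boot=1, seed=5, methods=("LDA",),
                              representations=("signal",))
        report = run_benchmark(separable_dataset, cfg)
        train, test = paired_bootstrap_splits(
            separable_dataset.n_voxels, separable_dataset.labels, cfg)[0]
        clf = make_classifier("LDA", seed=5, config=cfg)
        clf.fit(separable_dataset.signals[train],
                separable_dataset.labels[train])
        direct = cohen_kappa(separable_dataset.labels[test],
                             clf.predict(separable_dataset.signals[test])).kappa
        assert report.kappas[("LDA", "signal")][0] == pytest.approx(direct)

    def test_pairing_invariant_across_cells(self, separable_dataset):
        cfg = BenchmarkConfig(n_boot=4, seed=2)
        report = run_benchmark(separable_dataset, cfg)
        reference = paired_bootstrap_splits(
            separable_dataset.n_voxels, separable_dataset.labels, cfg)
        for b, (_, test) in enumerate(reference):
            assert report.split_tests[b].tobytes() == test.tobytes()

    def test_kappa_bounds_respected(self, separable_dataset):
        report = run_benchmark(separable_dataset,
                               BenchmarkConfig(n_boot=2, seed=9))
        for vals in report.kappas.values():
            assert np.all(vals >= -1.0) and np.all(vals <= 1.0)

    def test_missing_representation_raises(self, separable_dataset):
        cfg = BenchmarkConfig(representations=("signal",))
        ok = run_benchmark(separable_dataset,
                           BenchmarkConfig(n_boot=1, methods=("2-NN",),
                                           representations=("signal",)))
        assert ("2-NN", "signal") in ok.kappas
        import dataclasses as dc
        broken = dc.replace(separable_dataset.config)
        ds = separable_dataset
        ds2 = type(ds)(ds.signals, {}, ds.labels, ds.truth, ds.subjects,
                       broken)
        with pytest.raises(KeyError):
            run_benchmark(ds2, BenchmarkConfig(n_boot=1))


class TestTheoryConsistency:
    def test_empirical_error_respects_fano_bound(self):
        """On a discrete chain with known joint, the holdout error of a
        plug-in MAP predictor cannot beat the clamped Fano lower bound
        computed exactly from the chain (up to sampling slack)."""
        p_x, ch_xy, _ = make_chain_fixture((4, 4, 4), seed=21,
                                           concentration=0.6)
        joint = p_x[:, None] * ch_xy
        rep = bounds_report(joint)
        rng = np.random.default_rng(0)
        n = 20_000
        flat = rng.choice(16, size=2 * n, p=joint.ravel())
        x, y = np.divmod(flat, 4)
        counts = np.zeros((4, 4))
        np.add.at(counts, (x[:n], y[:n]), 1)
        map_rule = np.argmax(counts, axis=0)  # predict x from y
        err = np.mean(map_rule[y[n:]] != x[n:])
        assert err >= rep.fano_lower_clamped - 0.02
        # and the exact MAP error respects the sandwich
        assert rep.fano_lower <= rep.bayes_error <= rep.hellman_raviv_upper

    def test_dpi_on_phantom_style_chains(self):
        margins = [dpi_audit(*make_chain_fixture(
            tuple(np.random.default_rng(s).integers(2, 5, size=3)),
            seed=s)).margin for s in range(25)]
        assert min(margins) >= -1e-10
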