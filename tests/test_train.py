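import numpy as np
import pytest

from conftest import no_augment
from woundfusion import (
    DatasetSplit,
    NetworkConfig,
    SplitSpec,
    TrainConfig,
    aggregate_fold_accuracies,
    build_network,
    cross_entropy,
    evaluate,
    run_crossval,
    run_experiment_grid,
    split_dataset,
    train,
)
from woundfusion.metrics import compute_metrics
from woundfusion.nn import Adam, Parameter, ReduceLROnPlateau


class TestCrossEntropy:
    def test_perfect_prediction_costs_nothing(self):
        assert cross_entropy(np.array([0.0, 1.0, 0.0]), 1) == 0.0

    def test_uniform_prediction_costs_log_k(self):
        p = np.full(6, 1 / 6)
        assert abs(cross_entropy(p, 3) - np.log(6)) < 1e-12

    def test_binary_form(self):
        assert abs(cross_entropy(np.float64(0.8), 1) - 0.2231435513) < 1e-9
        assert abs(cross_entropy(np.float64(0.8), 0) - (-np.log(0.2))) < 1e-9

    def test_one_hot_label_form_equals_index_form(self, rng):
        p = rng.dirichlet(np.ones(5))
        y = np.zeros(5)
        y[2] = 1.0
        assert abs(cross_entropy(p, y) - cross_entropy(p, 2)) < 1e-12

    def test_matches_explicit_sum_oracle_on_random_batches(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(K))
            y = int(rng.integers(K))
            oracle = -sum((1.0 if i == y else 0.0) * np.log(max(p[i], 1e-12)) for i in range(K))
            assert abs(cross_entropy(p, y) - oracle) < 1e-7

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.2]), 0)  # does not sum to 1
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.5]), 5)  # label out of range


class TestMetrics:
    def test_all_correct_gives_perfect_scores(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = compute_metrics(y, y, classes=("a", "b", "c"))
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 100.0

    def test_binary_confusion_algebra(self):
        # TP=9, FN=1 (class 1 positive), FP=2, TN=8
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [1] * 2 + [0] * 8)
        rep = compute_metrics(y_true, y_pred, classes=("neg", "pos"))
        assert rep.accuracy == 85.0
        # closed forms: prec_pos 9/11, rec_pos 0.9; prec_neg 8/9, rec_neg 0.8
        w_prec = 100 * (0.5 * 8 / 9 + 0.5 * 9 / 11)
        w_rec = 100 * (0.5 * 0.8 + 0.5 * 0.9)
        assert abs(rep.precision - w_prec) < 1e-9
        assert abs(rep.recall - w_rec) < 1e-9
        np.testing.assert_array_equal(rep.confusion, [[8, 2], [1, 9]])

    def test_weighted_recall_equals_accuracy_on_random_evaluations(self, rng):
        for _ in range(25):
            K = int(rng.integers(2, 7))
            n = int(rng.integers(5, 60))
            y_true = rng.integers(K, size=n)
            y_pred = rng.integers(K, size=n)
            rep = compute_metrics(y_true, y_pred, classes=tuple("abcdefg"[:K]))
            assert abs(rep.recall - rep.accuracy) < 1e-9

    def test_confusion_rows_sum_to_class_support(self, rng):
        y_true = rng.integers(4, size=40)
        y_pred = rng.integers(4, size=40)
        rep = compute_metrics(y_true, y_pred, classes=("a", "b", "c", "d"))
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), np.bincount(y_true, minlength=4))
        assert rep.confusion.sum() == 40

    def test_absent_class_flagged_undefined(self):
        rep = compute_metrics(np.array([0, 0, 1]), np.array([0, 1, 1]), classes=("a", "b", "c"))
        assert rep.per_class["c"]["recall"] is None
        assert abs(rep.recall - rep.accuracy) < 1e-9

    def test_roc_curves_emitted_per_present_class(self, rng):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8], [0.4, 0.6]])
        rep = compute_metrics(y, probs.argmax(1), probs, classes=("a", "b"))
        assert set(rep.roc) == {"a", "b"}
        assert rep.roc["b"]["tpr"][-1] == 1.0


class TestScheduler:
    def test_plateau_decay_reaches_floor_and_stays(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1e-4)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2, min_lr=1e-5)
        lrs = []
        for _ in range(40):  # constant validation loss: permanent plateau
            sched.step(1.0)
            lrs.append(opt.lr)
        assert lrs[-1] == 1e-5
        assert min(lrs) == 1e-5  # never below the floor
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))  # monotone decay


class TestTrainingLoop:
    def _tiny_run(self, dataset, seed, epochs=2, use_location=False):
        ds = split_dataset(dataset, SplitSpec((0.6, 0.2, 0.2), seed=seed))
        cfg = NetworkConfig(num_classes=len(dataset.classes), image_size=32,
                            use_location=use_location, dropout=0.0)
        net = build_network(cfg, seed=seed)
        tc = TrainConfig(batch_size=8, epochs=epochs, lr=3e-3, lr_min=3e-5, seed=seed)
        return train(net, ds, tc, no_augment()), ds

    def test_two_runs_same_seed_identical_first_epoch_loss(self, small_dataset):
        (_, h1), _ = self._tiny_run(small_dataset, seed=4)
        (_, h2), _ = self._tiny_run(small_dataset, seed=4)
        assert h1[0]["train_loss"] == h2[0]["train_loss"]
        assert h1[-1]["val_acc"] == h2[-1]["val_acc"]

    def test_history_records_all_fields(self, small_dataset):
        (_, hist), _ = self._tiny_run(small_dataset, seed=2)
        for entry in hist:
            assert {"epoch", "train_loss", "lr", "val_loss", "val_acc"} <= set(entry)

    def test_loss_decreases_on_separable_data_median_over_seeds(self, small_dataset):
        deltas = []
        for seed in range(5):
            (_, hist), _ = self._tiny_run(small_dataset, seed=seed, epochs=4)
            deltas.append(hist[0]["train_loss"] - hist[-1]["train_loss"])
        assert np.median(deltas) > 0

    def test_empty_training_set_rejected(self, small_dataset):
        ds = split_dataset(small_dataset, SplitSpec((0.6, 0.2, 0.2), seed=0))
        empty = DatasetSplit(ds.train.__class__([], ds.train.classes), ds.val, ds.test)
        net = build_network(NetworkConfig(num_classes=6, image_size=32), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, empty, TrainConfig(epochs=1), no_augment())

    def test_evaluation_report_is_consistent(self, small_dataset):
        (net_hist, ds) = self._tiny_run(small_dataset, seed=1)
        net, _ = net_hist
        rep = evaluate(net, ds.test, no_augment())
        assert rep.n == len(ds.test)
        assert abs(rep.recall - rep.accuracy) < 1e-9
        assert rep.confusion.sum() == len(ds.test)


class TestCrossValidation:
    def test_aggregation_of_published_fold_accuracies(self):
        assert aggregate_fold_accuracies([80.01, 80.01, 82.72, 85.34, 84.81]) == 82.58
        assert aggregate_fold_accuracies([81.42, 80.71, 80.71, 81.42, 87.14]) == 82.28

    def test_identical_fold_accuracies_average_to_themselves(self):
        assert aggregate_fold_accuracies([77.77] * 5) == 77.77

    def test_end_to_end_two_folds(self, small_dataset):
        cfg = NetworkConfig(num_classes=6, image_size=32, dropout=0.0)
        tc = TrainConfig(batch_size=8, epochs=2, lr=3e-3, lr_min=3e-5, seed=0)
        result = run_crossval(small_dataset, cfg, tc, k=2, augment=no_augment())
        assert len(result["fold_accuracies"]) == 2
        assert result["avg"] == aggregate_fold_accuracies(result["fold_accuracies"])


class TestExperimentGrid:
    def test_grid_shape_and_determinism(self, small_dataset):
        cfg = NetworkConfig(num_classes=6, image_size=32, dropout=0.0)
        tc = TrainConfig(batch_size=8, epochs=2, lr=3e-3, lr_min=3e-5, seed=0)
        subsets = [("N", "D"), ("D", "P", "S", "V")]
        splits = [SplitSpec((0.6, 0.2, 0.2), seed=0), SplitSpec((0.5, 0.25, 0.25), seed=0)]
        rows = run_experiment_grid(small_dataset, subsets, splits, cfg, tc, no_augment())
        assert len(rows) == 4
        assert all({"classes", "split"} <= set(r) for r in rows)
        assert all(("A" in r) or ("error" in r) for r in rows)
        rows2 = run_experiment_grid(small_dataset, subsets, splits, cfg, tc, no_augment())
        assert rows == rows2

    def test_failing_cell_is_recorded_not_raised(self, small_dataset):
        cfg = NetworkConfig(num_classes=6, image_size=32)
        tc = TrainConfig(batch_size=8, epochs=1, seed=0)
        rows = run_experiment_grid(
            small_dataset, [("N", "Q")], [SplitSpec((0.7, 0.15, 0.15), seed=0)], cfg, tc
        )
        assert "error" in rows[0] and "Q" in rows[0]["error"]
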