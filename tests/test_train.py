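"""Metrics arithmetic, LR schedule, training loop and CV contracts."""
import numpy as np
import pytest

from hprnet import (ConfusionTable, ModelConfig, SynthConfig, TrainConfig,
                    build_model, cross_validate, evaluate,
                    metrics_from_confusion, synth_dataset, train_fold)
from hprnet.beats import make_folds
from hprnet.train import (Adam, ReduceLROnPlateau, macro_f1_from_class_f1)


class TestMetrics:
    def test_binary_worked_example(self):
        # TP=8, FP=2, FN=2, TN=88 for the positive class
        y_true = [1] * 10 + [0] * 90
        y_pred = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 88
        table = ConfusionTable(y_true, y_pred, 2)
        assert table.class_counts(1) == (8, 2, 2, 88)
        rep = metrics_from_confusion(table, ["neg", "pos"])
        assert rep.precision[1] == pytest.approx(0.80)
        assert rep.recall[1] == pytest.approx(0.80)
        assert rep.f1[1] == pytest.approx(0.80)

    def test_perfect_predictions(self):
        y = np.repeat(np.arange(4), 10)
        rep = metrics_from_confusion(ConfusionTable(y, y, 4), list("NSVF"))
        assert rep.accuracy == 1.0
        np.testing.assert_allclose(rep.f1, 1.0)

    def test_accuracy_equals_diagonal_fraction(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        table = ConfusionTable(y_true, y_pred, 4)
        rep = metrics_from_confusion(table, list("NSVF"))
        assert rep.accuracy == pytest.approx(
            np.trace(table.matrix) / table.matrix.sum())
        # pooled one-vs-rest counts reduce to the same quantity
        tp = sum(table.class_counts(c)[0] for c in range(4))
        assert rep.accuracy == pytest.approx(tp / table.n)

    def test_macro_f1_is_unweighted_mean(self):
        vals = [99.64, 90.43, 98.42, 81.01]
        assert macro_f1_from_class_f1(vals) == pytest.approx(92.375)
        assert round(macro_f1_from_class_f1(vals), 2) == 92.38

    def test_absent_class_scores_zero_with_warning(self, caplog):
        y_true = [0, 0, 1]
        y_pred = [0, 1, 1]
        with caplog.at_level("WARNING"):
            rep = metrics_from_confusion(ConfusionTable(y_true, y_pred, 3),
                                         ["a", "b", "c"])
        assert rep.recall[2] == 0.0
        assert "c" in caplog.text

    def test_row_normalized_rows_sum_to_one(self):
        table = ConfusionTable([0, 0, 1, 2], [0, 1, 1, 0], 3)
        rn = table.row_normalized()
        np.testing.assert_allclose(rn.sum(axis=1), 1.0)

    def test_confusion_invariants(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        table = ConfusionTable(y_true, y_pred, 3)
        assert table.n == 50
        for c in range(3):
            assert sum(table.class_counts(c)) == 50

    def test_against_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 4, 300)
        y_pred = rng.integers(0, 4, 300)
        rep = metrics_from_confusion(ConfusionTable(y_true, y_pred, 4),
                                     list("NSVF"))
        assert rep.macro_f1 == pytest.approx(
            sk.f1_score(y_true, y_pred, average="macro"))
        np.testing.assert_allclose(
            rep.precision,
            sk.precision_score(y_true, y_pred, average=None,
                               zero_division=0), atol=1e-12)


class TestSchedule:
    def test_lr_halves_after_patience_plus_one_flat_epochs(self, small_model):
        opt = Adam(small_model, lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3, floor=1e-5)
        sched.step(1.0)  # establishes the best
        for i in range(3):
            sched.step(1.0)
            assert opt.lr == 1e-3, f"halved too early at flat epoch {i + 1}"
        sched.step(1.0)  # 4th non-improving epoch (patience+1)
        assert opt.lr == 5e-4

    def test_lr_never_drops_below_floor(self, small_model):
        opt = Adam(small_model, lr=2e-5)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=0, floor=1e-5)
        for _ in range(10):
            sched.step(1.0)
        assert opt.lr == 1e-5


def _narrow_cfg(n_classes=4):
    return ModelConfig(
        front_channels=4,
        layer_channels=((4, 8), (8, 8), (8, 16)),
        layer_strides=(1, 2, 2),
        reb_counts=(1, 1, 1),
        num_classes=n_classes,
        dropout_p=0.1,
    )


@pytest.fixture(scope="module")
def narrow_training_run():
    ds = synth_dataset(SynthConfig(n_per_class=60, noise_sd=0.05, seed=0))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ds))
    val, train = ds.subset(perm[:60]), ds.subset(perm[60:])
    model = build_model(_narrow_cfg(), seed=0)
    model, hist = train_fold(model, train, val,
                             TrainConfig(max_epochs=5, batch_size=32, seed=0))
    return model, hist, val


class TestTraining:
    def test_loss_decreases_on_separable_task(self, narrow_training_run):
        _, hist, _ = narrow_training_run
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_history_records_all_fields(self, narrow_training_run):
        _, hist, _ = narrow_training_run
        assert {"epoch", "train_loss", "train_acc", "val_loss", "val_acc",
                "lr"} <= set(hist[0])

    def test_returned_model_is_best_checkpoint(self, narrow_training_run):
        model, hist, val = narrow_training_run
        logits = model.forward(val.beats[:, None, :], train=False)
        from hprnet.nn import cross_entropy
        loss, _ = cross_entropy(logits, val.labels)
        best = min(h["val_loss"] for h in hist)
        assert loss == pytest.approx(best, abs=1e-5)

    def test_empty_split_rejected(self, small_model, clean_synth):
        empty = clean_synth.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            train_fold(small_model, empty, clean_synth, TrainConfig())


class TestCrossValidation:
    def test_each_beat_tested_exactly_once(self):
        ds = synth_dataset(SynthConfig(n_per_class=25, noise_sd=0.05, seed=1))
        folds = make_folds(ds.labels, k=5, seed=1)
        result = cross_validate(
            ds, folds, lambda f: build_model(_narrow_cfg(), seed=f),
            TrainConfig(max_epochs=1, batch_size=32, seed=1))
        assert len(result.fold_reports) == 5
        assert sum(t.n for t in result.fold_tables) == len(ds)

    def test_five_fold_average_of_macro_f1(self):
        # per-fold macro F1 values average exactly (unweighted)
        vals = [92.38, 92.36, 91.67, 90.65, 93.20]
        assert round(float(np.mean(vals)), 2) == 92.05

    def test_evaluate_rejects_labels_outside_model_classes(self, small_model,
                                                           clean_synth):
        with pytest.raises(ValueError, match="class set"):
            bad = clean_synth.subset(np.arange(len(clean_synth)))
            bad.labels = np.full(len(bad), 10)
            evaluate(small_model, bad)
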