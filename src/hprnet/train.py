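"""Training and evaluation: Adam, plateau LR schedule, confusion-table
metrics, stratified cross-validation.

The optimizer protocol follows the published setup: Adam at an initial
learning rate of 1e-3, batch size 128, at most 30 epochs, with the
learning rate halved (floor 1e-5) after the validation loss fails to
improve for ``patience`` consecutive epochs.  The model returned by
``train_fold`` is the best-validation-loss checkpoint.  Metrics are
computed one-vs-rest from the raw confusion table: precision TP/(TP+FP),
recall TP/(TP+FN), F1 their harmonic mean, macro scores the unweighted
class means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import BeatDataset
from .model import HPRNet
from .beats import FoldSplit

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 30
    lr_factor: float = 0.5
    lr_patience: int = 3
    lr_floor: float = 1e-5
    seed: int = 0
    # stop as soon as validation accuracy reaches this level (None = never)
    early_stop_val_acc: float | None = None

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class Adam:
    def __init__(self, model: HPRNet, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(mod.params[k])
                  for n, mod, k in model.named_params()}
        self.v = {n: np.zeros_like(mod.params[k])
                  for n, mod, k in model.named_params()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for name, mod, key in self.model.named_params():
            g = mod.grads[key]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            mod.params[key] -= (self.lr * mhat /
                                (np.sqrt(vhat) + self.eps)).astype(nn.DTYPE)
        self.model.apply_masks()  # pruned weights stay exactly zero


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` non-improving epochs."""

    def __init__(self, optimizer: Adam, factor=0.5, patience=3, floor=1e-5):
        self.opt = optimizer
        self.factor, self.patience, self.floor = factor, patience, floor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.floor)
                self.bad_epochs = 0


# ------------------------------------------------------------------ metrics
class ConfusionTable:
    """Raw C x C counts; rows are true classes, columns predictions."""

    def __init__(self, y_true, y_pred, n_classes: int):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        self.matrix = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(self.matrix, (y_true, y_pred), 1)

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def class_counts(self, c: int):
        """(TP, FP, FN, TN) for class ``c`` one-vs-rest."""
        tp = int(self.matrix[c, c])
        fp = int(self.matrix[:, c].sum() - tp)
        fn = int(self.matrix[c, :].sum() - tp)
        tn = self.n - tp - fp - fn
        return tp, fp, fn, tn

    def row_normalized(self) -> np.ndarray:
        rs = self.matrix.sum(axis=1, keepdims=True)
        return np.divide(self.matrix, rs, where=rs > 0,
                         out=np.zeros_like(self.matrix, dtype=float))


@dataclass
class MetricsReport:
    """Scores stored as fractions in [0, 1]; printed as % at 2 dp."""

    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    class_names: list

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            **{f"precision_{c}": float(p)
               for c, p in zip(self.class_names, self.precision)},
            **{f"recall_{c}": float(r)
               for c, r in zip(self.class_names, self.recall)},
            **{f"f1_{c}": float(f)
               for c, f in zip(self.class_names, self.f1)},
        }

    def summary(self) -> str:
        lines = [f"accuracy: {100 * self.accuracy:.2f}%"]
        for i, c in enumerate(self.class_names):
            lines.append(
                f"  {c}: precision {100 * self.precision[i]:.2f}%  "
                f"recall {100 * self.recall[i]:.2f}%  "
                f"F1 {100 * self.f1[i]:.2f}%")
        lines.append(
            f"macro: precision {100 * self.macro_precision:.2f}%  "
            f"recall {100 * self.macro_recall:.2f}%  "
            f"F1 {100 * self.macro_f1:.2f}%")
        return "\n".join(lines)


def metrics_from_confusion(table: ConfusionTable, class_names) -> MetricsReport:
    C = len(class_names)
    precision = np.zeros(C)
    recall = np.zeros(C)
    f1 = np.zeros(C)
    for c in range(C):
        tp, fp, fn, _ = table.class_counts(c)
        if tp + fn == 0:
            log.warning("class %s absent from the evaluation set; "
                        "its recall/F1 are reported as 0", class_names[c])
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        denom = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / denom if denom else 0.0
    accuracy = float(np.trace(table.matrix) / table.n) if table.n else 0.0
    return MetricsReport(accuracy, precision, recall, f1, list(class_names))


def macro_f1_from_class_f1(class_f1_percent) -> float:
    """Unweighted mean of per-class F1 values given in percent."""
    return float(np.mean(np.asarray(class_f1_percent, dtype=float)))


# ----------------------------------------------------------------- training
def _predict(model: HPRNet, beats: np.ndarray, batch_size: int = 256):
    logits = []
    for i in range(0, len(beats), batch_size):
        logits.append(model.forward(beats[i:i + batch_size], train=False))
    return np.concatenate(logits)


def _eval_loss_acc(model, beats, labels, batch_size=256):
    logits = _predict(model, beats, batch_size)
    loss, _ = nn.cross_entropy(logits, labels)
    acc = float(np.mean(logits.argmax(axis=1) == labels))
    return loss, acc


def train_fold(model: HPRNet, train_set: BeatDataset, val_set: BeatDataset,
               cfg: TrainConfig):
    """Train one model; returns (model, history).

    The returned model carries the best-validation-loss parameters;
    ``history`` is a list of per-epoch dicts (losses, accuracies, lr).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.lr0)
    sched = ReduceLROnPlateau(opt, cfg.lr_factor, cfg.lr_patience, cfg.lr_floor)
    history = []
    best_loss, best_state = np.inf, None
    xb_all = train_set.beats[:, None, :]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = xb_all[idx]
            yb = train_set.labels[idx]
            logits = model.forward(xb, train=True, rng=rng)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_loss_acc(model, val_set.beats[:, None, :],
                                           val_set.labels)
        history.append({
            "epoch": epoch,
            "train_loss": ep_loss / len(order),
            "train_acc": ep_correct / len(order),
            "val_loss": val_loss,
            "val_acc": val_acc,
            "lr": opt.lr,
        })
        log.info("epoch=%d train_loss=%.4f val_loss=%.4f val_acc=%.4f lr=%.2e",
                 epoch, history[-1]["train_loss"], val_loss, val_acc, opt.lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
        sched.step(val_loss)
        if (cfg.early_stop_val_acc is not None
                and val_acc >= cfg.early_stop_val_acc):
            break
    if best_state is not None:
        load_masked(model, best_state)
    return model, history


def load_masked(model: HPRNet, state: dict):
    model.load_state_dict(state)
    model.apply_masks()


def evaluate(model: HPRNet, test_set: BeatDataset):
    """Confusion table and metrics for one dataset."""
    if test_set.labels.max(initial=-1) >= model.cfg.num_classes:
        raise ValueError("test labels outside the model's class set")
    logits = _predict(model, test_set.beats[:, None, :])
    pred = logits.argmax(axis=1)
    table = ConfusionTable(test_set.labels, pred, len(test_set.class_names))
    return table, metrics_from_confusion(table, test_set.class_names)


@dataclass
class CrossValResult:
    fold_reports: list
    fold_tables: list
    histories: list

    def averaged(self) -> dict:
        """Unweighted mean of per-fold metrics (fractions in [0, 1])."""
        keys = self.fold_reports[0].to_dict().keys()
        dicts = [r.to_dict() for r in self.fold_reports]
        return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def cross_validate(dataset: BeatDataset, folds: FoldSplit, model_factory,
                   train_cfg: TrainConfig, val_fraction: float = 0.1):
    """k-fold CV: fold f is the test set; a stratified slice of the
    remaining beats is held out as the validation set for the LR schedule
    and model selection.  ``model_factory(fold_index)`` must return a fresh
    model."""
    if folds.k < 2:
        raise ValueError("need at least 2 folds")
    reports, tables, histories = [], [], []
    for f in range(folds.k):
        test = dataset.subset(folds.test_indices(f))
        pool_idx = folds.train_indices(f)
        rng = np.random.default_rng(train_cfg.seed + f)
        perm = rng.permutation(len(pool_idx))
        n_val = max(1, int(round(val_fraction * len(pool_idx))))
        val = dataset.subset(pool_idx[perm[:n_val]])
        train = dataset.subset(pool_idx[perm[n_val:]])
        model = model_factory(f)
        cfg_f = TrainConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + f})
        model, hist = train_fold(model, train, val, cfg_f)
        table, report = evaluate(model, test)
        reports.append(report)
        tables.append(table)
        histories.append(hist)
        log.info("fold %d: %s", f, report.summary().replace("\n", " | "))
    return CrossValResult(reports, tables, histories)
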