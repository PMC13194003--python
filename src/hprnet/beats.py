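"""Beat segmentation, AAMI symbol mapping and cross-validation folds.

Beats are fixed-length windows (default 128 native samples) centered on the
annotated R-peak fiducial: 64 samples before, 64 after, half-open, 0-based.
Annotation symbols map to AAMI(-like) classes; anything unmapped is
EXCLUDED and dropped with bookkeeping so that
emitted + edge-skipped + excluded == total annotations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import BeatDataset, zscore_beats

log = logging.getLogger(__name__)

EXCLUDED = "EXCLUDED"

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

# AAMI grouping of MIT-BIH annotation symbols
MITBIH_SYMBOL_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}
# AAMI-like grouping of INCART annotation symbols
INCART_SYMBOL_MAP = {
    "N": "N", "R": "N", "j": "N", "n": "N", "B": "N",
    "A": "S", "S": "S",
    "V": "V",
    "Q": "Q",
}


@dataclass
class AamiMap:
    dataset_tag: str  # "mitbih" | "incart"
    symbol_to_class: dict

    @classmethod
    def for_dataset(cls, tag: str) -> "AamiMap":
        maps = {"mitbih": MITBIH_SYMBOL_MAP, "incart": INCART_SYMBOL_MAP}
        if tag not in maps:
            raise ValueError(f"unknown dataset tag {tag!r}; use one of {list(maps)}")
        return cls(tag, dict(maps[tag]))


def map_symbol(symbol: str, amap: AamiMap) -> str:
    """Map one annotation symbol to its AAMI class, or EXCLUDED."""
    return amap.symbol_to_class.get(symbol, EXCLUDED)


@dataclass
class SegmentationLog:
    emitted: int = 0
    skipped_edge: int = 0
    excluded: int = 0
    excluded_symbols: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.emitted + self.skipped_edge + self.excluded


def segment_beats(signal, fs, annotations, amap: AamiMap, L: int = 128,
                  normalize: bool = True, source_id: str = "",
                  class_names=AAMI_CLASSES):
    """Cut one beat of ``L`` samples around each mappable annotation.

    Returns ``(BeatDataset, SegmentationLog)``.  Beats whose window would
    cross a record edge are skipped and counted.  Raises if no beat at all
    is mappable.
    """
    if L % 2:
        raise ValueError("window length L must be even")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or len(signal) < L:
        raise ValueError(f"signal must be 1-D with at least {L} samples")
    half = L // 2
    beats, labels = [], []
    seg = SegmentationLog()
    for r, sym in annotations:
        cls = map_symbol(sym, amap)
        if cls == EXCLUDED:
            seg.excluded += 1
            seg.excluded_symbols[sym] = seg.excluded_symbols.get(sym, 0) + 1
            continue
        if r - half < 0 or r + half > len(signal):
            seg.skipped_edge += 1
            continue
        beats.append(signal[r - half:r + half])
        labels.append(class_names.index(cls))
        seg.emitted += 1
    if not beats:
        raise ValueError("no mappable beats found in record")
    if seg.excluded:
        log.info("excluded %d annotations by symbol: %s",
                 seg.excluded, seg.excluded_symbols)
    arr = np.asarray(beats)
    if normalize:
        arr = zscore_beats(arr)
    ds = BeatDataset(arr, np.asarray(labels), list(class_names),
                     np.asarray([source_id] * len(beats), dtype=object),
                     fs=fs, lead="")
    return ds, seg


def class_counts(dataset: BeatDataset) -> dict[str, int]:
    """Per-class beat counts; values sum to len(dataset)."""
    return dataset.counts()


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # per-beat fold index in [0, k)
    seed: int
    strategy: str = "stratified-beat"

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Beat-level stratified k-fold assignment.

    Within each class, beats are shuffled and dealt round-robin across
    folds, so per-class counts differ by at most one.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} beats; needs at least k={k}")
        perm = rng.permutation(idx)
        assignments[perm] = np.arange(len(perm)) % k
    return FoldSplit(k, assignments, seed)


_TASKS = {
    "mitbih-4class": {"keep": ("N", "S", "V", "F"), "map": None},
    "incart-binary": {"keep": ("N", "S", "V"),
                      "map": {"N": "normal", "S": "abnormal", "V": "abnormal"}},
    "incart-3class": {"keep": ("N", "S", "V"), "map": None},
}


def relabel_task(dataset: BeatDataset, task: str) -> BeatDataset:
    """Project a 5-class AAMI dataset onto one of the paper's tasks."""
    if task not in _TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks: {list(_TASKS)}")
    spec = _TASKS[task]
    for cls in spec["keep"]:
        if cls not in dataset.class_names:
            raise ValueError(
                f"task {task!r} needs class {cls!r}, not present in dataset")
    keep_ids = [dataset.class_names.index(c) for c in spec["keep"]]
    mask = np.isin(dataset.labels, keep_ids)
    sub = dataset.subset(np.flatnonzero(mask))
    old_names = [dataset.class_names[i] for i in keep_ids]
    if spec["map"] is None:
        new_names = list(spec["keep"])
        remap = {keep_ids[i]: i for i in range(len(keep_ids))}
    else:
        new_names = sorted(set(spec["map"].values()),
                           key=list(spec["map"].values()).index)
        remap = {keep_ids[i]: new_names.index(spec["map"][old_names[i]])
                 for i in range(len(keep_ids))}
    sub.labels = np.array([remap[l] for l in sub.labels], dtype=np.int64)
    sub.class_names = new_names
    return sub


def merge_datasets(datasets: list[BeatDataset]) -> BeatDataset:
    """Concatenate beat datasets sharing the same class vocabulary."""
    if not datasets:
        raise ValueError("no datasets to merge")
    names = datasets[0].class_names
    for d in datasets[1:]:
        if d.class_names != names:
            raise ValueError("datasets have mismatched class_names")
    return BeatDataset(
        np.concatenate([d.beats for d in datasets]),
        np.concatenate([d.labels for d in datasets]),
        list(names),
        np.concatenate([d.source_ids for d in datasets]),
        datasets[0].fs, datasets[0].lead,
    )
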