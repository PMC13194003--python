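"""Beat-level dataset container and on-disk formats (NPZ, CSV)."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class BeatDataset:
    """Fixed-length heartbeat matrix with integer class labels.

    beats : (N, L) float array, one beat per row (z-scored unless raw).
    labels : (N,) int array, indices into ``class_names``.
    class_names : ordered class labels, e.g. ["N", "S", "V", "F"].
    source_ids : per-beat record identifier (provenance).
    fs : sampling rate of the originating signal in Hz.
    lead : lead name the beats were taken from.
    """

    beats: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    source_ids: np.ndarray = None
    fs: float = 360.0
    lead: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beats = np.asarray(self.beats, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.beats.ndim != 2:
            raise ValueError("beats must be a 2-D (N, L) array")
        n = self.beats.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of beats")
        if not np.all(np.isfinite(self.beats)):
            raise ValueError("beats contain non-finite values")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range for class_names")
        if self.source_ids is None:
            self.source_ids = np.array([""] * n, dtype=object)
        self.source_ids = np.asarray(self.source_ids)
        if self.source_ids.shape != (n,):
            raise ValueError("source_ids length must match number of beats")

    def __len__(self) -> int:
        return self.beats.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def counts(self) -> dict[str, int]:
        """Per-class beat counts, in class_names order (zero-filled)."""
        c = np.bincount(self.labels, minlength=self.n_classes)
        return {name: int(c[i]) for i, name in enumerate(self.class_names)}

    def subset(self, idx) -> "BeatDataset":
        idx = np.asarray(idx)
        return BeatDataset(
            self.beats[idx], self.labels[idx], list(self.class_names),
            self.source_ids[idx], self.fs, self.lead, dict(self.meta),
        )

    # ------------------------------------------------------------------ io
    def save_npz(self, path) -> None:
        np.savez(
            path,
            beats=self.beats,
            labels=self.labels,
            class_names=np.array(self.class_names),
            source_ids=self.source_ids.astype(str),
            fs=np.array(self.fs),
            lead=np.array(self.lead),
        )

    @classmethod
    def load_npz(cls, path) -> "BeatDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["beats"], z["labels"], [str(c) for c in z["class_names"]],
                z["source_ids"].astype(object), float(z["fs"]), str(z["lead"]),
            )

    def save_csv(self, path) -> None:
        """One beat per row; last column is the integer label."""
        arr = np.column_stack([self.beats, self.labels.astype(np.float32)])
        header = ",".join([f"s{i}" for i in range(self.beats.shape[1])] + ["label"])
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def load_csv(cls, path, class_names) -> "BeatDataset":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        arr = np.atleast_2d(arr)
        return cls(arr[:, :-1], arr[:, -1].astype(np.int64), list(class_names))


def zscore_beats(beats: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-beat z-score; constant beats map to all-zero rows."""
    beats = np.asarray(beats, dtype=np.float64)
    mu = beats.mean(axis=1, keepdims=True)
    sd = beats.std(axis=1, keepdims=True)
    out = np.where(sd > eps, (beats - mu) / np.where(sd > eps, sd, 1.0), 0.0)
    return out.astype(np.float32)


def write_folds_csv(path, assignments: np.ndarray) -> None:
    idx = np.arange(len(assignments))
    np.savetxt(path, np.column_stack([idx, assignments]), fmt="%d",
               delimiter=",", header="beat_index,fold", comments="")


def read_folds_csv(path) -> np.ndarray:
    arr = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1, dtype=int))
    return arr[:, 1]
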