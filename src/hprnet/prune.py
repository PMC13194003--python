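"""Multi-level pruning optimization (MLPO): unstructured L1-magnitude
pruning with persistent binary masks.

Scopes
------
network_level : the front convolution weight(s) and the final fully
    connected weight.
block_level : every REB convolution weight, including the 1x1 skip convs.
mlpo : the union of the two.

Per tensor, the ``round(ratio * numel)`` smallest-magnitude entries are
zeroed (stable tie-break: the lower flat index survives).  Batch-norm
scale/shift and biases are never pruned.  Masks are stored on the model
and re-applied after every optimizer step so pruned weights stay exactly
zero through training.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import HPRNet, scope_groups, parameter_table


@dataclass
class PruneConfig:
    ratio: float = 0.9
    scope: str = "mlpo"  # network_level | block_level | mlpo | none

    def __post_init__(self):
        if not (0 <= self.ratio < 1):
            raise ValueError("pruning ratio must be in [0, 1)")
        scope_groups(self.scope)  # validates


def select_prunable(model: HPRNet, scope: str):
    """Ordered (name, module, key) list of weight tensors in a scope."""
    groups = scope_groups(scope)
    by_name = {name: g for name, _, g in parameter_table(model.cfg)}
    out = []
    for name, m, key in model.named_params():
        if by_name.get(name) in groups:
            out.append((name, m, key))
    return out


def _l1_mask(w: np.ndarray, ratio: float) -> np.ndarray:
    """Binary keep-mask zeroing the round(ratio*numel) smallest |w|."""
    n_prune = round(ratio * w.size)
    mask = np.ones(w.size, dtype=bool)
    if n_prune == 0:
        return mask.reshape(w.shape)
    mag = np.abs(w.reshape(-1))
    kth = np.partition(mag, n_prune - 1)[n_prune - 1]
    below = mag < kth
    n_below = int(below.sum())
    mask[below] = False
    # stable tie-break at the threshold magnitude: lower flat index pruned
    # first among equals
    ties = np.flatnonzero(mag == kth)
    mask[ties[: n_prune - n_below]] = False
    return mask.reshape(w.shape)


def prune_l1(model: HPRNet, cfg: PruneConfig) -> HPRNet:
    """Apply L1-magnitude pruning in place; masks persist on the model."""
    for name, m, key in select_prunable(model, cfg.scope):
        mask = _l1_mask(m.params[key], cfg.ratio)
        if name in model.masks:
            mask &= model.masks[name].astype(bool)
        model.masks[name] = mask
        m.params[key] *= mask
    return model


def nonzero_count(model: HPRNet) -> int:
    """Exact count of nonzero trainable entries."""
    return int(sum(np.count_nonzero(m.params[k])
                   for _, m, k in model.named_params()))


@dataclass
class SparsityReport:
    per_tensor: list  # (name, total, nonzero, fraction_pruned)
    total: int
    nonzero: int
    bin_edges: np.ndarray
    hist_before: np.ndarray
    hist_after: np.ndarray

    @property
    def fraction_pruned(self) -> float:
        return 1.0 - self.nonzero / self.total

    def to_json_dict(self) -> dict:
        return {
            "per_tensor": [
                {"name": n, "total": t, "nonzero": nz, "fraction_pruned": f}
                for n, t, nz, f in self.per_tensor],
            "total": self.total, "nonzero": self.nonzero,
            "fraction_pruned": self.fraction_pruned,
            "bin_edges": self.bin_edges.tolist(),
            "hist_before": self.hist_before.tolist(),
            "hist_after": self.hist_after.tolist(),
        }

    def to_csv(self, path):
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "total", "nonzero", "fraction_pruned"])
            for row in self.per_tensor:
                w.writerow(row)


def sparsity_report(model_before: HPRNet, model_after: HPRNet,
                    n_bins: int = 64) -> SparsityReport:
    """Per-tensor sparsity plus |w| histograms before/after pruning.

    Histograms use ``n_bins`` uniform bins over [0, max|w| before pruning];
    exact zeros after pruning are excluded from the 'after' histogram so
    the plot shows the surviving weight distribution.
    """
    names_b = [n for n, _, _ in model_before.named_params()]
    names_a = [n for n, _, _ in model_after.named_params()]
    if names_b != names_a:
        raise ValueError("models have different architectures")
    before = np.concatenate([np.abs(m.params[k].ravel())
                             for _, m, k in model_before.named_params()])
    after_tensors = list(model_after.named_params())
    after = np.concatenate([np.abs(m.params[k].ravel())
                            for _, m, k in after_tensors])
    edges = np.linspace(0.0, float(before.max()) or 1.0, n_bins + 1)
    hist_b, _ = np.histogram(before, bins=edges)
    hist_a, _ = np.histogram(after[after > 0], bins=edges)
    per_tensor = []
    total = nonzero = 0
    for name, m, k in after_tensors:
        t = m.params[k].size
        nz = int(np.count_nonzero(m.params[k]))
        per_tensor.append((name, t, nz, 1.0 - nz / t))
        total += t
        nonzero += nz
    return SparsityReport(per_tensor, total, nonzero, edges, hist_b, hist_a)
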