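"""Gradient-weighted class activation mapping (Grad-CAM) for 1-D signals.

For a chosen ResLayer, channel weights are the temporal average of the
gradient of the target-class logit (pre-softmax) with respect to that
layer's activations; the map is ReLU(sum_c w_c * A_c), linearly upsampled
to the input length and min-max normalized to [0, 1].  An identically zero
pre-normalization map stays all zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HPRNet


@dataclass
class SaliencyMap:
    values: np.ndarray   # length-L trace in [0, 1]
    layer_tag: str
    target_class: int
    beat_id: str = ""


def _layer_index(model: HPRNet, layer_tag) -> int:
    n = len(model.layers)
    if isinstance(layer_tag, (int, np.integer)):
        idx = int(layer_tag)
    elif isinstance(layer_tag, str) and layer_tag.startswith("ResLayer"):
        idx = int(layer_tag[len("ResLayer"):])
    else:
        raise ValueError(
            f"invalid layer tag {layer_tag!r}; valid tags: "
            f"{[f'ResLayer{i}' for i in range(n)]}")
    if not 0 <= idx < n:
        raise ValueError(
            f"layer tag {layer_tag!r} out of range; valid tags: "
            f"{[f'ResLayer{i}' for i in range(n)]}")
    return idx


def gradcam(model: HPRNet, beat: np.ndarray, target_class: int,
            layer_tag="ResLayer5", beat_id: str = "") -> SaliencyMap:
    """Saliency trace for one beat at the output of one ResLayer."""
    li = _layer_index(model, layer_tag)
    beat = np.asarray(beat, dtype=np.float64)
    x = beat.reshape(1, 1, -1)
    logits = model.forward(x, train=False)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} outside 0.."
                         f"{logits.shape[1] - 1}")
    acts = model.layer_outputs[li][0]            # (C, L_layer)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.zero_grad()
    model.backward(dlogits, capture_layers=[li])
    grads = model.layer_output_grads[li][0]      # (C, L_layer)
    weights = grads.mean(axis=1)                 # temporal average per channel
    cam = np.maximum((weights[:, None] * acts).sum(axis=0), 0.0)
    L = beat.shape[-1]
    if cam.size == 1:
        up = np.full(L, cam[0])
    else:
        src = np.linspace(0.0, 1.0, cam.size)
        dst = np.linspace(0.0, 1.0, L)
        up = np.interp(dst, src, cam)
    lo, hi = up.min(), up.max()
    values = np.zeros(L) if hi <= 0 or hi == lo else (up - lo) / (hi - lo)
    tag = f"ResLayer{li}"
    return SaliencyMap(values, tag, int(target_class), beat_id)


def saliency_panel(model: HPRNet, beats: np.ndarray, classes,
                   layer_tags=("ResLayer0", "ResLayer3", "ResLayer5"),
                   beat_ids=None) -> pd.DataFrame:
    """Long-format table (beat_id, layer_tag, sample_index, value)."""
    beats = np.atleast_2d(np.asarray(beats))
    classes = np.atleast_1d(np.asarray(classes))
    if len(beats) == 0:
        raise ValueError("no beats given")
    if len(classes) != len(beats):
        raise ValueError("need one target class per beat")
    if beat_ids is None:
        beat_ids = [f"beat{i}" for i in range(len(beats))]
    rows = []
    for beat, cls, bid in zip(beats, classes, beat_ids):
        for tag in layer_tags:
            sm = gradcam(model, beat, int(cls), tag, beat_id=bid)
            for i, v in enumerate(sm.values):
                rows.append((bid, sm.layer_tag, i, float(v)))
    return pd.DataFrame(rows, columns=["beat_id", "layer_tag",
                                       "sample_index", "value"])
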