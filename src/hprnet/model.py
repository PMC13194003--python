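"""HPRNet: hierarchical pyramidal 1-D residual network.

Structure: a front-end (Conv1d k=17 -> BatchNorm -> ReLU) feeds a
hierarchical backbone of nine ResLayers, each a cascade of residual
extraction blocks (REBs).  An REB's main branch is pre-activation
BN-ReLU-Conv(k=17) twice; its skip branch is a strided 1x1 convolution
(only in the first REB of a layer, where shape changes) followed by a
shape-preserving max pool (kernel 3, stride 1, padding 1).  The classifier
head is dropout -> global average pooling -> fully connected.

The default configuration reproduces the published complexity figures: the
head has ``num_classes=8`` output units and the front-end a single
convolution without bias — this is the configuration whose parameter
counts match the published tables exactly (the layer table in the source
describes two front convolutions and a C-class head, but no such variant
is consistent with the printed totals).  Classification tasks pass their
own ``num_classes``.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn

DEFAULT_REB_COUNTS = (3, 4, 4, 4, 4, 4, 4, 4, 3)
DEFAULT_LAYER_CHANNELS = ((32, 64), (64, 64), (64, 128), (128, 128),
                          (128, 256), (256, 256), (256, 512), (512, 512),
                          (512, 1024))
DEFAULT_LAYER_STRIDES = (1, 2, 2, 2, 2, 2, 2, 2, 2)


@dataclass
class ModelConfig:
    input_len: int = 128
    input_channels: int = 1
    front_channels: int = 32
    front_convs: int = 1           # calibrated; the schematic shows 2
    front_bias: bool = False
    kernel: int = 17
    padding: int = 8
    reb_counts: tuple = DEFAULT_REB_COUNTS
    layer_channels: tuple = DEFAULT_LAYER_CHANNELS
    layer_strides: tuple = DEFAULT_LAYER_STRIDES
    dropout_p: float = 0.5
    num_classes: int = 8           # published complexity head; tasks set 4 etc.
    skip_pool_kernel: int = 3

    def __post_init__(self):
        self.reb_counts = tuple(self.reb_counts)
        self.layer_channels = tuple(tuple(p) for p in self.layer_channels)
        self.layer_strides = tuple(self.layer_strides)
        n = len(self.reb_counts)
        if not (len(self.layer_channels) == len(self.layer_strides) == n):
            raise ValueError("reb_counts, layer_channels and layer_strides "
                             "must have equal length")
        if any(c < 1 for c in self.reb_counts):
            raise ValueError("every ResLayer needs at least one REB")
        if self.kernel % 2 != 1 or self.padding != (self.kernel - 1) // 2:
            raise ValueError("kernel must be odd with padding == (kernel-1)/2")
        c_prev = self.front_channels
        for i, (cin, cout) in enumerate(self.layer_channels):
            if cin != c_prev:
                raise ValueError(
                    f"channel schedule mismatch at ResLayer{i}: expected "
                    f"c_in {c_prev}, got {cin}")
            c_prev = cout
        if self.front_convs not in (1, 2):
            raise ValueError("front_convs must be 1 or 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# --------------------------------------------------------------------- REB
class REB:
    """Residual extraction block.

    Main path: BN-ReLU-Conv(c_in->c_out, stride) -> BN-ReLU-Conv(c_out->c_out).
    Skip path: strided 1x1 conv where shape changes (first block of a
    layer), otherwise identity; then max pool (k=3, s=1, p=1).  Output is
    the elementwise sum of the two branches.
    """

    def __init__(self, c_in, c_out, stride, cfg: ModelConfig, rng):
        k, p = cfg.kernel, cfg.padding
        self.bn1 = nn.BatchNorm1d(c_in, rng=rng)
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv1d(c_in, c_out, k, stride, p, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm1d(c_out, rng=rng)
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv1d(c_out, c_out, k, 1, p, bias=False, rng=rng)
        self.has_skip_conv = (stride != 1) or (c_in != c_out)
        self.skip_conv = (nn.Conv1d(c_in, c_out, 1, stride, 0, bias=False,
                                    rng=rng)
                          if self.has_skip_conv else None)
        self.pool = nn.MaxPool1d(cfg.skip_pool_kernel, 1,
                                 (cfg.skip_pool_kernel - 1) // 2)
        # branch switches used by the residual-additivity tests
        self.main_enabled = True
        self.skip_enabled = True

    def modules(self):
        out = [("bn1", self.bn1), ("conv1", self.conv1),
               ("bn2", self.bn2), ("conv2", self.conv2)]
        if self.skip_conv is not None:
            out.append(("skip", self.skip_conv))
        return out

    def forward(self, x, train=False, rng=None):
        main = self.bn1.forward(x, train)
        main = self.relu1.forward(main)
        main = self.conv1.forward(main)
        main = self.bn2.forward(main, train)
        main = self.relu2.forward(main)
        main = self.conv2.forward(main)
        skip = self.skip_conv.forward(x) if self.skip_conv is not None else x
        skip = self.pool.forward(skip)
        if not self.main_enabled:
            main = np.zeros_like(main)
        if not self.skip_enabled:
            skip = np.zeros_like(skip)
        return main + skip

    def backward(self, dy):
        dmain = dy if self.main_enabled else np.zeros_like(dy)
        dskip = dy if self.skip_enabled else np.zeros_like(dy)
        d = self.conv2.backward(dmain)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv1.backward(d)
        d = self.relu1.backward(d)
        dx_main = self.bn1.backward(d)
        d = self.pool.backward(dskip)
        dx_skip = self.skip_conv.backward(d) if self.skip_conv is not None else d
        return dx_main + dx_skip


class ResLayer:
    """Cascade of REBs; only the first carries stride/channel change."""

    def __init__(self, c_in, c_out, stride, n_rebs, cfg, rng):
        self.blocks = [REB(c_in, c_out, stride, cfg, rng)]
        self.blocks += [REB(c_out, c_out, 1, cfg, rng)
                        for _ in range(n_rebs - 1)]

    def forward(self, x, train=False, rng=None):
        for b in self.blocks:
            x = b.forward(x, train)
        return x

    def backward(self, dy):
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


class HPRNet:
    """The network; ``forward`` returns logits, ``backward`` backpropagates.

    ``prune masks`` (if any) live in ``self.masks`` keyed by parameter
    name; :meth:`apply_masks` re-zeroes masked weights (called by the
    training loop after every optimizer step).
    """

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.front = [("front.conv1",
                       nn.Conv1d(c.input_channels, c.front_channels, c.kernel,
                                 1, c.padding, bias=c.front_bias, rng=rng))]
        if c.front_convs == 2:
            self.front.append(
                ("front.conv2",
                 nn.Conv1d(c.front_channels, c.front_channels, c.kernel, 1,
                           c.padding, bias=c.front_bias, rng=rng)))
        self.front_bn = nn.BatchNorm1d(c.front_channels, rng=rng)
        self.front_relu = nn.ReLU()
        self.layers = [
            ResLayer(cin, cout, s, n, c, rng)
            for (cin, cout), s, n in zip(c.layer_channels, c.layer_strides,
                                         c.reb_counts)
        ]
        self.dropout = nn.Dropout(c.dropout_p)
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(c.layer_channels[-1][1], c.num_classes, bias=True,
                            rng=rng)
        self.masks: dict[str, np.ndarray] = {}
        # grad-cam capture state
        self.layer_outputs: list[np.ndarray] | None = None
        self.layer_output_grads: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------ registry
    def named_modules(self):
        for name, m in self.front:
            yield name, m
        yield "front.bn", self.front_bn
        for li, layer in enumerate(self.layers):
            for bi, block in enumerate(layer.blocks):
                for sub, m in block.modules():
                    yield f"layers.{li}.blocks.{bi}.{sub}", m
        yield "head.fc", self.fc

    def named_params(self):
        """Yield (name, module, key) for every trainable tensor."""
        for mname, m in self.named_modules():
            for key in m.params:
                yield f"{mname}.{key}", m, key

    def get_param(self, name: str) -> np.ndarray:
        for pname, m, key in self.named_params():
            if pname == name:
                return m.params[key]
        raise KeyError(name)

    # ------------------------------------------------------------- forward
    def forward(self, x, train=False, rng=None):
        """x: (B, 1, L) -> logits (B, C)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.cfg.input_len:
            raise ValueError(
                f"expected input length {self.cfg.input_len}, got {x.shape[2]}")
        for _, m in self.front:
            x = m.forward(x, train)
        x = self.front_bn.forward(x, train)
        x = self.front_relu.forward(x)
        self.layer_outputs = []
        for layer in self.layers:
            x = layer.forward(x, train)
            self.layer_outputs.append(x)
        x = self.dropout.forward(x, train, rng)
        x = self.gap.forward(x)
        return self.fc.forward(x)

    def predict_proba(self, x):
        return nn.softmax(self.forward(x, train=False))

    def backward(self, dlogits, capture_layers=()):
        """Backpropagate from logit gradients; optionally record the
        gradient arriving at given ResLayer outputs (for Grad-CAM)."""
        capture = set(capture_layers)
        self.layer_output_grads = {}
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        d = self.dropout.backward(d)
        for li in reversed(range(len(self.layers))):
            if li in capture:
                self.layer_output_grads[li] = d.copy()
            d = self.layers[li].backward(d)
        d = self.front_relu.backward(d)
        d = self.front_bn.backward(d)
        for _, m in reversed(self.front):
            d = m.backward(d)
        return d

    # ----------------------------------------------------------- utilities
    def zero_grad(self):
        for _, m, _ in self.named_params():
            m.zero_grad()

    def apply_masks(self):
        for name, m, key in self.named_params():
            if name in self.masks:
                m.params[key] *= self.masks[name]

    def state_dict(self) -> dict:
        state = {n: m.params[k].copy() for n, m, k in self.named_params()}
        for mname, m in self.named_modules():
            if isinstance(m, nn.BatchNorm1d):
                state[f"{mname}.running_mean"] = m.running_mean.copy()
                state[f"{mname}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for n, m, k in self.named_params():
            m.params[k] = state[n].copy()
        for mname, m in self.named_modules():
            if isinstance(m, nn.BatchNorm1d):
                m.running_mean = state[f"{mname}.running_mean"].copy()
                m.running_var = state[f"{mname}.running_var"].copy()


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> HPRNet:
    return HPRNet(cfg, seed=seed)


# ------------------------------------------------------- shape accounting
def _strided_len(L, kernel, padding, stride):
    return (L + 2 * padding - kernel) // stride + 1


def layer_output_shapes(cfg: ModelConfig, input_len: int | None = None):
    """Per-ResLayer (channels, temporal length) after each stage."""
    L = input_len if input_len is not None else cfg.input_len
    shapes = []
    for (cin, cout), stride in zip(cfg.layer_channels, cfg.layer_strides):
        L = _strided_len(L, cfg.kernel, cfg.padding, stride)
        shapes.append((cout, L))
    return shapes


# --------------------------------------------------- parameter accounting
def parameter_table(cfg: ModelConfig):
    """Closed-form list of (name, numel, group) for every trainable tensor.

    group is one of 'network' (front conv + FC weights), 'block' (REB conv
    weights, including the 1x1 skip convs) and 'other' (BN scale/shift and
    biases) — the pruning scopes operate on these groups.
    """
    c = cfg
    k = c.kernel
    rows = [("front.conv1.weight",
             c.input_channels * c.front_channels * k, "network")]
    if c.front_bias:
        rows.append(("front.conv1.bias", c.front_channels, "other"))
    if c.front_convs == 2:
        rows.append(("front.conv2.weight",
                     c.front_channels * c.front_channels * k, "network"))
        if c.front_bias:
            rows.append(("front.conv2.bias", c.front_channels, "other"))
    rows += [("front.bn.gamma", c.front_channels, "other"),
             ("front.bn.beta", c.front_channels, "other")]
    for li, ((cin, cout), stride, n) in enumerate(
            zip(c.layer_channels, c.layer_strides, c.reb_counts)):
        for bi in range(n):
            a, b = (cin, cout) if bi == 0 else (cout, cout)
            pre = f"layers.{li}.blocks.{bi}"
            rows += [(f"{pre}.bn1.gamma", a, "other"),
                     (f"{pre}.bn1.beta", a, "other"),
                     (f"{pre}.conv1.weight", a * b * k, "block"),
                     (f"{pre}.bn2.gamma", b, "other"),
                     (f"{pre}.bn2.beta", b, "other"),
                     (f"{pre}.conv2.weight", b * b * k, "block")]
            if bi == 0 and (stride != 1 or a != b):
                rows.append((f"{pre}.skip.weight", a * b, "block"))
    rows += [("head.fc.weight", c.layer_channels[-1][1] * c.num_classes,
              "network"),
             ("head.fc.bias", c.num_classes, "other")]
    return rows


def scope_groups(scope: str) -> set:
    groups = {"network_level": {"network"}, "block_level": {"block"},
              "mlpo": {"network", "block"}, "none": set()}
    if scope not in groups:
        raise ValueError(f"unknown pruning scope {scope!r}; "
                         f"valid: {sorted(groups)}")
    return groups[scope]


def count_parameters(cfg: ModelConfig, prune=None) -> int:
    """Closed-form trainable parameter count.

    With a PruneConfig, returns the nonzero count after per-tensor L1
    pruning: round(ratio * numel) weights removed from each tensor in the
    pruning scope (matching :func:`hprnet.prune.prune_l1`).
    """
    rows = parameter_table(cfg)
    total = sum(n for _, n, _ in rows)
    if prune is None or getattr(prune, "scope", "none") == "none":
        return total
    groups = scope_groups(prune.scope)
    removed = sum(round(prune.ratio * n) for _, n, g in rows if g in groups)
    return total - removed


def count_flops(cfg: ModelConfig, input_len: int | None = None) -> float:
    """MFLOPs for one single-beat inference.

    Convention: one multiply-accumulate = 2 FLOPs; convolution cost
    2 * c_in * c_out * k * len_out per layer plus the fully connected
    2 * c_in * c_out; batch norm, pooling and activations are not counted.
    """
    c = cfg
    L = input_len if input_len is not None else c.input_len
    flops = 2 * c.input_channels * c.front_channels * c.kernel * L
    if c.front_convs == 2:
        flops += 2 * c.front_channels ** 2 * c.kernel * L
    for (cin, cout), stride, n in zip(c.layer_channels, c.layer_strides,
                                      c.reb_counts):
        L_out = _strided_len(L, c.kernel, c.padding, stride)
        # first REB
        flops += 2 * cin * cout * c.kernel * L_out          # conv1 (strided)
        flops += 2 * cout * cout * c.kernel * L_out         # conv2
        if stride != 1 or cin != cout:
            flops += 2 * cin * cout * L_out                 # 1x1 skip conv
        # remaining REBs
        flops += (n - 1) * 2 * (2 * cout * cout * c.kernel * L_out)
        L = L_out
    flops += 2 * c.layer_channels[-1][1] * c.num_classes
    return flops / 1e6


def enumerate_parameters(model: HPRNet) -> int:
    """Oracle: walk the instantiated model and count trainable entries."""
    return sum(m.params[k].size for _, m, k in model.named_params())
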