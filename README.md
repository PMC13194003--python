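# hprnet

Heartbeat-level ECG arrhythmia classification with a hierarchical pyramidal
1-D residual network (HPRNet), multi-level unstructured L1-magnitude pruning
(MLPO), closed-form complexity accounting, and 1-D Grad-CAM saliency.

The package is aimed at people working on compact deep models for
single-lead ECG: it reads annotated PhysioNet-style (WFDB) records, cuts
fixed-length beats around annotated R peaks, maps annotation symbols to the
AAMI classes (N/S/V/F/Q), trains and evaluates the network with stratified
cross-validation, and audits model size exactly — both by closed-form
accounting and by counting nonzero weights of the instantiated network.
A synthetic beat generator with P-QRS-T morphology makes every stage
testable without downloading any database.

## The model

An input beat `x ∈ R^{1×128}` passes through a front-end
(Conv1d k=17 → BatchNorm → ReLU) into a backbone of nine ResLayers.
ResLayer `l` is a cascade of `N_l` residual extraction blocks (REBs),
`N_l = [3,4,4,4,4,4,4,4,3]` by default; channels grow 32 → 1024 while
stride-2 transitions shrink the temporal axis 128 → 1:

```
z_{i+1} = F(z_i) + P(D(z_i))
```

where `F` is the pre-activation main branch (BN–ReLU–Conv(k=17), twice),
`D` a strided 1×1 convolution where shape changes (identity elsewhere), and
`P` a shape-preserving max pool (k=3, s=1, p=1).  The head is dropout →
global average pooling → a fully connected layer and softmax.

MLPO prunes, per tensor, the `round(r·numel)` smallest-|w| weights at the
network level (front conv + FC) and the block level (all REB convolutions,
including the 1×1 skips); batch-norm parameters and biases are never
pruned.  Masks are re-applied after every optimizer step, so the model
trains sparse from the start.

Everything is implemented in NumPy, including the forward/backward passes,
Adam, and Grad-CAM; the only runtime dependencies are the scientific
Python basics plus PyWavelets (denoising ablation), click and PyYAML (CLI).

## Worked example

```python
import numpy as np
from hprnet import (ModelConfig, PruneConfig, SynthConfig, TrainConfig,
                    build_model, count_parameters, prune_l1, nonzero_count,
                    synth_dataset, train_fold, evaluate)

# size audit of the default architecture, dense and pruned at r=0.9
cfg = ModelConfig()
print(count_parameters(cfg))                              # 190738856
print(count_parameters(cfg, PruneConfig(0.9, "mlpo")))    # 19110641

# the same numbers measured on an instantiated model
model = build_model(cfg, seed=0)
prune_l1(model, PruneConfig(0.9, "mlpo"))
print(nonzero_count(model))                               # 19110641

# train a narrow variant on synthetic beats and evaluate it
ds = synth_dataset(SynthConfig(n_per_class=200, noise_sd=0.05, seed=0))
perm = np.random.default_rng(0).permutation(len(ds))
val, train = ds.subset(perm[:200]), ds.subset(perm[200:])
tiny = build_model(ModelConfig(reb_counts=(1,)*9, num_classes=4), seed=0)
tiny, hist = train_fold(tiny, train, val,
                        TrainConfig(max_epochs=10, seed=0,
                                    early_stop_val_acc=0.95))
table, report = evaluate(tiny, val)
print(report.summary())
```

The run above stops after 3 epochs with validation accuracy 1.00; the
summary prints per-class precision/recall/F1 of 100.00% on the held-out
synthetic beats (the four synthetic classes are fully separable at this
noise level).  The first two printed numbers are the dense and the
r=0.9-pruned parameter counts of the default network.

The same operations are available from the shell:

```
hprnet synth --n-per-class 250 --seed 0 --out beats.npz
hprnet params --prune-ratio 0.9 --scope mlpo
hprnet prepare --records-dir mitdb/ --dataset-tag mitbih --out-dir prep/
hprnet train --data beats.npz --reb-counts 1,1,1,1,1,1,1,1,1 --out-dir run/
hprnet gradcam --data beats.npz --out panel.csv
```

`hprnet prepare` with a local MIT-BIH copy reports the per-class beat
counts of the full database; no download is performed by this package.

## Layout

- `hprnet.synthetic` — Gaussian-bump P-QRS-T beat generator
- `hprnet.wfdb_io` — minimal WFDB reader/writer (formats 16/212, MIT
  annotations)
- `hprnet.beats` — segmentation, AAMI symbol maps, stratified folds, tasks
- `hprnet.denoise` — sym8 5-level soft-threshold wavelet denoising
- `hprnet.nn` / `hprnet.model` — NumPy layers and the HPRNet architecture
- `hprnet.prune` — MLPO pruning, masks, sparsity reports
- `hprnet.train` — Adam, plateau schedule, metrics, cross-validation
- `hprnet.gradcam` — 1-D Grad-CAM and saliency panels
- `hprnet.cli` — the `hprnet` console entry point

See `docs/methods.md` for the modelling assumptions, calibration of the
architecture against the published parameter tables, and known limitations.
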