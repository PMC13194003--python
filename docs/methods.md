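# Methods

## Model

HPRNet is a 1-D convolutional residual network for fixed-length heartbeat
classification.  A beat of 128 native samples (no resampling; both 360 Hz
and 257 Hz sources are windowed at native rate) enters a front-end
`Conv1d(1→32, k=17, bias=False) → BatchNorm → ReLU`, then nine ResLayers.
Each ResLayer is a cascade of residual extraction blocks (REBs):

- main branch: pre-activation `BN → ReLU → Conv1d(k=17, p=8)` twice; the
  first conv of a layer's first REB carries that layer's stride and
  channel change, all other convs are stride-1, same-channel, bias-free;
- skip branch: a strided `1×1` conv where the shape changes (first REB of
  a layer), identity elsewhere, followed by a shape-preserving max pool
  (kernel 3, stride 1, padding 1, −inf padding values);
- the block output is the elementwise sum of the two branches.

Channel/stride schedule (in→out, stride): (32→64, 1), (64→64, 2),
(64→128, 2), (128→128, 2), (128→256, 2), (256→256, 2), (256→512, 2),
(512→512, 2), (512→1024, 2); temporal lengths 128, 64, 32, 16, 8, 4, 2, 1,
1 by `len_out = floor((len + 2·8 − 17)/stride) + 1`.  Head: dropout
(p=0.5) → global average pooling → fully connected layer → softmax.

### Calibration of the block internals and head

The published parameter tables (dense total; pruned totals at nine ratios;
two pruning-scope ablations; five REB-count schedules) over-determine the
parts of the block design that the architectural description leaves open.
We treated those eighteen printed counts as the calibration authority and
searched the variant space (front-end composition, conv biases, skip-conv
placement, BN placement, head width, pruning-amount convention)
exhaustively.  Exactly one configuration reproduces the dense total and
sixteen of the seventeen pruned counts simultaneously:

- front-end with a **single** bias-free convolution (the schematic shows
  two; a second 32→32 k=17 conv adds 17,408 parameters that no other
  variant can absorb);
- REB convs bias-free, skip 1×1 conv only in each layer's first REB;
- a fully connected head of **eight** output units (1024×8 + 8) — the
  complexity figures correspond to an 8-logit head even though the
  classification tasks use 4 (or 2/3) classes, so `ModelConfig` defaults
  to `num_classes=8` and task code passes its own class count;
- pruning removes `round(r·numel)` weights **per tensor** (floor-based and
  scope-pooled conventions provably cannot reproduce the printed
  ratio-sweep totals).

The remaining printed count (network-level-only pruning, 190,730,981) is
arithmetically inconsistent with the other seventeen: they force the
network-level scope to be the front conv (544 weights) plus the FC weight
(8,192), and every pruning convention removes 7,861–7,863 of those 8,736
weights at r=0.9, never the 7,875 that the printed value implies.  The
package reports its computed value, 190,730,993 (12 parameters apart,
relative 6×10⁻⁸).

### Complexity accounting

`count_parameters` is a closed-form sum over the tensor table
(conv: `c_in·c_out·k`, BN: `2·channels`, FC: `1024·C + C`) and is verified
against enumeration of the instantiated model in the test suite (20
randomized small architectures) and inside `scripts/acceptance.py` on the
full-size variants.  `count_flops` counts one multiply-accumulate as two
FLOPs over convolutions and the FC layer only (BN, pooling and activations
excluded); under this convention the default network costs ≈986 MFLOPs per
beat.  Published MFLOPs figures use an unstated convention, so FLOPs are a
sanity check, not a target.

## Pruning (MLPO)

Scopes: `network_level` = front conv weight(s) + FC weight; `block_level`
= every REB conv weight including the 1×1 skips; `mlpo` = union.  Per
tensor, the `round(r·numel)` smallest-|w| entries are zeroed with a stable
tie-break (lower flat index pruned first among equal magnitudes).  Binary
masks persist on the model and are re-applied after every optimizer step
(sparse training from initialization; no post-pruning fine-tuning stage —
no retraining schedule is described for the published results, and the
ratio sweep's stable accuracy is consistent with train-with-masks).
Batch-norm parameters and biases are never pruned.

So that literal nonzero counts equal the structural closed form, all
parameters are initialized nonzero: He-normal conv/FC weights, uniform
biases, BN scale 1 and BN shift drawn from N(0, 10⁻³) — functionally
equivalent to the conventional zero shift, and it makes sparsity audits
exact.

## Training protocol

Adam (lr 10⁻³, β = 0.9/0.999), batch size 128, at most 30 epochs,
unweighted categorical cross-entropy.  "Adaptive" learning rate realized
as reduce-on-plateau: halve after the validation loss fails to improve for
4 consecutive epochs (patience 3), floor 10⁻⁵.  The model returned from a
fold is the best-validation-loss checkpoint.  Cross-validation is
beat-level (intra-patient) stratified k=5; within each round a stratified
10% slice of the training pool is held out as the validation set for
scheduling and model selection (the published protocol does not state the
inner split).  Metrics come from the raw confusion table, one-vs-rest per
class; macro scores are unweighted class means; values are stored at full
precision and printed at two decimals.  A class absent from a test set
scores recall/F1 0 with a logged warning.

## Synthetic data

The generator emulates the single-beat morphology that the classifier
exploits, not ECG physiology: each class is a sum of Gaussian bumps on
[0, 1) (amplitudes normalized to R = 1), plus a baseline-wander sinusoid
with random phase and white noise.  Class variants: N has P-Q-R-S-T; the
S-like class drops the P wave and narrows the QRS; the V-like class widens
the QRS 3× with higher amplitude and inverts the T wave; F is the average
of the N and V templates.  Defaults: 128 samples at a nominal 360 Hz,
noise_sd 0.05 (fraction of R amplitude), wander 0.05 at 0.33 Hz, 250 beats
per class.  The R bump is centered at sample length/2, mirroring the
R-centered windowing of real records.

What passing on this data shows: the training loop optimizes, the
architecture separates morphologically distinct classes, pruned models
stay trainable, and saliency lands on class-discriminative waveform
segments.  What it does not show: robustness to real recording artifacts,
inter-patient variability, or the heavy class imbalance of clinical
archives — real-database results require the archives themselves.

On the trained synthetic model, V-class Grad-CAM concentrates on the
inverted-T / late-QRS region (samples ≈85–106; the inverted T is centered
near sample 100).  That is the correct discriminator for this generator —
the T-wave polarity separates V from N/S more cleanly than QRS width does
— and the localization regression test freezes exactly that behaviour.

## Grad-CAM

Maps are computed from the pre-softmax logit: channel weights are the
temporal mean of ∂logit/∂activation at the probed ResLayer output, the map
is `ReLU(Σ_c w_c A_c)`, linearly interpolated (endpoint-aligned) to the
input length, then min-max normalized to [0, 1]; an identically zero map
stays zero.  Deep layers have very coarse maps (length 4 at ResLayer5 for
128-sample input), so argmax locations are quantized to interpolation
knots — localization statements at deep layers carry ±1-cell uncertainty
by construction.

## Denoising (ablation path)

sym8 wavelet, 5 decomposition levels, symmetric extension, soft
thresholding of all detail levels at the universal threshold
σ·sqrt(2·ln N) with σ = median(|finest detail|)/0.6745.  Validity requires
length ≥ 2^levels; 128-sample beats technically admit 5 levels but all
coefficients are boundary-affected, so denoising is applied per record
before segmentation.  The headline pipeline is non-denoised; the CLI flag
`--denoise` enables the stage.

## Numerical choices

Float32 arithmetic throughout the network (the test suite re-derives
gradients in float64 against finite differences); im2col convolutions
evaluated as a single GEMM; max-pool padding uses −inf; z-scored beats
with zero variance map to all-zero rows; softmax is max-shifted;
cross-entropy clamps probabilities at 10⁻¹².  Determinism: every stochastic
component (generator, fold shuffling, initialization, batch order,
dropout) is driven by an explicit seed; repeated runs are bit-identical up
to BLAS reduction order.

## Problem sizes used in the checks

The shipped tests train a full-width single-REB-per-layer network
(reb_counts [1]×9) on 800 synthetic beats — enough to demonstrate
optimization, pruning-mask persistence and saliency behaviour at a few
minutes of CPU — and verify all parameter accounting on the full-size
architectures closed-form plus by enumeration.  The acceptance script
instantiates the full 190M-parameter (and 250M-parameter) variants
explicitly and prunes them tensor by tensor.

## Known limitations

- Beat-level (intra-patient) cross-validation: splits share patients
  between train and test, as in the published protocol; inter-patient
  evaluation is future work.
- Annotations are trusted as R-peak ground truth; no peak detection.
- Single lead only; no multi-lead fusion, no rhythm-episode labeling.
- The WFDB reader covers single-segment format 16/212 records with
  MIT-format annotations — sufficient for the two target archives, not a
  general WFDB implementation.
- The published network-level-only pruned count cannot be reproduced
  exactly (see calibration above); the 12-parameter discrepancy is
  reported, not hidden.
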