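# Methods

## Problem and model

`mnattnet` scores single-lymphocyte photomicrographs for the presence of a
micronucleus (MN) — a small, round DNA-containing body separate from the
main nucleus that serves as a biomarker of genotoxic damage. The classifier
is a truncated AlexNet fused with a two-branch spatial attention module:

* **Backbone.** The canonical five-convolution AlexNet stack with every
  dense layer removed (2.47 M parameters instead of 61.1 M). Three taps are
  exposed: the outputs of the 4th and 5th convolution blocks, `M5` and `M6`
  (both 256×13×13 for a 224×224 input), and the final max-pooled map
  `L` (256×6×6). `M5`/`M6` are the only adjacent same-resolution
  256-channel pair in the stack, which the attention shape algebra
  requires; the tap naming ("layer-5", "layer-6") follows the block
  indices. No layer is ever frozen.
* **Attention gate.** The deepest map leads: `F_l = bilinear(W_l ⊗ L)`
  (1×1 convolution then bilinear 6×6 → 13×13). Each branch projects its
  middle tap, `F_m = W_m ⊗ M`, and forms
  `A = σ(W ⊗ ReLU(F_l + F_m))` with a single-channel 1×1 convolution, so
  `A ∈ (0,1)^{1×13×13}`. The attended feature is the broadcast product
  `F̄ = A ⊙ F_m`. `F_l` is computed once and shared by both branches
  (minimal-parameter reading); each branch owns its `W_m` and gate `W`.
* **Head.** `F_g = cat(GAP(F̄5), GAP(F̄6), GAP(L))` ∈ R^768, then an
  affine 768 → 2 map with softmax; index 1 = micronucleus present.

Two printed descriptions of this architecture are mutually inconsistent
and required a canonical reading, recorded here as the package's design:
the attended operand is the 256-channel projection `F_m` (the gate output
`F` is single-channel, so attending it would be degenerate), and the
classifier consumes pooled features only — concatenating the raw image
into `F_g` is shape-incoherent. Global average pooling is the spatial
reduction (adds no parameters, consistent with the fewer-parameters goal).
Bilinear interpolation uses the half-pixel-centers (non-align-corners)
convention everywhere, including the test oracles; the upsampler is
implemented as two fixed interpolation matrices, so its backward pass is
the exact transpose.

## Loss

Focal loss on the positive-class probability,
`L(p,y) = −y(1−p)^γ log p − (1−y)p^γ log(1−p)`, with γ = 2 by default;
γ = 0 recovers cross-entropy exactly and is exposed as the `cross_entropy`
ablation pathway. There is no α balancing term — imbalance is handled by
the dataset pipeline. Probabilities are clamped to [1e−7, 1−1e−7] inside
logarithms; batch reduction is the mean. The gradient with respect to the
two logits is implemented in closed form (the 1/p singularities cancel
against the softmax Jacobian), verified against central finite differences.

## Dataset pipeline

Per class, samples are split 6:2:2 with train = ceil, test = floor,
val = remainder — the unique simple rounding that reproduces the reference
class totals (726 → 436/145/145; 10419 → 6252/2084/2083). Augmentation is
five-fold per image: original, random rotation θ ~ U(−180°, 180°), that
rotation flipped horizontally, flipped vertically, and rescaled by
s ~ U(0.85, 1.15) (ranges are package choices; images are resampled
bicubically with reflect padding, masks with nearest-neighbour so they
stay binary). Train positives are augmented and train negatives randomly
downsampled to the augmented-positive pool size (2180 at study scale; the
reference tabulation lists 2191, which no stated rule produces, so the
target is config-overridable rather than imitated). TAD augments the train
split only; TVAD additionally augments the whole validation split, without
downsampling its negatives (2084·5 = 10420 at study scale). The test split
is never augmented. Manifests store the per-record transform parameters,
so pixels materialize lazily and deterministically, and a provenance-graph
check enforces that no augmented record crosses its parent's split.

## Training

SGD with Nesterov momentum 0.9, weight decay 5e−4 (weights only), batch
size 32, and the step schedule lr = 0.01 · 0.1^floor(epoch/20) over 60
epochs by default. After each epoch the model is scored on the validation split by
ROC-AUC; the earliest-best epoch's weights are the selected checkpoint,
and the test split is evaluated once, on that checkpoint only.

Training this architecture from scratch with plain momentum-SGD at
lr = 0.01 is numerically delicate: the pooled features `F_g` carry a large
uncentered common component (‖F_g‖ ≈ 50 at He init), which makes the head's
loss surface badly conditioned — the whole batch's logits swing together
and the network collapses to constant output. Four numerical choices make
the stated schedule trainable, none of which changes the function class:

* `F_g` is standardized (parameter-free, batch-norm style, no affine
  terms) before the affine classifier; at inference the fixed
  standardization composes with the affine head, while its backward pass
  projects the common-mode component out of the upstream gradient;
* the head weights start at the classic small scale N(0, 0.01²), so the
  model begins near p = 0.5 instead of confidently wrong;
* gate weights are initialized non-negative (their input is post-ReLU)
  and scaled so the initial pre-activation is O(1): attention starts
  positively correlated with feature magnitude — its intended "highlight"
  polarity — without saturating the sigmoid;
* gradients are clipped to global norm 1.0 (config-exposed), and the
  standardization statistics are recalibrated over the training images
  before each validation pass, since statistics tracked mid-epoch
  describe weights that have since moved.

He-normal initialization is used for all convolutions when training from
scratch, and input normalization uses training-set channel statistics
(ImageNet constants in pretrained mode; loading pretrained convolution
weights is an optional flag and never required).

## Metrics

Confusion matrix (predicted positive iff score ≥ threshold, default 0.5),
precision, recall, F1, sensitivity (= recall), specificity, ROC-AUC
(trapezoid over tie-grouped thresholds, equal to Mann–Whitney concordance
with ties counted ½), and step-wise average precision (tied scores grouped
at one threshold). Zero-denominator conventions: precision = 0 when
TP+FP = 0, F1 = 0 when precision+recall = 0. All are hand-implemented and
cross-checked in tests against O(n²) brute-force oracles and scikit-learn.

## Synthetic data

The real assay images are not public, so the package ships a generator
whose frames emulate their structure: pale background, pink cytoplasm
ellipse, dark violet nucleus, and (positives) one micronucleus disc of
radius 3–7 px lying inside the cytoplasm and clear of the nucleus, with a
pixel-exact ground-truth mask. Three confounders are modeled, with
per-image probabilities 15% / 15% / 10%: stain-contamination specks (dark
discs drawn from the micronucleus size range, placed outside the
cytoplasm, so they never touch the mask), understained cells (stain level
0.25–0.45 versus 0.8–1.0, blending all cell colors toward the background),
and two-cell frames. Rendering adds Gaussian grey-level noise (σ = 4) and
then a Gaussian point-spread blur (σ = 0.8 px) emulating microscope
optics; the blur is essential, because crisp iid pixel noise is an
artifact real photomicrographs do not have, and it would otherwise let a
classifier distinguish interpolated (augmented) from original frames by
texture alone instead of by the micronucleus. All geometry ranges are
self-chosen and deliberately not presented as calibrated to any real
scanner or magnification; passing tests on this data demonstrate that the
architecture, losses, pipeline and training loop behave as specified, not
that the model would reach any particular accuracy on clinical images.

## Interpretability

Attention maps are bilinearly upsampled to 224×224 and min-max normalized
(constant maps normalize to zero). Localization is quantified as the mean
heatmap value inside the ground-truth micronucleus mask — dilated by 3 px
to absorb the 13 → 224 resolution gap — divided by the mean outside; a
ratio above 1 means attention concentrates on the micronucleus. On trained
synthetic models the median layer-6 ratio over held-out positives exceeds
1; the layer-5 branch is reported as a statistic but not asserted, since
shallow maps often carry little spatial signal.

## Implementation and problem sizes

The network, backpropagation and optimizer are implemented directly on
numpy (float32, im2col + BLAS matmuls; max-pool and convolution backward
passes scatter by kernel offset). Every layer's backward pass is verified
against finite differences, and the convolution stack against an
independent scipy direct-convolution oracle. The bundled desk-scale
experiment trains on 400 generated frames (10% positive, TVAD manifests,
10 epochs) — a deliberately small configuration chosen so that a full
train-select-evaluate cycle completes in minutes on a single CPU while
still being hard enough that chance-level models fail its thresholds
(validation AUC ≥ 0.90, median layer-6 localization ratio > 1).

## Known limitations

* No photo-realistic microscopy simulation; the generator's palette and
  geometry are stylized.
* Single 224×224 input size only, matching the architecture's tap algebra.
* ImageNet pretraining is supported only by loading an existing
  convolution-weight checkpoint; the package never downloads weights.
* Training at the study's full scale (≈15k images, 60 epochs) is supported
  by the same code paths but is compute-bound on CPU.
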