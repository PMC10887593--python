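# Methods

This note records the modelling and numerical decisions behind
`pneumofusion`, in the spirit of a model-description appendix: what the
components compute, which parameters matter, what the synthetic fixture
does and does not emulate, and where genuinely open design choices were
resolved.

## Architecture

The classifier is a two-branch convolutional network. Each branch is a
backbone feature extractor (EfficientNetB0 → 7×7×1280, DenseNet121 →
7×7×1024 on 224×224×3 input, or the `tiny_test` stride-2 conv stack for
CPU-scale work) whose final convolutional map is refined by multi-head
self-attention, followed by channel-attention feature fusion, a residual
block, an attention-augmentation gate, dynamic attention pooling, and a
regularized two-way softmax head.

Decisions where the architecture description leaves room:

* **Spatial tokens for attention.** A rank-4 map (b, h, w, c) enters
  multi-head attention as h·w tokens in row-major order with the channel
  vector as the token embedding. No positional encoding and no residual
  connection are used around the attention block: its output *replaces*
  the feature map, so the "remove multi-head attention" ablation is an
  exact identity bypass.
* **Fusion reshape order.** The 784-unit fused vector is reshaped
  row-major (last axis fastest) to (7, 7, 16). Any fixed convention works;
  row-major is pinned for reproducibility.
* **Dynamic pooling order.** The spatial sigmoid gate is applied to the
  feature map *before* global average pooling (multiply-then-pool). The
  alternative reading — gating the already-pooled vector — does not
  type-check, since the spatial gate has h×w entries while the pooled
  descriptor has none.
* **Attention augmentation axis.** The two dense layers of the gate act on
  the channel axis at each spatial position — the only reading for which a
  Dense(channels) layer composes with a rank-4 input. Note the gate's
  post-sigmoid batch norm can push gate values outside [0, 1] once
  trained; the [0, 1] containment guarantee holds exactly when that batch
  norm is the identity.
* **Residual block depth.** "Standard architecture" is implemented as two
  3×3 conv + BN + ReLU stages, stride 1, same padding, with an identity
  shortcut (1×1 projection when channel counts differ), 256 filters.
* **Simple-fusion bypass.** The "dimensionality reduction followed by
  concatenation" ablation pools each branch, reduces it with a
  Dense(392, ReLU), concatenates to 784 and reshapes to (7, 7, 16), so all
  downstream shapes are unchanged.
* **Head constants.** Dropout 0.2377 and L2 coefficient 6.72×10⁻³ are the
  tuned values; 0.23 and 0.006 that appear in block definitions are their
  two-significant-figure roundings. One global dropout value is applied.

## The numpy autodiff core

All layers run on a small reverse-mode tape engine (`pneumofusion.nn`):
float32, NHWC, im2col convolutions, analytic softmax/sigmoid/swish
backward passes. Gradients are retained at every tape node, which is what
lets Grad-CAM read ∂(class logit)/∂(any internal activation) without
framework hooks. Every primitive's gradient is validated against central
finite differences in the test suite.

Numerical choices:

* **Batch norm**: momentum 0.9, eps 1e-3, statistics over all axes but
  channels. After training completes, the exponential moving averages are
  replaced by exact dataset averages of the batch moments (one shuffled
  sweep in batch-statistics mode with dropout off). After short
  small-batch runs the EMA is noisy and biased toward the last updates;
  without this re-estimation, eval-mode predictions can diverge badly
  from train-mode behaviour.
* **Initialization**: Glorot uniform everywhere except the bias-free
  `tiny_test` convolutions, which use He-scaled normal init — without
  batch norm, Glorot under-scales a ReLU stack and stalls from-scratch
  training.
* **Loss**: categorical cross-entropy over one-hot labels with per-sample
  class weights, normalized by the total weight (so zero-weight samples
  drop out of both numerator and denominator), plus the head's L2 kernel
  penalty. Probabilities are clamped with eps 1e-7 inside the log.
* **Warmup schedule**: lr(step) = peak · min(1, (step+1)/warmup_steps),
  constant afterwards; warmup_steps defaults to one epoch of updates.
  The schedule form is the simplest consistent with a "warmup" and is
  fully configurable.
* **Adam**: β₁ 0.9, β₂ 0.999, eps 1e-7, bias-corrected.

## Pretrained weights

Only randomly initialized backbones are supported. The EfficientNetB0 and
DenseNet121 implementations follow the published architectures (asserted
at build time to produce 7×7×1280 / 7×7×1024 on 224-input), but no weight
source ships with the package, so results on real chest X-rays at the
published scale are out of scope here; the architecture, training loop and
evaluation stack are the same code paths the tiny backbone exercises.

## Evaluation

Metrics come from the integer confusion matrix with "pneumonia" as the
positive class; any metric with an empty denominator is reported as
undefined (`None`), never silently zero — tiny cross-validation folds can
produce such cases. AUC is the rank statistic P(s⁺ > s⁻) + ½P(tie),
identical to the trapezoidal area under the empirical ROC curve.

`recover_confusion` treats published two-decimal percentages as
**truncations**, not roundings, of the exact fractions: for a 390-positive
test set, 366/390 = 93.846…% prints as 93.84 only under truncation
(rounding would give 93.85), and truncation is the convention under which
all five published test metrics are simultaneously consistent with a
single integer matrix (TP 366, FN 24, FP 6, TN 228). The search is
exhaustive over TP ∈ [0, n₊] × TN ∈ [0, n₋] and errors on zero or
multiple solutions, so uniqueness is verified, not assumed.

## Hyperparameter search

The search space is batch size {8, 16, 32}, dropout [0.2, 0.5], L2
[1e-4, 1e-2] (log), learning rate [1e-5, 1e-3] (log), 20 trials. No
installed optimizer provides a TPE sampler, so the package implements a
compact one: 8 random startup trials; thereafter observations are split at
the top-25% quantile, continuous dimensions model good/bad sets with
Gaussian KDEs (bandwidth 0.2× Scott, one pseudo-count of uniform prior to
keep the density ratio bounded at the box edges) and propose the candidate
maximizing l(x)/g(x); categorical dimensions use smoothed frequency
ratios. On a deterministic quadratic benchmark the sampler's 20-trial
best lands in the top decile of a 1000-point random sweep for 30/30
seeds.

## The synthetic fixture

`generate_synthetic_dataset` writes `<split>/<class>/*.png` 8-bit
grayscale images: a mid-gray field (intensity 150), two dark elliptical
"lung fields" (55), Gaussian pixel noise (sd 6), and — for the pneumonia
class — 2–5 blurred bright opacity blobs (amplitude 140, radius 3–8% of
the image side, blur sigma 4) planted inside the lung fields. PNG is used
for bit-exact determinism (identical config + seed ⇒ identical files);
the loading path also accepts JPEG.

What the fixture emulates: the two-class directory layout, a
bright-opacity-in-dark-lung contrast cue, class imbalance when built with
`scaled_source_counts` (train ≈ 74% pneumonia). What it does not: anatomy,
acquisition physics, inter-patient variability, label noise. Passing
smoke tests therefore demonstrates that the pipeline can learn a planted,
separable signal end-to-end — not clinical performance.

By construction the mean intensity of pneumonia images strictly exceeds
that of normal images. Per-image histogram equalization — a monotone remap
that flattens each image's intensity distribution — removes precisely that
global-intensity cue. The two end-to-end studies use this deliberately:

* the **training smoke test** (200 images/class, 5 epochs, batch 8, warmup
  Adam, class weights) runs with equalization off, so the documented
  separability cue is available and ≥95% training accuracy is expected;
* the **full-vs-ablated comparison** runs with equalization on, so neither
  model can saturate on the trivial cue and the comparison measures the
  value of the attention components; the full model is required to beat
  the all-components-removed bypass on validation accuracy in ≥3 of 5
  seeded runs. At ceiling (both models ≥95%) this comparison would only
  measure noise.

Both studies use learning rate 1e-3 — the top of the tuned search range —
rather than the 7.47×10⁻⁵ default: that default was tuned for fine-tuning
pretrained backbones, while the fixture studies train ~900k parameters
from random init in 250 steps. The `TrainingConfig` default remains
7.47×10⁻⁵.

## Known limitations

* Training is CPU-scale: the tiny backbone stands in for the full
  backbones in all end-to-end tests; the full backbones are validated for
  geometry and finite forward passes only.
* Grad-CAM localization is only meaningful on layers that precede the
  fusion reshape (e.g. `fusion/multiply_eff`): global average pooling
  followed by a dense projection and reshape scrambles spatial
  correspondence, so post-reshape heatmaps are abstract. The
  interpretability tests therefore check blob localization on a
  pre-fusion layer.
* Histogram equalization is applied to all splits when enabled; whether
  it should apply to training data only is exposed as a config flag
  rather than decided.
* Dropout shares one global rate per block as configured; per-layer rates
  are not exposed.
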