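# pneumofusion

A library and CLI for binary pneumonia detection in chest X-ray images
with a **dual-backbone, attention-ensemble convolutional classifier**, plus
everything needed to study the model on a single CPU: a synthetic
X-ray-like fixture generator, a class-weighted training harness,
confusion-matrix evaluation, TPE hyperparameter search, and Grad-CAM
interpretability.

It is aimed at researchers and students of medical image analysis who want
a transparent, fully inspectable implementation of this architecture —
every layer, gradient and attention map is plain numpy and can be read,
probed and unit-tested.

## The model

An input X-ray (224×224×3, grayscale replicated to three channels, scaled
to [0, 1], optionally histogram-equalized) flows through:

1. **Feature extraction** — two convolutional backbones in parallel,
   EfficientNetB0 (7×7×1280 final map) and DenseNet121 (7×7×1024), or a
   tiny stride-2 conv stack for CPU work. Each branch's feature map is
   refined by **multi-head self-attention** over its h·w spatial tokens
   (4 heads, key dimension 128):

   Attention(Q, K, V) = softmax(QKᵀ/√d_k) V

2. **Channel-attention feature fusion** — each branch is gated by a
   1×1-conv sigmoid channel-attention map (F ⊙ A), globally average
   pooled, projected to a 784-unit space (ReLU, dropout 0.23), summed
   across branches, and reshaped to 7×7×16.
3. **Enhancement** — a 256-filter residual block (two 3×3 conv + BN + ReLU
   stages with a shortcut), an **attention-augmentation** gate
   (Dense-ReLU → BN → Dropout → Dense-sigmoid → BN → Dropout, applied as a
   Hadamard product), and **dynamic attention pooling** (a learned spatial
   sigmoid gate weighting the map before global average pooling).
4. **Classifier** — Dense(128, ReLU, L2 = 6.72×10⁻³) → BatchNorm →
   Dropout(0.2377) → Dense(2, softmax).

Training uses Adam with a linear warmup schedule, categorical
cross-entropy with per-class weights `w_c = n_total / (n_classes · n_c)`,
and seeds every source of randomness. Each of the four bespoke components
has an identity/simple bypass so ablation studies are one config flag.

Evaluation reports accuracy, precision, recall, F1 and specificity from
the confusion matrix, rank-based AUC, and stratified k-fold
cross-validation. `recover_confusion` inverts published two-decimal metric
values back to the unique integer confusion matrix behind them.

No deep-learning framework is required: the package ships a compact
reverse-mode autodiff engine (`pneumofusion.nn`) with NHWC conv / batch
norm / attention primitives, which also gives Grad-CAM direct access to
the gradient at any named internal layer.

## Worked example

```python
import numpy as np
from pneumofusion import (ModelConfig, SyntheticConfig, TrainingConfig,
                          generate_synthetic_dataset)
from pneumofusion.preprocessing import PreprocessConfig
from pneumofusion.training import manifest_accuracy, train_fresh

manifests = generate_synthetic_dataset(
    SyntheticConfig(n_per_class=200, seed=3), "data")
cfg = TrainingConfig(epochs=5, batch_size=8, peak_lr=1e-3, seed=0,
                     preprocess=PreprocessConfig(equalize=False),
                     class_weights={"normal": 1.0, "pneumonia": 1.0})
model, history = train_fresh(ModelConfig(), manifests["train"], cfg)
print([round(a, 3) for a in history.accuracy])
print(round(manifest_accuracy(model, manifests["train"], cfg.preprocess), 3))
```

prints (per-epoch running training accuracy, then the trained model's
training-set accuracy):

```
[0.642, 0.79, 0.863, 0.922, 0.96]
1.0
```

The synthetic "pneumonia" images carry bright blurred opacities inside
dark elliptical lung fields, so the two classes are separable by
construction and five epochs suffice for the tiny-backbone model to fit
them; Grad-CAM heatmaps of the trained model concentrate on the planted
opacities.

The same workflow is available from the shell:

```bash
pneumofusion synth --out data --n-per-class 200 --seed 3
pneumofusion train --config run.yaml --data data --out run
pneumofusion evaluate --model run/model.npz --data data/test --report report.json
pneumofusion gradcam --model run/model.npz --image img.png \
    --layer post_reshape_conv --out heatmap.png
pneumofusion tune --config run.yaml --data data --trials 20
```

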