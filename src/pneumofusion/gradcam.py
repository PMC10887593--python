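"""Grad-CAM heatmaps on named internal layers of the assembled model.

For a chosen rank-4 activation A with channels A_k, the channel weights
are the spatial means of d(class logit)/dA_k; the raw map is
ReLU(sum_k alpha_k A_k), min-max normalized to [0, 1] (a constant map is
defined as all zeros) and bilinearly upsampled to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .fixtures import CLASSES
from .model import PneumoniaAttentionNet
from .nn import Tensor


@dataclass
class HeatmapResult:
    heatmap: np.ndarray  # (H, W) in [0, 1], input resolution
    raw_map: np.ndarray  # pre-upsampling weighted activation map
    layer_name: str
    target_class: str
    raw_min: float
    raw_max: float


def cam_from_activation(activation: np.ndarray,
                        grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized class-activation maps for one (h, w, c) layer.

    alpha_k = spatial mean of the gradient for channel k;
    raw = ReLU(sum_k alpha_k A_k); normalized = min-max to [0, 1]
    (all zeros if the raw map is constant).
    """
    alpha = grad.mean(axis=(0, 1))
    raw = np.maximum((activation * alpha).sum(axis=-1), 0.0)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0:
        return raw, np.zeros_like(raw)
    return raw, (raw - lo) / (hi - lo)


def gradcam(model: PneumoniaAttentionNet, image: np.ndarray,
            layer_name: str, target_class: str) -> HeatmapResult:
    """Compute a Grad-CAM heatmap for one preprocessed image.

    ``image`` is a single (H, W, 3) float array (or a batch of one); the
    class score is the pre-softmax logit of ``target_class``.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    if image.ndim != 4 or image.shape[0] != 1:
        raise ValueError("gradcam expects a single image")
    if target_class not in CLASSES:
        raise ValueError(f"unknown class {target_class!r}")
    class_index = CLASSES.index(target_class)

    model.eval()
    model.zero_grad()
    model(Tensor(image))
    if layer_name not in model.activations:
        raise KeyError(f"unknown layer {layer_name!r}; available: "
                       f"{sorted(model.activations)}")
    activation = model.activations[layer_name]
    if activation.ndim != 4:
        raise ValueError(f"layer {layer_name!r} is not a rank-4 activation")
    logits = model.activations["logits"]
    seed = np.zeros_like(logits.data)
    seed[0, class_index] = 1.0
    logits.backward(seed)
    if activation.grad is None:
        grad = np.zeros_like(activation.data)
    else:
        grad = activation.grad
    raw, normalized = cam_from_activation(activation.data[0], grad[0])
    lo, hi = float(raw.min()), float(raw.max())
    upsampled = resize(normalized, image.shape[1:3], order=1,
                       preserve_range=True, anti_aliasing=False)
    return HeatmapResult(heatmap=np.clip(upsampled, 0.0, 1.0), raw_map=raw,
                         layer_name=layer_name, target_class=target_class,
                         raw_min=lo, raw_max=hi)
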