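"""Image preprocessing: histogram equalization, augmentation, input scaling
to the 224x224x3 network input, and class-weight computation.

Augmentation parameters follow the usual medical-imaging defaults used for
this task: rotation +/-15 deg, shift 0.1 of the side, shear 0.2, zoom 0.2
(scale in [0.8, 1.2]), multiplicative brightness in [0.8, 1.2], nearest-edge
boundary fill.  All random draws come from a caller-supplied generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_deg: float = 15.0
    shift_frac: float = 0.1
    shear: float = 0.2
    zoom_frac: float = 0.2
    brightness_range: tuple[float, float] = (0.8, 1.2)
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        if min(self.rotation_deg, self.shift_frac, self.shear,
               self.zoom_frac) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        lo, hi = self.brightness_range
        if lo > hi:
            raise ValueError("brightness_range must satisfy low <= high")


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: tuple[int, int] = (224, 224)
    channels: int = 3
    equalize: bool = True

    def __post_init__(self):
        if min(self.target_size) <= 0:
            raise ValueError("target_size must be positive")
        if self.channels != 3:
            raise ValueError("the network expects 3 input channels")


# ----------------------------------------------------------------------
def histogram_equalize(img: np.ndarray) -> np.ndarray:
    """Classical CDF histogram equalization of an 8-bit grayscale image.

    out(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255), where cdf_min
    is the CDF at the lowest occurring intensity.  A constant image (where
    cdf_min = N and the denominator vanishes) maps to all zeros.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("histogram_equalize expects a single-channel image; "
                         "equalize before channel replication")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("histogram_equalize expects an integer image")
    hist = np.bincount(img.reshape(-1).astype(np.int64), minlength=256)
    cdf = np.cumsum(hist)
    n = img.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min == n:  # constant image: degenerate denominator
        return np.zeros_like(img, dtype=np.uint8)
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


# ----------------------------------------------------------------------
def _affine_about_center(shape, rotation_rad, shear_rad, scale, shift):
    """Compose zoom/rotation/shear about the image center plus a shift."""
    h, w = shape
    center = np.array([w / 2.0 - 0.5, h / 2.0 - 0.5])
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=rotation_rad, shear=shear_rad,
                               scale=(scale, scale))
             + AffineTransform(translation=center + shift))
    return tform


def augment(img: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply one random rotation/shift/shear/zoom/brightness augmentation.

    Works on float images in [0, 1] (the post-scaling representation) or
    uint8; output matches the input dtype and range.  The four geometric
    draws are composed into a single affine warp with nearest-edge fill;
    brightness is a multiplicative factor applied afterwards and clipped to
    the valid intensity range.
    """
    img = np.asarray(img)
    was_uint8 = img.dtype == np.uint8
    work = img.astype(np.float64) / 255.0 if was_uint8 else \
        img.astype(np.float64)

    rot = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shift = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * \
        np.array([img.shape[1], img.shape[0]])
    shear = rng.uniform(-cfg.shear, cfg.shear)
    scale = rng.uniform(1.0 - cfg.zoom_frac, 1.0 + cfg.zoom_frac)
    brightness = rng.uniform(*cfg.brightness_range)

    identity = (rot == 0.0 and shear == 0.0 and scale == 1.0
                and not shift.any())
    if not identity:
        tform = _affine_about_center(work.shape[:2], rot, shear, scale, shift)
        mode = "edge" if cfg.fill_mode == "nearest" else cfg.fill_mode
        if work.ndim == 3:
            planes = [warp(work[..., c], tform.inverse, mode=mode, order=1)
                      for c in range(work.shape[-1])]
            work = np.stack(planes, axis=-1)
        else:
            work = warp(work, tform.inverse, mode=mode, order=1)
    work = np.clip(work * brightness, 0.0, 1.0)
    if was_uint8:
        return np.round(work * 255.0).astype(np.uint8)
    return work.astype(img.dtype)


# ----------------------------------------------------------------------
def preprocess(img: np.ndarray,
               cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Raw grayscale image -> (H, W, 3) float32 array in [0, 1].

    Pipeline: bilinear resize to target_size, optional histogram
    equalization (on the 8-bit grayscale, before channel replication),
    replicate to 3 channels, scale to [0, 1].
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot preprocess a zero-sized image")
    if img.ndim == 3:  # collapse RGB inputs to grayscale first
        img = np.round(img.mean(axis=-1)).astype(np.uint8)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if img.shape != cfg.target_size:
        resized = resize(img.astype(np.float64), cfg.target_size, order=1,
                         preserve_range=True, anti_aliasing=False)
        img = np.clip(np.round(resized), 0, 255).astype(np.uint8)
    if cfg.equalize:
        img = histogram_equalize(img)
    scaled = img.astype(np.float32) / 255.0
    return np.repeat(scaled[:, :, None], cfg.channels, axis=2)


def preprocess_batch(images, cfg: PreprocessConfig = PreprocessConfig()
                     ) -> np.ndarray:
    return np.stack([preprocess(im, cfg) for im in images])


# ----------------------------------------------------------------------
def compute_class_weights(class_counts: dict[str, int]) -> dict[str, float]:
    """Balanced class weights w_c = n_total / (n_classes * n_c).

    Satisfies the conservation identity sum_c n_c * w_c = n_total, so the
    weighted loss keeps the scale of the unweighted one.
    """
    if any(count <= 0 for count in class_counts.values()):
        raise ValueError("every class must have a positive count")
    n_total = sum(class_counts.values())
    n_classes = len(class_counts)
    return {label: n_total / (n_classes * count)
            for label, count in class_counts.items()}
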