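"""Class-weighted training loop with warmup Adam, plus dataset plumbing.

The loss is categorical cross-entropy over one-hot labels with per-sample
class weights (normalized weighted mean, so zero-weight classes contribute
exactly nothing), plus the head's L2 kernel penalty.  The learning rate
ramps linearly from peak_lr/warmup_steps to peak_lr over the first
``warmup_steps`` updates and stays constant afterwards.  All randomness
(shuffling, dropout, init) is keyed off the config seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .fixtures import CLASSES, DatasetManifest, load_manifest_images
from .model import ModelConfig, PneumoniaAttentionNet
from .nn import Adam, Tensor
from .preprocessing import (AugmentationConfig, PreprocessConfig, augment,
                            preprocess)

POSITIVE_CLASS = "pneumonia"


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 5
    batch_size: int = 8
    peak_lr: float = 7.47e-5
    warmup_steps: int | None = None  # None -> one epoch of steps
    class_weights: dict[str, float] | None = None
    augmentation: AugmentationConfig | None = None
    preprocess: PreprocessConfig = PreprocessConfig()
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be > 0")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def warmup_schedule(step: int, peak_lr: float, warmup_steps: int) -> float:
    """Linear ramp to peak_lr over warmup_steps updates, then constant."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if warmup_steps <= 0:
        return peak_lr
    return peak_lr * min(1.0, (step + 1) / warmup_steps)


def one_hot(labels: list[str], classes: tuple[str, ...] = CLASSES
            ) -> np.ndarray:
    index = {label: i for i, label in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)), dtype=np.float32)
    for row, label in enumerate(labels):
        out[row, index[label]] = 1.0
    return out


def weighted_cross_entropy(probs: Tensor, targets: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Normalized weighted categorical cross-entropy.

    loss = sum_i w_i * ce_i / sum_i w_i, so samples with zero weight drop
    out of both numerator and denominator.
    """
    eps = 1e-7
    ce = -(Tensor(targets) * probs.log(eps)).sum(axis=1)
    w = Tensor(weights.astype(np.float32))
    total_w = float(weights.sum())
    if total_w <= 0:
        raise ValueError("at least one sample must have positive weight")
    return (ce * w).sum() * (1.0 / total_w)


# ----------------------------------------------------------------------
def _prepare_arrays(manifest: DatasetManifest, cfg: PreprocessConfig
                    ) -> tuple[np.ndarray, list[str]]:
    """Decode + preprocess every manifest image once, keeping grayscale."""
    images = load_manifest_images(manifest)
    # keep the single-channel [0,1] plane; channels replicated per batch so
    # augmentation can run on the 2-D image
    planes = [preprocess(im, cfg)[:, :, 0] for im in images]
    return np.stack(planes).astype(np.float32), manifest.labels()


def _to_batch(planes: np.ndarray, channels: int = 3) -> np.ndarray:
    return np.repeat(planes[:, :, :, None], channels, axis=3)


def predict_manifest(model: PneumoniaAttentionNet, manifest: DatasetManifest,
                     cfg: PreprocessConfig = PreprocessConfig(),
                     batch_size: int = 16) -> tuple[np.ndarray, list[str]]:
    """Class probabilities for every image of a manifest (eval mode)."""
    planes, labels = _prepare_arrays(manifest, cfg)
    model.eval()
    probs = []
    for start in range(0, len(planes), batch_size):
        batch = _to_batch(planes[start:start + batch_size])
        probs.append(model(Tensor(batch)).data)
    return np.concatenate(probs), labels


def manifest_accuracy(model: PneumoniaAttentionNet,
                      manifest: DatasetManifest,
                      cfg: PreprocessConfig = PreprocessConfig()) -> float:
    probs, labels = predict_manifest(model, manifest, cfg)
    predicted = [CLASSES[i] for i in probs.argmax(axis=1)]
    return float(np.mean([p == t for p, t in zip(predicted, labels)]))


# ----------------------------------------------------------------------
def calibrate_batchnorm(model: PneumoniaAttentionNet, planes: np.ndarray,
                        rng: np.random.Generator,
                        batch_size: int = 32) -> None:
    """Replace EMA batch-norm statistics with exact dataset averages.

    After a short small-batch run the exponential moving averages are both
    noisy and biased toward the last batches; one shuffled sweep in
    batch-statistics mode (dropout off) re-estimates them as plain means
    of the observed batch moments.
    """
    from .nn.layers import BatchNorm
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    if not bns:
        return
    model.eval()
    for bn in bns:
        bn.training = True
        bn.start_calibration()
    order = rng.permutation(len(planes))
    for start in range(0, len(planes), batch_size):
        model(Tensor(_to_batch(planes[order[start:start + batch_size]])))
    for bn in bns:
        bn.finish_calibration()
        bn.training = False


def train(model: PneumoniaAttentionNet, train_manifest: DatasetManifest,
          cfg: TrainingConfig,
          val_manifest: DatasetManifest | None = None) -> TrainingHistory:
    """Train the model in place; returns the per-epoch history."""
    if len(train_manifest) == 0:
        raise ValueError("training manifest is empty")
    planes, labels = _prepare_arrays(train_manifest, cfg.preprocess)
    targets = one_hot(labels)
    weights_by_class = cfg.class_weights or {c: 1.0 for c in CLASSES}
    sample_weights = np.array([weights_by_class.get(lab, 1.0)
                               for lab in labels], dtype=np.float32)

    n = len(planes)
    steps_per_epoch = -(-n // cfg.batch_size)
    warmup = cfg.warmup_steps if cfg.warmup_steps is not None \
        else steps_per_epoch
    optimizer = Adam(model.parameters(),
                     lr=lambda step: warmup_schedule(step, cfg.peak_lr,
                                                     warmup))
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        started = time.perf_counter()
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        epoch_weight = 0.0
        model.train()
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_planes = planes[idx]
            if cfg.augmentation is not None:
                batch_planes = np.stack([
                    augment(p, cfg.augmentation, aug_rng)
                    for p in batch_planes])
            batch = _to_batch(batch_planes)
            batch_targets = targets[idx]
            batch_weights = sample_weights[idx]
            if batch_weights.sum() <= 0:
                continue  # every sample in this batch has zero weight
            model.zero_grad()
            probs = model(Tensor(batch))
            loss = weighted_cross_entropy(probs, batch_targets, batch_weights)
            loss = loss + model.head.l2_penalty()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}, step {start // cfg.batch_size}")
            loss.backward()
            optimizer.step()
            bw = float(batch_weights.sum())
            epoch_loss += float(loss.data) * bw
            epoch_weight += bw
            epoch_correct += int(
                (probs.data.argmax(axis=1) ==
                 batch_targets.argmax(axis=1)).sum())
        history.loss.append(epoch_loss / max(epoch_weight, 1e-12))
        history.accuracy.append(epoch_correct / n)
        if epoch == cfg.epochs - 1:
            calibrate_batchnorm(model, planes, np.random.default_rng(
                cfg.seed + 2))
        if val_manifest is not None and len(val_manifest) > 0:
            history.val_accuracy.append(
                manifest_accuracy(model, val_manifest, cfg.preprocess))
        history.epoch_seconds.append(time.perf_counter() - started)
    model.eval()
    return history


def train_fresh(model_cfg: ModelConfig, train_manifest: DatasetManifest,
                cfg: TrainingConfig,
                val_manifest: DatasetManifest | None = None
                ) -> tuple[PneumoniaAttentionNet, TrainingHistory]:
    """Build a model seeded consistently with the training config and train."""
    model = PneumoniaAttentionNet(replace(model_cfg, seed=cfg.seed))
    history = train(model, train_manifest, cfg, val_manifest)
    return model, history
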