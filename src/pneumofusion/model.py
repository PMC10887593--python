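"""Classifier head and full dual-backbone model assembly.

The full wiring is

    image -> {branch A backbone, branch B backbone}
          -> per-branch multi-head self-attention
          -> channel-attention feature fusion -> residual block
          -> attention augmentation -> dynamic attention pooling
          -> Dense(128, ReLU, L2) -> BN -> Dropout -> Dense(2, softmax)

Each of the four bespoke components can be replaced by an identity/simple
bypass through :class:`ComponentFlags` for ablation studies; with all four
disabled the model collapses to global-average-pooled, concatenated
backbone features feeding the head directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .attention import AttentionConfig, MapSelfAttention
from .backbones import BackboneSpec, build_backbone
from .fusion import (AttentionAugmentation, DynamicAttentionPooling,
                     FeatureFusion, FusionConfig, ResidualBlock, SimpleFusion,
                     global_avg_pool)
from .nn import BatchNorm, Dense, Dropout, Module, Tensor, concat, softmax


@dataclass(frozen=True)
class HeadConfig:
    hidden_units: int = 128
    l2_coeff: float = 6.72e-3
    dropout: float = 0.2377
    n_classes: int = 2

    def __post_init__(self):
        if self.hidden_units <= 0 or self.n_classes < 2:
            raise ValueError("hidden_units and n_classes must be positive")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class ComponentFlags:
    """Ablation switches; True = component present."""

    feature_fusion: bool = True
    attention_augmentation: bool = True
    dynamic_pooling: bool = True
    multi_head_attention: bool = True

    @classmethod
    def none(cls) -> "ComponentFlags":
        return cls(False, False, False, False)

    def all_disabled(self) -> bool:
        return not (self.feature_fusion or self.attention_augmentation
                    or self.dynamic_pooling or self.multi_head_attention)


class ClassifierHead(Module):
    """Dense(hidden, ReLU, L2) -> BatchNorm -> Dropout -> Dense(n_classes)."""

    def __init__(self, in_features: int, cfg: HeadConfig,
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.hidden = Dense(in_features, cfg.hidden_units, rng)
        self.bn = BatchNorm(cfg.hidden_units)
        self.drop = Dropout(cfg.dropout, dropout_rng or
                            np.random.default_rng(0))
        self.out = Dense(cfg.hidden_units, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Return class logits (softmax applied by the caller)."""
        h = self.drop(self.bn(self.hidden(x).relu()))
        return self.out(h)

    def l2_penalty(self) -> Tensor:
        """L2 kernel penalty of the hidden layer: coeff * sum(W^2)."""
        return (self.hidden.weight ** 2).sum() * self.cfg.l2_coeff


def build_head(cfg: HeadConfig, in_features: int = 256,
               seed: int = 0) -> ClassifierHead:
    return ClassifierHead(in_features, cfg, np.random.default_rng(seed))


@dataclass(frozen=True)
class ModelConfig:
    backbone_a: BackboneSpec = BackboneSpec("tiny_test", stages=5)
    backbone_b: BackboneSpec = BackboneSpec("tiny_test", stages=5)
    attention: AttentionConfig = AttentionConfig()
    fusion: FusionConfig = FusionConfig()
    head: HeadConfig = HeadConfig()
    components: ComponentFlags = ComponentFlags()
    seed: int = 0

    def with_components(self, flags: ComponentFlags) -> "ModelConfig":
        return replace(self, components=flags)


class PneumoniaAttentionNet(Module):
    """The assembled dual-backbone attention-ensemble classifier.

    ``forward`` accepts an NHWC float batch (numpy or Tensor) and returns
    class probabilities; after a forward pass ``self.activations`` maps
    stable layer names to the live tape tensors (inputs to Grad-CAM).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng(
            np.random.default_rng(cfg.seed + 1).integers(0, 2 ** 31))
        try:
            self.backbone_a = build_backbone(cfg.backbone_a, rng)
            self.backbone_b = build_backbone(cfg.backbone_b, rng)
            c_a = self.backbone_a.out_channels
            c_b = self.backbone_b.out_channels
            flags = cfg.components
            if flags.multi_head_attention:
                self.mha_a = MapSelfAttention(c_a, cfg.attention, rng)
                self.mha_b = MapSelfAttention(c_b, cfg.attention, rng)
            if flags.all_disabled():
                head_in = c_a + c_b
            else:
                if flags.feature_fusion:
                    self.fusion = FeatureFusion(c_a, c_b, cfg.fusion, rng,
                                                dropout_rng=drop_rng)
                else:
                    self.fusion = SimpleFusion(c_a, c_b, cfg.fusion, rng)
                fused_channels = cfg.fusion.reshape_target[-1]
                self.residual = ResidualBlock(
                    fused_channels, cfg.fusion.residual_filters, rng)
                if flags.attention_augmentation:
                    self.augment = AttentionAugmentation(
                        cfg.fusion.residual_filters, rng,
                        dropout=cfg.fusion.dropout, dropout_rng=drop_rng)
                if flags.dynamic_pooling:
                    self.pooling = DynamicAttentionPooling(
                        cfg.fusion.residual_filters, rng)
                head_in = cfg.fusion.residual_filters
            self.head = ClassifierHead(head_in, cfg.head, rng,
                                       dropout_rng=drop_rng)
        except ValueError as exc:
            raise ValueError(f"model assembly failed: {exc}") from exc
        self.activations: dict[str, Tensor] = {}

    # ------------------------------------------------------------------
    def forward(self, images) -> Tensor:
        x = images if isinstance(images, Tensor) else \
            Tensor(np.asarray(images, dtype=np.float32))
        if x.ndim != 4:
            raise ValueError("expected an NHWC image batch")
        acts: dict[str, Tensor] = {"input": x}
        f_a = self.backbone_a(x)
        f_b = self.backbone_b(x)
        acts["backbone_a"] = f_a
        acts["backbone_b"] = f_b
        flags = self.cfg.components
        if flags.multi_head_attention:
            f_a = self.mha_a(f_a)
            f_b = self.mha_b(f_b)
            acts["mha_a"] = f_a
            acts["mha_b"] = f_b
        if flags.all_disabled():
            pooled = concat([global_avg_pool(f_a), global_avg_pool(f_b)],
                            axis=-1)
        else:
            fused = self.fusion(f_a, f_b)
            acts.update(self.fusion.activations)
            enhanced = self.residual(fused)
            acts.update(self.residual.activations)
            if flags.attention_augmentation:
                enhanced = self.augment(enhanced)
                acts.update(self.augment.activations)
            if flags.dynamic_pooling:
                pooled = self.pooling(enhanced)
                acts.update(self.pooling.activations)
            else:
                pooled = global_avg_pool(enhanced)
        acts["pooled"] = pooled
        logits = self.head(pooled)
        probs = softmax(logits, axis=-1)
        acts["logits"] = logits
        acts["probs"] = probs
        self.activations = acts
        return probs

    def layer_names(self) -> list[str]:
        return list(self.activations)

    # ------------------------------------------------------------------
    def predict_proba(self, images) -> np.ndarray:
        self.eval()
        return self.forward(images).data

    def save_checkpoint(self, path: Path | str) -> None:
        np.savez(path, **self.state_dict())

    def load_checkpoint(self, path: Path | str) -> None:
        with np.load(path) as archive:
            self.load_state_dict(dict(archive))


def assemble_model(cfg: ModelConfig = ModelConfig()) -> PneumoniaAttentionNet:
    return PneumoniaAttentionNet(cfg)
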