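"""The bespoke feature fusion and enhancement blocks.

Four blocks form the fusion-and-enhancement pipeline between the two
backbone branches and the classifier head:

* channel-attention feature fusion — each branch is gated by a 1x1-conv
  sigmoid channel-attention map, globally average pooled, projected to a
  common 784-unit space (ReLU + dropout), the two vectors are added and
  reshaped row-major to (7, 7, 16);
* residual block — two 3x3 conv + batch-norm + ReLU stages with an
  identity (or 1x1-conv projection) shortcut, 256 filters;
* attention augmentation — a channel-axis gate Dense(ReLU) -> BN ->
  Dropout -> Dense(sigmoid) -> BN -> Dropout applied as a Hadamard
  product, acting per spatial position;
* dynamic attention pooling — a 1x1-conv sigmoid spatial gate multiplies
  the map before global average pooling.

Dropout is active in training mode only.  Every block records its salient
intermediate tensors in ``self.activations`` under stable names so they can
be addressed for Grad-CAM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm, Conv2D, Dense, Dropout, Module, Tensor


@dataclass(frozen=True)
class FusionConfig:
    projection_units: int = 784
    reshape_target: tuple[int, int, int] = (7, 7, 16)
    dropout: float = 0.23
    residual_filters: int = 256

    def __post_init__(self):
        expected = int(np.prod(self.reshape_target))
        if self.projection_units != expected:
            raise ValueError(
                f"projection_units ({self.projection_units}) must equal the "
                f"product of reshape_target ({expected})")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.residual_filters < 1:
            raise ValueError("residual_filters must be >= 1")


def global_avg_pool(fmap: Tensor) -> Tensor:
    """(batch, h, w, c) -> (batch, c) mean over spatial positions."""
    return fmap.mean(axis=(1, 2))


class ChannelAttention(Module):
    """1x1 convolution (channels -> channels) with sigmoid activation."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2D(channels, channels, 1, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        return self.conv(fmap).sigmoid()


def channel_attention(fmap, module: ChannelAttention) -> Tensor:
    fmap = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
    return module(fmap)


class FeatureFusion(Module):
    """Channel-attention fusion of the two backbone branches."""

    def __init__(self, c_eff: int, c_dense: int, cfg: FusionConfig,
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.att_eff = ChannelAttention(c_eff, rng)
        self.att_dense = ChannelAttention(c_dense, rng)
        self.proj_eff = Dense(c_eff, cfg.projection_units, rng)
        self.proj_dense = Dense(c_dense, cfg.projection_units, rng)
        drng = dropout_rng or np.random.default_rng(0)
        self.drop_eff = Dropout(cfg.dropout, drng)
        self.drop_dense = Dropout(cfg.dropout, drng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, f_eff: Tensor, f_dense: Tensor) -> Tensor:
        a_eff = self.att_eff(f_eff)
        a_dense = self.att_dense(f_dense)
        weighted_eff = f_eff * a_eff
        weighted_dense = f_dense * a_dense
        pooled_eff = global_avg_pool(weighted_eff)
        pooled_dense = global_avg_pool(weighted_dense)
        mapped_eff = self.drop_eff(self.proj_eff(pooled_eff).relu())
        mapped_dense = self.drop_dense(self.proj_dense(pooled_dense).relu())
        fused = mapped_eff + mapped_dense
        b = fused.shape[0]
        reshaped = fused.reshape((b,) + self.cfg.reshape_target)
        self.activations = {
            "fusion/att_eff": a_eff,
            "fusion/att_dense": a_dense,
            "fusion/multiply_eff": weighted_eff,
            "fusion/multiply_dense": weighted_dense,
            "fusion/reshaped": reshaped,
        }
        return reshaped


class SimpleFusion(Module):
    """Ablation bypass: dimensionality reduction followed by concatenation.

    Each branch is globally average pooled and linearly reduced to half the
    projection width (ReLU); the two halves are concatenated and reshaped to
    the same target as the full fusion block, so downstream shapes match.
    """

    def __init__(self, c_eff: int, c_dense: int, cfg: FusionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        half = cfg.projection_units // 2
        self.reduce_eff = Dense(c_eff, half, rng)
        self.reduce_dense = Dense(c_dense, cfg.projection_units - half, rng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, f_eff: Tensor, f_dense: Tensor) -> Tensor:
        from .nn import concat
        lo = self.reduce_eff(global_avg_pool(f_eff)).relu()
        hi = self.reduce_dense(global_avg_pool(f_dense)).relu()
        fused = concat([lo, hi], axis=-1)
        b = fused.shape[0]
        reshaped = fused.reshape((b,) + self.cfg.reshape_target)
        self.activations = {"fusion/reshaped": reshaped}
        return reshaped


class ResidualBlock(Module):
    """Two conv-BN-ReLU stages plus a shortcut; spatial dims preserved."""

    def __init__(self, in_channels: int, filters: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2D(in_channels, filters, 3, rng)
        self.bn1 = BatchNorm(filters)
        self.conv2 = Conv2D(filters, filters, 3, rng)
        self.bn2 = BatchNorm(filters)
        self.shortcut = None if in_channels == filters else \
            Conv2D(in_channels, filters, 1, rng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, fmap: Tensor) -> Tensor:
        first = self.bn1(self.conv1(fmap)).relu()
        main = self.bn2(self.conv2(first))
        skip = fmap if self.shortcut is None else self.shortcut(fmap)
        out = (main + skip).relu()
        self.activations = {"post_reshape_conv": first, "residual_out": out}
        return out


class AttentionAugmentation(Module):
    """Channel-axis sigmoid gate applied as a Hadamard product."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 dropout: float = 0.23,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        self.dense1 = Dense(channels, channels, rng)
        self.bn1 = BatchNorm(channels)
        self.dense2 = Dense(channels, channels, rng)
        self.bn2 = BatchNorm(channels)
        drng = dropout_rng or np.random.default_rng(0)
        self.drop1 = Dropout(dropout, drng)
        self.drop2 = Dropout(dropout, drng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, fmap: Tensor) -> Tensor:
        gate = self.drop1(self.bn1(self.dense1(fmap).relu()))
        gate = self.drop2(self.bn2(self.dense2(gate).sigmoid()))
        out = fmap * gate
        self.activations = {"augment/gate": gate, "augment/out": out}
        return out


def attention_augmentation(fmap, module: AttentionAugmentation) -> Tensor:
    fmap = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
    return module(fmap)


class DynamicAttentionPooling(Module):
    """Learned spatial sigmoid gate followed by global average pooling."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.gate_conv = Conv2D(channels, 1, 1, rng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, fmap: Tensor) -> Tensor:
        gate = self.gate_conv(fmap).sigmoid()  # (b, h, w, 1), broadcasts
        weighted = fmap * gate
        pooled = global_avg_pool(weighted)
        self.activations = {"pooling/gate": gate, "pooling/weighted": weighted}
        return pooled


def dynamic_attention_pooling(fmap, module: DynamicAttentionPooling) -> Tensor:
    fmap = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
    return module(fmap)
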