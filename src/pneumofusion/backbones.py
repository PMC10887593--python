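"""Convolutional feature-extraction backbones.

Three backbones are available, all returning the final convolutional
feature map (no global pooling, no classifier head):

* ``tiny_test`` — a small fixed stack of stride-2 3x3 convolutions + ReLU
  (bias-free), meant for CPU tests; ``stages`` stride-2 stages divide the
  spatial side by ``2**stages``; intermediate stages have 8 channels and
  the last stage 16.
* ``efficientnet_b0`` — the standard B0 geometry (stem, 16 MBConv blocks
  with squeeze-excitation and swish, 1x1 head conv): 224x224x3 input gives
  a 7x7x1280 map.  Stochastic depth is omitted (inference-equivalent).
* ``densenet121`` — the standard 121-layer geometry (growth 32, blocks
  6/12/24/16, bottleneck + transition layers): 224x224x3 gives 7x7x1024.

Only randomly initialized weights are supported (``pretrained=False``);
requesting pretrained weights raises, as no weight source ships with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm, Conv2D, DepthwiseConv2D, Module, Tensor,
                 avg_pool2d, concat, max_pool2d)

BACKBONE_NAMES = ("tiny_test", "efficientnet_b0", "densenet121")


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny_test"
    pretrained: bool = False
    seed: int = 0
    # tiny_test only: number of stride-2 stages (3 halves 32->4; 5 maps
    # 224 -> 7, matching the full backbones' spatial geometry).
    stages: int = 3

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES:
            raise ValueError(f"unknown backbone {self.name!r}; "
                             f"choose from {BACKBONE_NAMES}")
        if self.stages < 1:
            raise ValueError("stages must be >= 1")


class TinyTestBackbone(Module):
    """Fixed stride-2 conv stack; bias-free so zero weights give zero maps.

    He-scaled init: without batch norm, Glorot under-scales the activations
    of a ReLU stack and stalls from-scratch training.
    """

    out_channels = 16

    def __init__(self, rng: np.random.Generator, stages: int = 3):
        super().__init__()
        channels = [3] + [8] * (stages - 1) + [16]
        self.convs = []
        for i in range(stages):
            conv = Conv2D(channels[i], channels[i + 1], 3, rng, stride=2,
                          padding="same", use_bias=False)
            fan_in = 9 * channels[i]
            conv.weight.data = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), conv.weight.shape
            ).astype(np.float32)
            self.convs.append(conv)

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        return x

    def output_shape(self, hw: tuple[int, int]) -> tuple[int, int, int]:
        h, w = hw
        for _ in range(len(self.convs)):
            h, w = -(-h // 2), -(-w // 2)
        return h, w, self.out_channels


# ----------------------------------------------------------------------
class _ConvBnAct(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, act="swish"):
        super().__init__()
        self.conv = Conv2D(c_in, c_out, k, rng, stride=stride,
                           padding="same", use_bias=False)
        self.bn = BatchNorm(c_out)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        if self.act == "swish":
            return x.swish()
        if self.act == "relu":
            return x.relu()
        return x


class _SqueezeExcite(Module):
    def __init__(self, channels, reduced, rng):
        super().__init__()
        self.reduce = Conv2D(channels, reduced, 1, rng)
        self.expand = Conv2D(reduced, channels, 1, rng)

    def forward(self, x):
        s = x.mean(axis=(1, 2), keepdims=True)
        s = self.reduce(s).swish()
        s = self.expand(s).sigmoid()
        return x * s


class _MBConv(Module):
    def __init__(self, c_in, c_out, k, stride, expand, rng, se_ratio=0.25):
        super().__init__()
        mid = c_in * expand
        self.expand_conv = _ConvBnAct(c_in, mid, 1, rng) if expand != 1 \
            else None
        self.dw = DepthwiseConv2D(mid, k, rng, stride=stride, padding="same")
        self.dw_bn = BatchNorm(mid)
        self.se = _SqueezeExcite(mid, max(1, int(c_in * se_ratio)), rng)
        self.project = Conv2D(mid, c_out, 1, rng, use_bias=False)
        self.project_bn = BatchNorm(c_out)
        self.use_skip = stride == 1 and c_in == c_out

    def forward(self, x):
        h = self.expand_conv(x) if self.expand_conv is not None else x
        h = self.dw_bn(self.dw(h)).swish()
        h = self.se(h)
        h = self.project_bn(self.project(h))
        return h + x if self.use_skip else h


# (expand, out_channels, repeats, stride, kernel) per B0 stage
_B0_STAGES = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]


class EfficientNetB0(Module):
    out_channels = 1280

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = _ConvBnAct(3, 32, 3, rng, stride=2)
        blocks = []
        c_in = 32
        for expand, c_out, repeats, stride, k in _B0_STAGES:
            for r in range(repeats):
                blocks.append(_MBConv(c_in, c_out, k, stride if r == 0 else 1,
                                      expand, rng))
                c_in = c_out
        self.blocks = blocks
        self.head = _ConvBnAct(c_in, self.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for block in self.blocks:
            x = block(x)
        return self.head(x)

    def output_shape(self, hw):
        h, w = hw
        for _ in range(5):  # stem + four stride-2 stages
            h, w = -(-h // 2), -(-w // 2)
        return h, w, self.out_channels


# ----------------------------------------------------------------------
class _DenseLayer(Module):
    def __init__(self, c_in, growth, rng):
        super().__init__()
        self.bn1 = BatchNorm(c_in)
        self.conv1 = Conv2D(c_in, 4 * growth, 1, rng, use_bias=False)
        self.bn2 = BatchNorm(4 * growth)
        self.conv2 = Conv2D(4 * growth, growth, 3, rng, use_bias=False)

    def forward(self, x):
        h = self.conv1(self.bn1(x).relu())
        h = self.conv2(self.bn2(h).relu())
        return concat([x, h], axis=-1)


class _Transition(Module):
    def __init__(self, c_in, rng):
        super().__init__()
        self.bn = BatchNorm(c_in)
        self.conv = Conv2D(c_in, c_in // 2, 1, rng, use_bias=False)

    def forward(self, x):
        return avg_pool2d(self.conv(self.bn(x).relu()), 2)


class DenseNet121(Module):
    out_channels = 1024

    def __init__(self, rng: np.random.Generator, growth: int = 32,
                 block_layers: tuple[int, ...] = (6, 12, 24, 16)):
        super().__init__()
        self.stem_conv = Conv2D(3, 64, 7, rng, stride=2, padding="same",
                                use_bias=False)
        self.stem_bn = BatchNorm(64)
        layers: list[Module] = []
        c = 64
        for i, n_layers in enumerate(block_layers):
            for _ in range(n_layers):
                layers.append(_DenseLayer(c, growth, rng))
                c += growth
            if i < len(block_layers) - 1:
                layers.append(_Transition(c, rng))
                c //= 2
        self.layers = layers
        self.final_bn = BatchNorm(c)
        assert c == self.out_channels

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_bn(self.stem_conv(x)).relu()
        x = max_pool2d(x, 3, 2, padding="same")
        for layer in self.layers:
            x = layer(x)
        return self.final_bn(x).relu()

    def output_shape(self, hw):
        h, w = hw
        for _ in range(5):  # stem conv, stem pool, three transitions
            h, w = -(-h // 2), -(-w // 2)
        return h, w, self.out_channels


# ----------------------------------------------------------------------
_CONTRACTS_224 = {"efficientnet_b0": (7, 7, 1280), "densenet121": (7, 7, 1024)}


def build_backbone(spec: BackboneSpec,
                   rng: np.random.Generator | None = None) -> Module:
    """Instantiate a backbone; asserts the 224-input geometry contract."""
    if spec.pretrained:
        raise ValueError("pretrained weights are not available in this "
                         "package; build with pretrained=False")
    rng = rng or np.random.default_rng(spec.seed)
    if spec.name == "tiny_test":
        backbone = TinyTestBackbone(rng, stages=spec.stages)
    elif spec.name == "efficientnet_b0":
        backbone = EfficientNetB0(rng)
    else:
        backbone = DenseNet121(rng)
    if spec.name in _CONTRACTS_224:
        got = backbone.output_shape((224, 224))
        expected = _CONTRACTS_224[spec.name]
        if got != expected:
            raise AssertionError(
                f"{spec.name} geometry contract violated: {got} != {expected}")
    return backbone


def extract_features(images: np.ndarray, spec: BackboneSpec) -> Tensor:
    """Run a freshly built backbone over an image batch (NHWC float)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError("extract_features expects a rank-4 NHWC batch")
    backbone = build_backbone(spec)
    backbone.eval()
    out = backbone(Tensor(images))
    if not np.isfinite(out.data).all():
        raise FloatingPointError("backbone produced non-finite activations")
    return out
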