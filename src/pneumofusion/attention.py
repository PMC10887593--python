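"""Scaled-dot-product and multi-head self-attention over CNN feature maps.

A rank-4 feature map (batch, h, w, c) is flattened row-major into h*w
spatial tokens whose embeddings are the channel vectors; multi-head
self-attention with learned per-head query/key/value projections (to
``key_dim``) and an output projection back to the channel count is applied,
and the result is reshaped back to (batch, h, w, c).  No positional
encoding and no residual connection: the attention output replaces the
feature map, so disabling the block is an identity bypass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dense, Module, Tensor, softmax


@dataclass(frozen=True)
class AttentionConfig:
    num_heads: int = 4
    key_dim: int = 128

    def __post_init__(self):
        if self.num_heads < 1 or self.key_dim < 1:
            raise ValueError("num_heads and key_dim must be >= 1")


def scaled_dot_attention(q, k, v, d_k: int | None = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V.

    Accepts 2-D matrices or batched stacks (…, tokens, dim); ``d_k``
    defaults to the number of query/key columns.  Each softmax row sums
    to 1.
    """
    q = q if isinstance(q, Tensor) else Tensor(q)
    k = k if isinstance(k, Tensor) else Tensor(k)
    v = v if isinstance(v, Tensor) else Tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("Q and K must have the same feature dimension")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    d_k = d_k if d_k is not None else q.shape[-1]
    axes = list(range(k.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    scores = (q @ k.transpose(axes)) * (1.0 / np.sqrt(float(d_k)))
    return softmax(scores, axis=-1) @ v


def attention_weights(q: np.ndarray, k: np.ndarray,
                      d_k: int | None = None) -> np.ndarray:
    """The softmax weight matrix alone (for row-stochasticity checks)."""
    d_k = d_k if d_k is not None else q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(float(d_k))
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Multi-head self-attention over a token sequence (B, T, C)."""

    def __init__(self, channels: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.channels = channels
        width = cfg.num_heads * cfg.key_dim
        self.wq = Dense(channels, width, rng)
        self.wk = Dense(channels, width, rng)
        self.wv = Dense(channels, width, rng)
        self.wo = Dense(width, channels, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        b, t, c = tokens.shape
        h, d = self.cfg.num_heads, self.cfg.key_dim

        def split_heads(x: Tensor) -> Tensor:
            return x.reshape(b, t, h, d).transpose((0, 2, 1, 3))

        q = split_heads(self.wq(tokens))
        k = split_heads(self.wk(tokens))
        v = split_heads(self.wv(tokens))
        attended = scaled_dot_attention(q, k, v, d_k=d)  # (b, h, t, d)
        merged = attended.transpose((0, 2, 1, 3)).reshape(b, t, h * d)
        return self.wo(merged)


class MapSelfAttention(Module):
    """Shape-preserving multi-head self-attention on a rank-4 feature map."""

    def __init__(self, channels: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadSelfAttention(channels, cfg, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        if fmap.ndim != 4:
            raise ValueError("expected a rank-4 (batch, h, w, c) feature map")
        b, h, w, c = fmap.shape
        tokens = fmap.reshape(b, h * w, c)
        return self.mha(tokens).reshape(b, h, w, c)


def apply_mha_to_map(fmap, module: MapSelfAttention) -> Tensor:
    """Functional wrapper: run a built MapSelfAttention over a feature map."""
    fmap = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
    return module(fmap)
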