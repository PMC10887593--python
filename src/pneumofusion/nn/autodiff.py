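"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node that
remembers its parents and a closure computing the local vector-Jacobian
product.  ``Tensor.backward`` runs the tape in reverse topological order.
All arrays are float32, NHWC layout for images.  Gradients are retained on
every node of the tape (not only leaves), which is what Grad-CAM needs to
read the gradient at an arbitrary internal activation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "avg_pool2d",
    "max_pool2d",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._vjp = vjp
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every tape ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires "
                                 "a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, pgrad in node._vjp(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(np.float32, copy=True)
                else:
                    parent.grad = parent.grad + pgrad

    # ------------------------------------------------------------------
    # elementwise arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def vjp(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor(out_data, parents=(self, other), vjp=vjp)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def vjp(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor(out_data, parents=(self, other), vjp=vjp)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def vjp(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))

        return Tensor(out_data, parents=(self, other), vjp=vjp)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def vjp(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def vjp(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward needs >=2-D inputs")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))

        return Tensor(out_data, parents=(self, other), vjp=vjp)

    # ------------------------------------------------------------------
    # nonlinearities
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def vjp(g):
            return ((self, g * mask),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def vjp(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def swish(self):
        """x * sigmoid(x) (SiLU)."""
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def vjp(g):
            return ((self, g * (sig + self.data * sig * (1.0 - sig))),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def exp(self):
        out_data = np.exp(self.data)

        def vjp(g):
            return ((self, g * out_data),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def log(self, eps: float = 0.0):
        out_data = np.log(self.data + eps)

        def vjp(g):
            return ((self, g / (self.data + eps)),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def vjp(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def vjp(g):
            return ((self, g.reshape(in_shape)),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def vjp(g):
            return ((self, g.transpose(inv)),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    # ------------------------------------------------------------------
    # reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def vjp(g):
            if axis is None:
                return ((self, np.broadcast_to(g, in_shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            gg = g
            if not keepdims:
                for a in sorted(a % len(in_shape) for a in ax):
                    gg = np.expand_dims(gg, a)
            return ((self, np.broadcast_to(gg, in_shape).copy()),)

        return Tensor(out_data, parents=(self,), vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)


def _as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# ----------------------------------------------------------------------
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with an analytic backward pass."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((x, out_data * (g - dot)),)

    return Tensor(out_data, parents=(x,), vjp=vjp)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        pieces = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            pieces.append((t, g[tuple(index)]))
        return tuple(pieces)

    return Tensor(out_data, parents=tuple(tensors), vjp=vjp)


# ----------------------------------------------------------------------
# convolution machinery (NHWC)

def _pad_amount(size: int, k: int, stride: int) -> tuple[int, int]:
    """'same' padding amounts matching the usual conv convention."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _resolve_padding(h, w, kh, kw, stride, padding):
    if padding == "same":
        pt, pb = _pad_amount(h, kh, stride)
        pl, pr = _pad_amount(w, kw, stride)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    return pt, pb, pl, pr


def _window_view(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (N, oh, ow, kh, kw, C) over an already-padded NHWC array."""
    n, h, w, c = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, kh, kw, c),
        (s0, s1 * stride, s2 * stride, s1, s2, s3))


def _scatter_windows(dwin: np.ndarray, padded_shape, stride: int) -> np.ndarray:
    """Adjoint of _window_view: scatter-add window gradients back."""
    n, oh, ow, kh, kw, c = dwin.shape
    dx = np.zeros(padded_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dx[:, i:i + oh * stride:stride, j:j + ow * stride:stride, :] += \
                dwin[:, :, :, i, j, :]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: str = "same") -> Tensor:
    """2-D convolution, NHWC input, weight (kh, kw, c_in, c_out)."""
    kh, kw, c_in, c_out = weight.shape
    n, h, w, c = x.shape
    if c != c_in:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {c_in}")
    pt, pb, pl, pr = _resolve_padding(h, w, kh, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = _window_view(xp, kh, kw, stride)
    n_, oh, ow = win.shape[:3]
    cols = win.reshape(n * oh * ow, kh * kw * c_in)
    wmat = weight.data.reshape(kh * kw * c_in, c_out)
    out = cols @ wmat
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(n, oh, ow, c_out)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def vjp(g):
        gf = g.reshape(n * oh * ow, c_out)
        grads = []
        if x.requires_grad:
            dcols = gf @ wmat.T
            dwin = dcols.reshape(n, oh, ow, kh, kw, c_in)
            dxp = _scatter_windows(dwin, xp.shape, stride)
            grads.append((x, dxp[:, pt:pt + h, pl:pl + w, :]))
        if weight.requires_grad:
            dw = cols.T @ gf
            grads.append((weight, dw.reshape(kh, kw, c_in, c_out)))
        if bias is not None and bias.requires_grad:
            grads.append((bias, gf.sum(axis=0)))
        return tuple(grads)

    return Tensor(out_data, parents=parents, vjp=vjp)


def depthwise_conv2d(x: Tensor, weight: Tensor, stride: int = 1,
                     padding: str = "same") -> Tensor:
    """Depthwise convolution; weight (kh, kw, c), one filter per channel."""
    kh, kw, c_w = weight.shape
    n, h, w, c = x.shape
    if c != c_w:
        raise ValueError("depthwise_conv2d: channel mismatch")
    pt, pb, pl, pr = _resolve_padding(h, w, kh, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = _window_view(xp, kh, kw, stride)
    out_data = np.einsum("nxyijc,ijc->nxyc", win, weight.data,
                         optimize=True).astype(np.float32)

    def vjp(g):
        grads = []
        if x.requires_grad:
            dwin = g[:, :, :, None, None, :] * weight.data[None, None, None]
            dxp = _scatter_windows(dwin, xp.shape, stride)
            grads.append((x, dxp[:, pt:pt + h, pl:pl + w, :]))
        if weight.requires_grad:
            dw = np.einsum("nxyijc,nxyc->ijc", win, g, optimize=True)
            grads.append((weight, dw))
        return tuple(grads)

    return Tensor(out_data, parents=(x, weight), vjp=vjp)


def avg_pool2d(x: Tensor, pool: int = 2, stride: int | None = None) -> Tensor:
    stride = stride or pool
    n, h, w, c = x.shape
    win = _window_view(x.data, pool, pool, stride)
    out_data = win.mean(axis=(3, 4))

    def vjp(g):
        dwin = np.broadcast_to(
            g[:, :, :, None, None, :] / (pool * pool),
            g.shape[:3] + (pool, pool, c)).astype(np.float32)
        return ((x, _scatter_windows(dwin, x.data.shape, stride)),)

    return Tensor(out_data, parents=(x,), vjp=vjp)


def max_pool2d(x: Tensor, pool: int = 3, stride: int = 2,
               padding: str = "same") -> Tensor:
    n, h, w, c = x.shape
    pt, pb, pl, pr = _resolve_padding(h, w, pool, pool, stride, padding)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                constant_values=-np.inf)
    win = _window_view(xp, pool, pool, stride)
    n_, oh, ow = win.shape[:3]
    flat = win.reshape(n, oh, ow, pool * pool, c)
    idx = flat.argmax(axis=3)
    out_data = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[
        :, :, :, 0, :]

    def vjp(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, :, :, None, :],
                          g[:, :, :, None, :], axis=3)
        dwin = dflat.reshape(n, oh, ow, pool, pool, c)
        dxp = _scatter_windows(dwin, xp.shape, stride)
        return ((x, dxp[:, pt:pt + h, pl:pl + w, :]),)

    return Tensor(out_data, parents=(x,), vjp=vjp)
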