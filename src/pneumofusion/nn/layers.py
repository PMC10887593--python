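"""Neural-network modules built on the autodiff tape.

Conventions follow the common NHWC deep-learning stack: Glorot-uniform
weight init, batch norm with momentum 0.99 / eps 1e-3, inverted dropout.
Every module draws its initial weights from an explicit
``numpy.random.Generator`` so a single integer seed makes the whole model
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, depthwise_conv2d


class Parameter(Tensor):
    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = False

    # -- traversal ------------------------------------------------------
    def _children(self):
        for key, value in vars(self).items():
            if isinstance(value, Module):
                yield key, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{key}.{i}", item

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for key, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{key}", value
        for key, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{key}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- persistence ----------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for key, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{key}", value
        for key, child in self._children():
            yield from child._named_buffers(prefix=f"{prefix}{key}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, array in state.items():
            if name.startswith("buffer:"):
                target = buffers[name[len("buffer:"):]]
                np.copyto(target, array)
            else:
                params[name].data = np.asarray(array, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, use_bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot_uniform(
            rng, (in_features, out_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if use_bias \
            else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2D(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: str = "same", use_bias: bool = True):
        super().__init__()
        k = kernel_size
        fan_in = k * k * in_channels
        fan_out = k * k * out_channels
        self.weight = Parameter(glorot_uniform(
            rng, (k, k, in_channels, out_channels), fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if use_bias \
            else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class DepthwiseConv2D(Module):
    def __init__(self, channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: str = "same"):
        super().__init__()
        k = kernel_size
        self.weight = Parameter(glorot_uniform(
            rng, (k, k, channels), k * k, k * k))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, stride=self.stride,
                                padding=self.padding)


class BatchNorm(Module):
    """Batch normalization over all axes but the last (channel) axis.

    Training mode normalizes with batch statistics (differentiable, via the
    tape) and updates the moving averages; eval mode uses the stored moving
    statistics as constants.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.moving_mean = np.zeros(channels, np.float32)
        self.moving_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps

    def set_identity(self) -> None:
        """Freeze to the identity map (unit scale, zero shift, unit moments)."""
        self.gamma.data = np.ones_like(self.gamma.data)
        self.beta.data = np.zeros_like(self.beta.data)
        self.moving_mean[:] = 0.0
        self.moving_var[:] = 1.0 - self.eps

    # -- statistics re-estimation --------------------------------------
    # EMA moving statistics are poor after short small-batch runs; a
    # calibration pass replaces them with exact averages of the batch
    # statistics observed over a dataset sweep.
    def start_calibration(self) -> None:
        self._calib = [np.zeros_like(self.moving_mean),
                       np.zeros_like(self.moving_var), 0]

    def finish_calibration(self) -> None:
        mean_sum, var_sum, count = self._calib
        if count > 0:
            self.moving_mean[:] = mean_sum / count
            self.moving_var[:] = var_sum / count
        self._calib = None

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            norm = (x - mu) / ((var + self.eps) ** 0.5)
            calib = getattr(self, "_calib", None)
            if calib is not None:
                calib[0] += mu.data.reshape(-1)
                calib[1] += var.data.reshape(-1)
                calib[2] += 1
            else:
                m = self.momentum
                self.moving_mean[:] = m * self.moving_mean + \
                    (1 - m) * mu.data.reshape(-1)
                self.moving_var[:] = m * self.moving_var + \
                    (1 - m) * var.data.reshape(-1)
        else:
            norm = (x - self.moving_mean) * \
                (1.0 / np.sqrt(self.moving_var + self.eps))
        return norm * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded per-layer."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.stages = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for stage in self.stages:
            x = stage(x)
        return x
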