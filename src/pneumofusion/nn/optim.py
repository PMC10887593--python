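"""Optimizers for the autodiff core (currently Adam, the only one used)."""

from __future__ import annotations

from typing import Callable

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with an optional per-step learning-rate schedule.

    ``lr`` may be a float or a callable ``step -> lr`` (used for the warmup
    schedule); ``step`` counts completed updates starting at 0.
    """

    def __init__(self, params: list[Parameter],
                 lr: float | Callable[[int], float] = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_count = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        return self.lr(self.step_count) if callable(self.lr) else self.lr

    def step(self) -> None:
        lr = self.current_lr()
        t = self.step_count + 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** t)
            vhat = self._v[i] / (1 - b2 ** t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
        self.step_count = t
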