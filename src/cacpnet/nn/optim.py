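"""Stochastic gradient descent with classical momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["SGD"]


class SGD:
    """v <- mu*v + (g + wd*w);  w <- w - lr*v  (torch-style coupled decay)."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
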