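"""Optimisers: adaptive-moment estimation (Adam) with exponential LR decay."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "ExponentialLR"]


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of parameter tensors.

    Defaults match the training protocol used throughout this package:
    lr 1e-4, betas (0.9, 0.999).
    """

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class ExponentialLR:
    """lr(epoch) = lr0 * rate**epoch; call :meth:`step` once per epoch."""

    def __init__(self, optimizer: Adam, rate: float = 0.96):
        if not 0 < rate <= 1:
            raise ValueError("decay rate must be in (0, 1]")
        self.optimizer = optimizer
        self.rate = rate
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self):
        self.epoch += 1
        self.optimizer.lr = self.base_lr * self.rate ** self.epoch

    @property
    def lr(self):
        return self.optimizer.lr
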