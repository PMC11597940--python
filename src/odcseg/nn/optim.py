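"""Optimisers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with bias correction.

    Defaults mirror the training recipe of the segmentation framework:
    the caller supplies the learning rate (1e-4 for the segmenter, 1e-2
    for the domain discriminators) and betas (0.9, 0.99).
    """

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.99),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - self.lr * update).astype(DTYPE)


class StepLR:
    """Multiply the optimiser learning rate by ``gamma`` every ``step_size`` calls."""

    def __init__(self, optimizer: Adam, step_size: int = 1, gamma: float = 0.95):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self._count = 0

    def step(self) -> None:
        self._count += 1
        if self._count % self.step_size == 0:
            self.optimizer.lr *= self.gamma
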