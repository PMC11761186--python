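"""Adam optimizer and stepwise learning-rate decay."""
from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with bias correction (Kingma & Ba defaults for betas/eps)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class StepDecay:
    """Multiply the learning rate by ``factor`` every ``step_epochs`` epochs."""

    def __init__(self, optimizer: Adam, step_epochs: int = 7, factor: float = 0.1) -> None:
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.step_epochs = int(step_epochs)
        self.factor = float(factor)

    def at_epoch(self, epoch: int) -> float:
        """Set and return the learning rate for 0-based ``epoch``."""
        lr = self.base_lr * self.factor ** (epoch // self.step_epochs)
        self.opt.lr = lr
        return lr
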