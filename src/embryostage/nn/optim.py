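"""Adam optimizer and step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                # decoupled decay, applied to weight tensors only
                if p.data.ndim > 1:
                    p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs.

    ``lr(epoch) = base_lr * gamma ** (epoch // step_size)`` with epochs
    counted from 0; call :meth:`at_epoch` at the start of each epoch.
    """

    def __init__(self, optimizer: Adam, step_size: int = 10, gamma: float = 0.5):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.step_size = int(step_size)
        self.gamma = float(gamma)

    def lr_for_epoch(self, epoch: int) -> float:
        return self.base_lr * self.gamma ** (epoch // self.step_size)

    def at_epoch(self, epoch: int) -> float:
        self.opt.lr = self.lr_for_epoch(epoch)
        return self.opt.lr
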