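"""Optimizers and learning-rate schedules for the numpy network stack."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Adam:
    """Adam with bias correction; ``beta1`` is the momentum-style coefficient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def poly_decay(lr_init: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """Polynomially decaying learning rate: lr0 * (1 - step/total)^power."""
    if total_steps <= 0:
        return lr_init
    frac = min(max(step / total_steps, 0.0), 1.0)
    return lr_init * (1.0 - frac) ** power
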