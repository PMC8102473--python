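"""Adam optimizer (Kingma & Ba) with the standard default hyperparameters."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / (1.0 - b1**self.t)
            vhat = v / (1.0 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
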