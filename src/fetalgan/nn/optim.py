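"""Adam optimizer for the numpy network layers."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments.

    ``maximize=True`` performs gradient ascent on the same accumulated
    gradients — used for the critic, which maximizes the multi-scale
    adversarial loss while the generator minimizes it.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8, maximize: bool = False):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.maximize = maximize
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = -p.grad if self.maximize else p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
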