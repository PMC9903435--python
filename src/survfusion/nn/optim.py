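"""Adam optimizer with an optional L2 penalty.

The L2 term matches the loss definition ``loss + l2_weight * ||theta||^2``:
its gradient ``2 * l2_weight * theta`` is added to each parameter gradient
before the Adam update (it is part of the objective, not decoupled decay).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        l2_weight: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.l2_weight = l2_weight
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2_weight:
                g = g + 2.0 * self.l2_weight * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
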