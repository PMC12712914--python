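"""Adam / AdamW with mutable learning rate (for poly or linear schedules)."""

from __future__ import annotations

import numpy as np

from .ops import Param


class Adam:
    """Adam; set ``decoupled_wd > 0`` for AdamW-style decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, decoupled_wd: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = decoupled_wd
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            if self.wd:
                p.value -= self.lr * self.wd * p.value
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
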