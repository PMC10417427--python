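"""Optimisation utilities: Adam and cosine-annealed learning rate."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_lr"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def cosine_lr(epoch: int, total_epochs: int, base_lr: float,
              min_lr: float = 0.0) -> float:
    """Cosine annealing from ``base_lr`` (epoch 0) towards ``min_lr``."""
    if total_epochs <= 1:
        return base_lr
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + np.cos(np.pi * epoch / total_epochs))
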