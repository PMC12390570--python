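"""SGD with momentum, weight decay, warmup schedule and gradient clipping."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``.

    Returns the *pre-clip* global norm.
    """
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float(np.sum(p.grad.astype(np.float64) ** 2))
    total = float(np.sqrt(sq))
    if total > max_norm and total > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class SGD:
    """Momentum SGD matching the usual deep-learning convention:

    ``v = momentum * v + grad + weight_decay * w``; ``w -= lr * v``.
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def warmup_lr(base_lr: float, iteration: int, warmup_iters: int) -> float:
    """Linear warmup from base_lr/warmup_iters up to base_lr."""
    if warmup_iters <= 0 or iteration >= warmup_iters:
        return base_lr
    return base_lr * (iteration + 1) / warmup_iters
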