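"""Differentiable loss/activation helpers shared across the networks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, where_mask


def bce_with_logits(logits: Tensor, targets, reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on logits.

    Uses ``max(x,0) - x*t + log(1 + exp(-|x|))``.
    """
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=logits.dtype)
    pos = where_mask(logits.data > 0, logits, as_tensor(np.zeros_like(logits.data)))
    loss = pos - logits * t + (1.0 + (-logits.abs()).exp()).log()
    if reduction == "mean":
        return loss.mean()
    if reduction == "sum":
        return loss.sum()
    return loss


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray, axis: int = 1) -> Tensor:
    """Mean CE over all positions; ``labels`` are integer class indices."""
    logp = log_softmax(logits, axis=axis)
    labels = np.asarray(labels)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    np.put_along_axis(onehot, np.expand_dims(labels, axis), 1.0, axis=axis)
    picked = (logp * onehot).sum(axis=axis)
    return -picked.mean()
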