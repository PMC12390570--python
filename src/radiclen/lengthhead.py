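"""Radicle length prediction: RoIAlign, attention blending, masks, regression.

Per kept instance, stride-8 pixel features (or optionally the basis tensor B)
are RoI-aligned to an R x R crop f_i, blended multiplicatively with the
instance's upsampled M x M attention map (f_i' = f_i ⊙ A_i), projected by a
1x1 conv into instance-mask logits, and fed to a small regressor:
two 3x3 conv+BN+ReLU blocks, global average pooling to a 64-dim vector per
instance, then FC(64->64, ReLU) and FC(64->1).  The per-image output is a
64-slot length vector filled in detection-score order; slots beyond the
number of instances are exactly zero (a dish holds fewer than 64 seedlings).
Lengths are regressed in network-input pixels and converted to mm with the
per-image grid pitch.
"""

from __future__ import annotations

import logging

import numpy as np

from .conf import ModelConfig
from .nnet import (BatchNorm2d, Conv2d, Linear, Module, Tensor,
                   bilinear_resize, roi_align, stack)

logger = logging.getLogger(__name__)


def roi_crop(feature: Tensor, boxes: np.ndarray, r: int,
             stride: float, image_size: tuple | None = None):
    """RoI-aligned crops; degenerate boxes are dropped with a log entry.

    Returns (crops (K,C,R,R) Tensor, kept_indices).
    """
    if r < 2:
        raise ValueError("RoI output size must be >= 2")
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    if image_size is not None:
        h, w = image_size
        boxes = boxes.copy()
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    kept = np.nonzero(areas > 0)[0]
    if len(kept) < len(boxes):
        for i in np.nonzero(areas <= 0)[0]:
            logger.warning("dropping degenerate box %s", boxes[i])
    if len(kept) == 0:
        raise ValueError("all boxes degenerate after clipping")
    crops = roi_align(feature, boxes[kept], out_size=r, stride=stride)
    return crops, kept


def blend(fi: Tensor, ai) -> Tensor:
    """f_i' = f_i ⊙ A_i with A_i bilinearly upsampled to the crop size.

    ``fi`` is (K,C,R,R) or (C,R,R); ``ai`` is matching (K,M,M) / (M,M)
    (Tensor or array).  The attention is broadcast over channels.
    """
    from .nnet import as_tensor

    ai = as_tensor(ai)
    single = fi.ndim == 3
    if single:
        fi = fi.reshape(1, *fi.shape)
        ai = ai.reshape(1, *ai.shape)
    r = fi.shape[-1]
    if ai.shape[-1] != r or ai.shape[-2] != fi.shape[-2]:
        ai = bilinear_resize(ai, fi.shape[-2], r)
    k = fi.shape[0]
    out = fi * ai.reshape(k, 1, fi.shape[-2], r)
    return out.reshape(*out.shape[1:]) if single else out


class LengthHead(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        ch = cfg.k if cfg.basis_source == "B" else cfg.fpn_channels
        self.in_channels = ch
        # the softmax attention sums to 1 over M*M cells, so blended
        # features carry a 1/M^2 mean factor; this fixed gain restores
        # unit scale at the head inputs
        self.input_gain = float(cfg.attention_size ** 2)
        self.mask_proj = Conv2d(rng, ch, 1, 1)
        self.conv1 = Conv2d(rng, ch, 128, 3, bias=False)
        self.bn1 = BatchNorm2d(128)
        self.conv2 = Conv2d(rng, 128, 64, 3, bias=False)
        self.bn2 = BatchNorm2d(64)
        self.fc1 = Linear(rng, 64, 64)
        self.fc2 = Linear(rng, 64, 1)

    # -- blending and masks -------------------------------------------------
    def blend_crops(self, crops: Tensor, attentions) -> Tensor:
        if isinstance(attentions, (list, tuple)):
            attentions = stack(list(attentions), axis=0)
        return blend(crops, attentions)

    def mask_logits(self, blended: Tensor) -> Tensor:
        """(K,C,R,R) blended features -> (K,1,R,R) instance-mask logits."""
        return self.mask_proj(blended * self.input_gain)

    # -- regression ---------------------------------------------------------
    def regress(self, blended: Tensor) -> Tensor:
        """(K,C,R,R) -> (K,) predicted lengths in network-input pixels."""
        x = self.bn1(self.conv1(blended * self.input_gain)).relu()
        x = self.bn2(self.conv2(x)).relu()
        pooled = x.mean(axis=(2, 3))  # (K, 64): GAP condenses the crop
        h = self.fc1(pooled).relu()
        return self.fc2(h).reshape(pooled.shape[0])

    def length_vector(self, lengths: np.ndarray,
                      scores: np.ndarray | None = None) -> np.ndarray:
        """64-slot vector in score order; zeros beyond the live count."""
        n_slots = self.cfg.max_instances
        lengths = np.asarray(lengths, dtype=float).ravel()
        if scores is not None:
            order = np.argsort(-np.asarray(scores), kind="stable")
            lengths = lengths[order]
        if len(lengths) > n_slots:
            logger.warning(
                "dropping %d instances beyond the %d length slots",
                len(lengths) - n_slots, n_slots)
            lengths = lengths[:n_slots]
        out = np.zeros(n_slots)
        out[: len(lengths)] = lengths
        return out


def predict_instance_mask(mask_logits: np.ndarray, box, image_size,
                          threshold: float = 0.5) -> np.ndarray:
    """Sigmoid, resize into the box, threshold, paste at image resolution.

    Pixels outside the (clipped) box are background by construction.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0,1)")
    h, w = image_size
    x1 = int(np.floor(max(box[0], 0)))
    y1 = int(np.floor(max(box[1], 0)))
    x2 = int(np.ceil(min(box[2], w)))
    y2 = int(np.ceil(min(box[3], h)))
    out = np.zeros((h, w), dtype=bool)
    if x2 <= x1 or y2 <= y1:
        return out
    logits = np.asarray(mask_logits, dtype=float).reshape(
        mask_logits.shape[-2], mask_logits.shape[-1])
    prob = 1.0 / (1.0 + np.exp(-logits))
    resized = bilinear_resize(Tensor(prob), y2 - y1, x2 - x1).numpy()
    out[y1:y2, x1:x2] = resized >= threshold
    return out
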