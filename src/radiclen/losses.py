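"""Training losses: the two-stage composite objectives.

Stage 1 jointly supervises the two feature extractors:
``L_S1 = lambda1 * L_pixel + lambda2 * L_instance``, where the pixel part is
a per-level BCE of projected foreground logits against the downsampled union
foreground mask plus a semantic cross-entropy at stride 4, and the instance
part is focal objectness + (1 - IoU) box loss + centerness BCE.  The blended
per-instance mask logits are supervised with BCE against ground-truth mask
crops as part of the pixel mask supervision.

Stage 2 trains only the length regressor with a hybrid L2/L1 loss: quadratic
``e^2/(2*beta)`` for residuals below ``beta`` and linear ``|e| - beta/2``
beyond it (continuous and once-differentiable at the knee).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .nnet import Tensor, as_tensor, where_mask
from .instnet import box_iou_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossConfig:
    """Loss weights and optimization hyperparameters (full-scale defaults)."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    gamma: float = 2.0  # focal focusing parameter
    beta: float = 1.0  # hybrid-loss knee (stage 2)
    lr_stage1: float = 5e-3
    lr_stage2: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 1e-4
    iterations_stage1: int = 10_000
    iterations_stage2: int = 2_000
    warmup_iterations: int = 1_000
    grad_clip_norm: float = 1.0
    batch_size: int = 4
    input_sizes: tuple = (640, 800)  # multi-scale shorter sides
    hflip: bool = True

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "beta", "lr_stage1", "lr_stage2"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")

    @staticmethod
    def tiny(**overrides) -> "LossConfig":
        """Desk-scale schedule: short runs, fixed small input, flip only."""
        base = dict(
            lr_stage1=2e-2, lr_stage2=1e-2,
            iterations_stage1=450, iterations_stage2=1200,
            warmup_iterations=50, input_sizes=(192,),
        )
        base.update(overrides)
        return LossConfig(**base)


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def stage2_loss(lengths, predictions, beta: float = 1.0) -> Tensor:
    """Hybrid L2/L1 regression loss, mean over the live slots of a batch."""
    lengths = as_tensor(lengths)
    predictions = as_tensor(predictions)
    if lengths.data.size == 0:
        warnings.warn("stage2_loss on an empty batch; returning 0")
        return as_tensor(0.0)
    e = lengths - predictions
    quad = e * e / (2.0 * beta)
    lin = e.abs() - beta / 2.0
    return where_mask(np.abs(e.data) < beta, quad, lin).mean()


def focal_loss(p_true, gamma: float = 2.0, npos: int | None = None) -> Tensor:
    """Focal objectness loss ``-(1/npos) * sum (1-p)^gamma * log(p)``.

    ``p_true`` holds, for each sample in the evaluated set, the probability
    the model assigned to that sample's correct label; at ``gamma = 0`` the
    loss reduces to cross-entropy normalized by ``npos`` (the positive
    count, defaulting to the sample count).
    """
    p = as_tensor(p_true)
    if p.data.size == 0 or (npos is not None and npos == 0):
        warnings.warn("focal_loss with no positive samples; returning 0")
        return as_tensor(0.0)
    n = float(p.data.size if npos is None else npos)
    p = p.clip(1e-12, 1.0)
    term = (1.0 - p) ** gamma * p.log()
    return -term.sum() / n


def iou_box_loss(pred_boxes, gt_boxes) -> float:
    """Mean ``1 - IoU`` over paired xyxy boxes; degenerate GT are excluded."""
    pred = np.asarray(pred_boxes, dtype=float).reshape(-1, 4)
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    ok = (gt[:, 2] > gt[:, 0]) & (gt[:, 3] > gt[:, 1])
    if not ok.all():
        logger.warning("excluding %d degenerate GT boxes", int((~ok).sum()))
    pred, gt = pred[ok], gt[ok]
    if len(gt) == 0:
        return 0.0
    iou = np.diag(box_iou_matrix(pred, gt))
    return float(np.mean(1.0 - iou))


def centerness_target(location, box) -> float:
    """FCOS centerness: 1 at the box center, 0 on edges and outside."""
    x, y = location
    x1, y1, x2, y2 = box
    l, t, r, b = x - x1, y - y1, x2 - x, y2 - y
    if min(l, t, r, b) < 0:
        return 0.0
    num = min(l, r) * min(t, b)
    den = max(l, r) * max(t, b)
    if den == 0:
        return 0.0
    return float(np.sqrt(num / den))


def iou_loss_ltrb(pred: Tensor, target: np.ndarray,
                  weights: np.ndarray | None = None) -> Tensor:
    """Differentiable ``1 - IoU`` from (N,4) ltrb edge distances."""
    target = np.asarray(target, dtype=pred.dtype)
    tl, tt, tr, tb = target[:, 0], target[:, 1], target[:, 2], target[:, 3]
    pl, pt, pr, pb = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    # elementwise minimum via constant-mask select
    iw = where_mask(pl.data < tl, pl, as_tensor(tl)) + \
        where_mask(pr.data < tr, pr, as_tensor(tr))
    ih = where_mask(pt.data < tt, pt, as_tensor(tt)) + \
        where_mask(pb.data < tb, pb, as_tensor(tb))
    inter = iw.clip(0.0, np.inf) * ih.clip(0.0, np.inf)
    area_p = (pl + pr) * (pt + pb)
    area_t = (tl + tr) * (tt + tb)
    union = area_p + as_tensor(area_t) - inter
    iou = inter / (union + 1e-9)
    loss = 1.0 - iou
    if weights is not None:
        wsum = float(np.sum(weights)) + 1e-9
        return (loss * as_tensor(weights.astype(pred.dtype))).sum() / wsum
    return loss.mean()


def stage1_loss(pixel_components: dict, instance_components: dict,
                cfg: LossConfig) -> Tensor:
    """``lambda1 * sum(pixel) + lambda2 * sum(instance)`` with NaN guard."""
    def total(components: dict) -> Tensor:
        acc = as_tensor(0.0)
        for name, value in components.items():
            value = as_tensor(value)
            if not np.isfinite(value.data).all():
                raise FloatingPointError(
                    f"loss component {name!r} is not finite"
                )
            acc = acc + value
        return acc

    return (cfg.lambda1 * total(pixel_components)
            + cfg.lambda2 * total(instance_components))
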