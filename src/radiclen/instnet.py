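"""Instance-level feature extraction: dense anchor-free heads and attention.

A single head, shared across the five pyramid levels F3-F7, predicts at every
location an objectness score, a centerness score, box offsets (l, t, r, b)
to the four edges, and attention logits with M*M output channels.  Boxes are
the anchor-free five-tuple (location; l, t, r, b).  At inference the dense
predictions are reduced to instances by per-level top-d filtering followed by
class-agnostic greedy NMS ranked by score x centerness; each kept instance
carries the softmax-normalized M x M attention map read at its location.
During training, ground-truth boxes are assigned to levels by the usual
regression-range scheme with center sampling and attention maps are read at
the GT-assigned locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conf import STRIDES, ModelConfig
from .nnet import Conv2d, Module, Tensor, parameter
from .nnet.functional import softmax

logger = logging.getLogger(__name__)

LEVELS = (3, 4, 5, 6, 7)


def level_locations(h: int, w: int, stride: int) -> np.ndarray:
    """Image-plane points of grid cells: cell (i,j) -> ((j+.5)s, (i+.5)s)."""
    xs = (np.arange(w) + 0.5) * stride
    ys = (np.arange(h) + 0.5) * stride
    xx, yy = np.meshgrid(xs, ys)
    return np.stack([xx, yy], axis=-1)  # (H, W, 2)


def decode_boxes(locations: np.ndarray, ltrb: np.ndarray) -> np.ndarray:
    """(π; l,t,r,b) -> [x1,y1,x2,y2]; shapes (...,2) and (...,4)."""
    x, y = locations[..., 0], locations[..., 1]
    l, t, r, b = np.moveaxis(ltrb, -1, 0)
    return np.stack([x - l, y - t, x + r, y + b], axis=-1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) vs (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy score-descending NMS; ties broken by lower candidate index."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    iou = box_iou_matrix(boxes, boxes)
    keep = []
    suppressed = np.zeros(len(order), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        suppressed |= iou[idx] > iou_threshold
        suppressed[idx] = True
    return np.array(keep, dtype=int)


class DenseHead(Module):
    """FCOS-style head shared by all five pyramid levels."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        ch = cfg.fpn_channels
        m2 = cfg.attention_size ** 2
        from .nnet import Sequential

        def tower():
            mods = []
            for _ in range(cfg.head_convs):
                mods.append(Conv2d(rng, ch, ch, 3))
            return Sequential(*mods)

        self.cls_tower = tower()
        self.box_tower = tower()
        self.cls_out = Conv2d(rng, ch, 1, 3)
        self.ctr_out = Conv2d(rng, ch, 1, 3)
        self.reg_out = Conv2d(rng, ch, 4, 3)
        self.att_out = Conv2d(rng, ch, m2, 3)
        # objectness bias starts low (foreground prior ~0.05)
        self.cls_out.bias.data[:] = -3.0

    def _run_tower(self, tower, x):
        for m in tower._seq:
            x = m(x).relu()
        return x

    def forward(self, feat: Tensor) -> dict:
        ct = self._run_tower(self.cls_tower, feat)
        bt = self._run_tower(self.box_tower, feat)
        return {
            "cls": self.cls_out(ct),
            "ctr": self.ctr_out(bt),
            "reg": self.reg_out(bt),
            "att": self.att_out(bt),
        }


class InstNet(Module):
    """Shared dense head over F3..F7 plus per-level regression scales."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.head = DenseHead(rng, cfg)
        for i, _s in zip(LEVELS, STRIDES):
            p = parameter(rng, (1,), zero=True)
            p.data[:] = 1.0
            setattr(self, f"scale{i}", p)

    def forward(self, feats: dict) -> dict:
        """Run the shared head on every level; returns per-level raw maps."""
        out = {}
        for i, stride in zip(LEVELS, STRIDES):
            maps = self.head(feats[f"F{i}"])
            out[i] = {"stride": stride, **maps}
        return out

    def decode_ltrb(self, level: int, reg: np.ndarray) -> np.ndarray:
        """exp parameterization in stride units -> nonnegative image units."""
        scale = float(getattr(self, f"scale{level}").data[0])
        stride = STRIDES[level - 3]
        return np.exp(np.clip(reg * scale, -10.0, 10.0)) * stride

    def decode_ltrb_tensor(self, level: int, reg: Tensor) -> Tensor:
        scale = getattr(self, f"scale{level}")
        stride = STRIDES[level - 3]
        return (reg * scale).clip(-10.0, 10.0).exp() * float(stride)


@dataclass
class DetectionSet:
    """Kept instances after top-d filtering and NMS (one image)."""

    boxes: np.ndarray  # (n, 4) xyxy
    scores: np.ndarray  # objectness * centerness ranking score
    objectness: np.ndarray
    centerness: np.ndarray
    levels: np.ndarray  # pyramid level per instance (3..7)
    cells: np.ndarray  # (n, 2) grid row/col at the instance's level
    attention: np.ndarray = field(default=None)  # (n, M, M), softmaxed

    def __len__(self):
        return len(self.boxes)


def select_instances(outputs: dict, net: InstNet, d: int | None = None,
                     nms_threshold: float | None = None,
                     max_instances: int | None = None,
                     vote_iou: float | None = None) -> DetectionSet:
    """Top-d per level, pooled greedy NMS, box voting, attention read-out.

    ``vote_iou`` (default from config) enables score-weighted averaging of
    each kept box with the candidates it overlaps above the threshold.
    """
    cfg = net.cfg
    d = cfg.topk_per_level if d is None else d
    nms_threshold = cfg.nms_threshold if nms_threshold is None else nms_threshold
    max_instances = cfg.max_instances if max_instances is None else max_instances
    if d < 1:
        raise ValueError("top-d must be >= 1")
    if not (0 < nms_threshold < 1):
        raise ValueError("NMS threshold must lie in (0, 1)")

    cand = {"boxes": [], "obj": [], "ctr": [], "level": [], "cell": []}
    for i, maps in outputs.items():
        stride = maps["stride"]
        cls = 1.0 / (1.0 + np.exp(-maps["cls"].data[0, 0]))
        ctr = 1.0 / (1.0 + np.exp(-maps["ctr"].data[0, 0]))
        h, w = cls.shape
        score = (cls * ctr).ravel()
        k = min(d, score.size)
        top = np.argpartition(-score, k - 1)[:k]
        rows, cols = np.unravel_index(top, (h, w))
        locs = level_locations(h, w, stride)[rows, cols]
        reg = maps["reg"].data[0].transpose(1, 2, 0)[rows, cols]
        ltrb = net.decode_ltrb(i, reg)
        cand["boxes"].append(decode_boxes(locs, ltrb))
        cand["obj"].append(cls[rows, cols])
        cand["ctr"].append(ctr[rows, cols])
        cand["level"].append(np.full(k, i))
        cand["cell"].append(np.stack([rows, cols], axis=1))

    boxes = np.concatenate(cand["boxes"])
    obj = np.concatenate(cand["obj"])
    ctr = np.concatenate(cand["ctr"])
    levels = np.concatenate(cand["level"])
    cells = np.concatenate(cand["cell"])
    score = obj * ctr
    if boxes.size == 0:
        return DetectionSet(*(np.empty((0, 4)), np.empty(0), np.empty(0),
                              np.empty(0), np.empty(0, int),
                              np.empty((0, 2), int)))
    keep = nms(boxes, score, nms_threshold)[:max_instances]
    if vote_iou is None:
        vote_iou = cfg.box_vote_iou
    kept_boxes = boxes[keep]
    if vote_iou and len(keep):
        # box voting: each kept box becomes the score-weighted mean of the
        # dense candidates it suppressed, tightening localization
        overlap = box_iou_matrix(kept_boxes, boxes)
        for k in range(len(keep)):
            sel = overlap[k] > vote_iou
            wts = score[sel]
            kept_boxes[k] = (boxes[sel] * wts[:, None]).sum(0) / wts.sum()
    det = DetectionSet(kept_boxes, score[keep], obj[keep], ctr[keep],
                       levels[keep].astype(int), cells[keep])
    det.attention = read_attention(outputs, det.levels, det.cells,
                                   cfg.attention_size)
    return det


def read_attention(outputs: dict, levels, cells, m: int,
                   as_tensor: bool = False):
    """Softmax-normalized M x M attention at (level, row, col) per instance."""
    maps = []
    for lvl, (r, c) in zip(levels, cells):
        logits = outputs[int(lvl)]["att"][0, :, int(r), int(c)]  # (M*M,) Tensor
        if as_tensor:
            maps.append(softmax(logits, axis=0).reshape(m, m))
        else:
            maps.append(softmax(logits.detach(), axis=0).numpy().reshape(m, m))
    if as_tensor:
        return maps
    return (np.stack(maps) if maps else np.empty((0, m, m)))


def assign_gt_levels(gt_boxes: np.ndarray, cfg: ModelConfig,
                     level_shapes: dict) -> list:
    """Map each GT box to (level, row, col) by the regression-range scheme.

    A box belongs to the level whose range contains half its longer side;
    the read-out cell is the grid cell nearest the box center (the
    nearest-location fallback when the exact cell is out of bounds is
    logged).
    """
    assigned = []
    for box in np.asarray(gt_boxes).reshape(-1, 4):
        half_long = max(box[2] - box[0], box[3] - box[1]) / 2.0
        lvl = LEVELS[-1]
        for i, (lo, hi) in zip(LEVELS, cfg.regress_ranges):
            if lo <= half_long < hi:
                lvl = i
                break
        stride = STRIDES[lvl - 3]
        h, w = level_shapes[lvl]
        cx = (box[0] + box[2]) / 2.0
        cy = (box[1] + box[3]) / 2.0
        col = int(np.floor(cx / stride))
        row = int(np.floor(cy / stride))
        if not (0 <= row < h and 0 <= col < w):
            logger.warning("GT box %s has no assigned cell; clamping", box)
            row = int(np.clip(row, 0, h - 1))
            col = int(np.clip(col, 0, w - 1))
        assigned.append((lvl, row, col))
    return assigned


def fcos_targets(gt_boxes: np.ndarray, level_shapes: dict,
                 cfg: ModelConfig) -> dict:
    """Dense FCOS supervision targets for one image.

    Returns per level: ``pos`` (bool H,W), ``ltrb`` (H,W,4), ``centerness``
    (H,W).  Positive cells lie within the center-sampling radius of a GT
    whose required offsets fall in the level's regression range; overlaps
    resolve to the smallest-area GT.
    """
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    areas = np.clip(gt[:, 2] - gt[:, 0], 0, None) * np.clip(gt[:, 3] - gt[:, 1], 0, None)
    out = {}
    for lvl, stride, (lo, hi) in zip(LEVELS, STRIDES, cfg.regress_ranges):
        h, w = level_shapes[lvl]
        locs = level_locations(h, w, stride).reshape(-1, 2)
        if len(gt) == 0:
            out[lvl] = {
                "pos": np.zeros((h, w), bool),
                "ltrb": np.zeros((h, w, 4)),
                "centerness": np.zeros((h, w)),
            }
            continue
        l = locs[:, None, 0] - gt[None, :, 0]
        t = locs[:, None, 1] - gt[None, :, 1]
        r = gt[None, :, 2] - locs[:, None, 0]
        b = gt[None, :, 3] - locs[:, None, 1]
        ltrb = np.stack([l, t, r, b], axis=-1)  # (HW, K, 4)
        inside = ltrb.min(axis=-1) > 0
        maxoff = ltrb.max(axis=-1)
        in_range = (maxoff >= lo) & (maxoff < hi)
        cx = (gt[:, 0] + gt[:, 2]) / 2
        cy = (gt[:, 1] + gt[:, 3]) / 2
        rad = cfg.center_sample_radius * stride
        near = (np.abs(locs[:, None, 0] - cx[None]) <= rad) & (
            np.abs(locs[:, None, 1] - cy[None]) <= rad)
        cand = inside & in_range & near
        cost = np.where(cand, areas[None, :], np.inf)
        best = cost.argmin(axis=1)
        pos = cand.any(axis=1)
        sel = ltrb[np.arange(len(locs)), best]  # (HW, 4)
        lmin = np.minimum(sel[:, 0], sel[:, 2])
        lmax = np.maximum(sel[:, 0], sel[:, 2])
        tmin = np.minimum(sel[:, 1], sel[:, 3])
        tmax = np.maximum(sel[:, 1], sel[:, 3])
        with np.errstate(invalid="ignore", divide="ignore"):
            ctr = np.sqrt(
                np.clip(lmin / np.maximum(lmax, 1e-12), 0, None)
                * np.clip(tmin / np.maximum(tmax, 1e-12), 0, None)
            )
        ctr = np.where(pos, ctr, 0.0)
        out[lvl] = {
            "pos": pos.reshape(h, w),
            "ltrb": np.where(pos[:, None], sel, 0.0).reshape(h, w, 4),
            "centerness": ctr.reshape(h, w),
            "gt_index": np.where(pos, best, -1).reshape(h, w),
        }
    return out
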