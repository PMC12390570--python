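"""Two-stage training: joint extractor optimization, then frozen-feature
length regression.

Stage 1 optimizes the pixel- and instance-level extractors (plus the
auxiliary supervision heads and the mask projection) with SGD + momentum,
linear warmup, multi-scale resize + horizontal-flip augmentation, and
gradient clipping.  Stage 2 freezes every extractor parameter bit-exactly
and trains only the length regressor on blended ground-truth crops with the
hybrid L2/L1 loss; the frozen features are deterministic, so they are
precomputed once per image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .instnet import assign_gt_levels, fcos_targets, read_attention
from .lengthhead import blend, roi_crop
from .losses import (LossConfig, focal_loss, iou_loss_ltrb, stage1_loss,
                     stage2_loss)
from .model import GLEN, normalize_image
from .nnet import (SGD, Tensor, as_tensor, bce_with_logits, bilinear_resize,
                   clip_grad_norm, concatenate, cross_entropy, roi_align,
                   stack, warmup_lr, where_mask)
from .pixelnet import pad_to_stride

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# samples and augmentation
# ---------------------------------------------------------------------------

class TrainSample:
    """One scene prepared for training: image + boxes + masks + lengths."""

    def __init__(self, image, boxes, masks, lengths_px):
        self.image = np.asarray(image)
        self.boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
        self.masks = [np.asarray(m, dtype=bool) for m in masks]
        self.lengths_px = np.asarray(lengths_px, dtype=float)

    @staticmethod
    def from_scene(scene) -> "TrainSample":
        return TrainSample(scene.image, scene.boxes, scene.masks,
                           scene.lengths_px)

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.image.shape[:2], dtype=bool)
        for m in self.masks:
            out |= m
        return out

    def hflip(self) -> "TrainSample":
        w = self.image.shape[1]
        boxes = self.boxes.copy()
        boxes[:, [0, 2]] = w - boxes[:, [2, 0]]
        return TrainSample(self.image[:, ::-1].copy(), boxes,
                           [m[:, ::-1].copy() for m in self.masks],
                           self.lengths_px)

    def resized(self, size: int) -> "TrainSample":
        from skimage.transform import resize

        h, w = self.image.shape[:2]
        if max(h, w) == size:
            return self
        scale = size / max(h, w)
        nh, nw = int(round(h * scale)), int(round(w * scale))
        img = resize(self.image, (nh, nw), order=1, preserve_range=True,
                     anti_aliasing=True).astype(np.uint8)
        masks = [
            resize(m.astype(float), (nh, nw), order=0,
                   preserve_range=True) > 0.5
            for m in self.masks
        ]
        return TrainSample(img, self.boxes * scale, masks,
                           self.lengths_px * scale)


def augment(sample: TrainSample, cfg: LossConfig,
            rng: np.random.Generator) -> TrainSample:
    size = int(rng.choice(cfg.input_sizes))
    sample = sample.resized(size)
    if cfg.hflip and rng.random() < 0.5:
        sample = sample.hflip()
    return sample


def _as_samples(scenes) -> list:
    return [s if isinstance(s, TrainSample) else TrainSample.from_scene(s)
            for s in scenes]


# ---------------------------------------------------------------------------
# stage-1 loss
# ---------------------------------------------------------------------------

def _blended_gt_crops(model: GLEN, feats_b, outputs_b, sample: TrainSample):
    """Blended crops at GT boxes for one batch element (training mode)."""
    level_shapes = {lvl: outputs_b[lvl]["cls"].shape[-2:] for lvl in outputs_b}
    assigned = assign_gt_levels(sample.boxes, model.cfg, level_shapes)
    atts = read_attention(outputs_b, [a[0] for a in assigned],
                          [(a[1], a[2]) for a in assigned],
                          model.cfg.attention_size, as_tensor=True)
    feature, stride = model.basis_feature(feats_b)
    crops, kept = roi_crop(feature, sample.boxes, model.cfg.roi_size, stride,
                           image_size=sample.image.shape[:2])
    att_t = stack([atts[int(i)] for i in kept], axis=0)
    return blend(crops, att_t), kept


def _index_batch(feats: dict, outputs: dict, b: int):
    """Single-element views of batched features / dense outputs."""
    feats_b = {k: v[b:b + 1] for k, v in feats.items()}
    outputs_b = {
        lvl: {k: (v if k == "stride" else v[b:b + 1])
              for k, v in maps.items()}
        for lvl, maps in outputs.items()
    }
    return feats_b, outputs_b


def stage1_batch_loss(model: GLEN, batch: list, cfg: LossConfig):
    """Composite stage-1 loss over a batch of equal-sized samples."""
    if len({s.image.shape for s in batch}) != 1:
        raise ValueError("stage-1 batches must share one image size")
    x = Tensor(np.concatenate(
        [pad_to_stride(normalize_image(s.image)) for s in batch]))
    feats = model.pixel(x)
    outputs = model.inst(feats)
    level_shapes = {lvl: outputs[lvl]["cls"].shape[-2:] for lvl in outputs}
    per_sample_targets = [
        fcos_targets(s.boxes, level_shapes, model.cfg) for s in batch
    ]

    # --- instance components ---
    logit_parts, ctr_parts, pos_parts, ctr_tgt_parts = [], [], [], []
    reg_losses, reg_counts = [], []
    npos = 0
    for lvl, maps in outputs.items():
        pos_b = np.stack([t[lvl]["pos"] for t in per_sample_targets])
        ltrb_b = np.stack([t[lvl]["ltrb"] for t in per_sample_targets])
        ctr_b = np.stack([t[lvl]["centerness"] for t in per_sample_targets])
        npos += int(pos_b.sum())
        logit_parts.append(maps["cls"].reshape(-1))
        ctr_parts.append(maps["ctr"].reshape(-1))
        pos_parts.append(pos_b.reshape(-1))
        ctr_tgt_parts.append(ctr_b.reshape(-1))
        if pos_b.any():
            nb, rows, cols = np.nonzero(pos_b)
            reg_sel = maps["reg"][nb, :, rows, cols]  # (P, 4)
            pred_ltrb = model.inst.decode_ltrb_tensor(lvl, reg_sel)
            reg_losses.append(
                iou_loss_ltrb(pred_ltrb, ltrb_b[nb, rows, cols],
                              weights=ctr_b[nb, rows, cols]))
            reg_counts.append(int(pos_b.sum()))
    logits = concatenate(logit_parts)
    pos_all = np.concatenate(pos_parts)
    p = logits.sigmoid().clip(1e-6, 1.0 - 1e-6)
    p_true = where_mask(pos_all, p, 1.0 - p)
    focal = focal_loss(p_true, gamma=cfg.gamma, npos=max(npos, 1))
    if reg_losses:
        wsum = float(sum(reg_counts))
        box_loss = sum((l * (n / wsum) for l, n in zip(reg_losses, reg_counts)),
                       as_tensor(np.float32(0.0)))
    else:
        box_loss = as_tensor(np.float32(0.0))
    if npos > 0:
        ctr_all = concatenate(ctr_parts)
        idx = np.nonzero(pos_all)[0]
        ctr_tgt = np.concatenate(ctr_tgt_parts)
        ctr_loss = bce_with_logits(ctr_all[idx], ctr_tgt[idx])
    else:
        ctr_loss = as_tensor(np.float32(0.0))

    # --- pixel components ---
    unions = np.stack([s.union_mask() for s in batch]).astype(np.float32)
    union_t = Tensor(unions[:, None])
    seg_losses = []
    for lvl in outputs:
        f = feats[f"F{lvl}"]
        h, w = f.shape[-2:]
        target = bilinear_resize(union_t, h, w).numpy()
        seg_losses.append(bce_with_logits(model.aux.seg_proj(f), target))
    seg_loss = sum(seg_losses[1:], seg_losses[0]) / len(seg_losses)

    bmap = feats["B"]
    hb, wb = bmap.shape[-2:]
    sem_labels = (bilinear_resize(union_t, hb, wb).numpy()[:, 0] > 0.5
                  ).astype(int)
    sem_loss = cross_entropy(model.aux.sem_head(bmap), sem_labels, axis=1)

    blend_losses = []
    for b, sample in enumerate(batch):
        if len(sample.boxes) == 0:
            continue
        feats_b, outputs_b = _index_batch(feats, outputs, b)
        blended, kept = _blended_gt_crops(model, feats_b, outputs_b, sample)
        mlogits = model.length.mask_logits(blended)
        # binary crop targets: the GT mask resampled into the box and
        # thresholded, matching the binary nature of the mask BCE
        mask_targets = np.stack([
            (roi_align(Tensor(sample.masks[i].astype(np.float32)[None]),
                       sample.boxes[i][None], model.cfg.roi_size,
                       stride=1.0).numpy()[0] >= 0.5).astype(np.float32)
            for i in kept
        ])
        blend_losses.append(bce_with_logits(mlogits, mask_targets))
    if blend_losses:
        blend_loss = sum(blend_losses[1:], blend_losses[0]) / len(blend_losses)
    else:
        blend_loss = as_tensor(np.float32(0.0))

    pixel = {"mask_bce": seg_loss, "semantic_ce": sem_loss,
             "blend_mask_bce": blend_loss}
    instance = {"focal": focal, "box_iou": box_loss, "centerness": ctr_loss}
    total = stage1_loss(pixel, instance, cfg)
    comps = {k: float(v.data) for k, v in {**pixel, **instance}.items()}
    return total, comps


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

class TrainingLog:
    def __init__(self):
        self.rows: list[dict] = []

    def append(self, **row):
        self.rows.append(row)

    @property
    def losses(self):
        return [r["loss"] for r in self.rows]

    def to_csv(self, path):
        pd.DataFrame(self.rows).to_csv(path, index=False)


def train_stage1(scenes: list, model: GLEN, cfg: LossConfig,
                 seed: int = 0, iterations: int | None = None,
                 log_path=None) -> TrainingLog:
    """Jointly optimize both feature extractors on annotated scenes."""
    samples = _as_samples(scenes)
    iterations = cfg.iterations_stage1 if iterations is None else iterations
    rng = np.random.default_rng([seed, 1])
    params = model.extractor_parameters()
    opt = SGD(params, lr=cfg.lr_stage1, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    model.train()
    log = TrainingLog()
    stable_state = model.state_dict()
    for it in range(iterations):
        opt.lr = warmup_lr(cfg.lr_stage1, it, cfg.warmup_iterations)
        idx = rng.integers(0, len(samples), size=cfg.batch_size)
        batch = [augment(samples[i], cfg, rng) for i in idx]
        opt.zero_grad()
        loss, comps = stage1_batch_loss(model, batch, cfg)
        if not np.isfinite(loss.data):
            model.load_state_dict(stable_state)
            raise FloatingPointError(
                f"stage-1 loss diverged at iteration {it}; "
                "restored last stable checkpoint"
            )
        loss.backward()
        grad_norm = clip_grad_norm(params, cfg.grad_clip_norm)
        opt.step()
        log.append(iteration=it, loss=float(loss.data),
                   grad_norm=min(grad_norm, cfg.grad_clip_norm),
                   pre_clip_grad_norm=grad_norm, lr=opt.lr, **comps)
        if it % 50 == 0:
            stable_state = model.state_dict()
            logger.info("stage1 it=%d loss=%.4f", it, float(loss.data))
    model.eval()
    model.stage1_trained = True
    if log_path is not None:
        log.to_csv(log_path)
    return log


def _jitter_boxes(boxes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly rescale/shift boxes, emulating detector localization noise
    so the regressor is robust to inference-time box perturbations."""
    boxes = boxes.copy()
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    scale = rng.uniform(0.85, 1.2, size=(len(boxes), 1))
    shift = rng.uniform(-0.07, 0.07, size=(len(boxes), 2))
    cx = (boxes[:, 0] + boxes[:, 2]) / 2 + shift[:, 0] * w
    cy = (boxes[:, 1] + boxes[:, 3]) / 2 + shift[:, 1] * h
    half_w = w * scale[:, 0] / 2
    half_h = h * scale[:, 0] / 2
    return np.stack([cx - half_w, cy - half_h, cx + half_w, cy + half_h],
                    axis=1)


def precompute_stage2_inputs(scenes: list, model: GLEN, n_jitter: int = 2,
                             seed: int = 0):
    """Frozen-extractor blended crops + pixel-length targets per scene.

    Each instance contributes its ground-truth-box crop plus ``n_jitter``
    crops at randomly perturbed boxes (same length target).
    """
    model.eval()
    rng = np.random.default_rng([seed, 3])
    crops, targets, owners = [], [], []
    for si, sample in enumerate(_as_samples(scenes)):
        if len(sample.boxes) == 0:
            continue
        feats, outputs = model.forward_features(sample.image)
        box_sets = [sample.boxes] + [
            _jitter_boxes(sample.boxes, rng) for _ in range(n_jitter)
        ]
        for boxes in box_sets:
            jittered = TrainSample(sample.image, boxes, sample.masks,
                                   sample.lengths_px)
            blended, kept = _blended_gt_crops(model, feats, outputs, jittered)
            crops.append(blended.detach().numpy())
            targets.append(sample.lengths_px[kept])
            owners.extend([si] * len(kept))
    return (np.concatenate(crops), np.concatenate(targets),
            np.asarray(owners))


def _dihedral(crops: np.ndarray, k: int) -> np.ndarray:
    """One of the 8 square symmetries applied to (K,C,R,R) crops.

    A rotated or mirrored radicle has the same length, so the dihedral
    group is an exact label-preserving augmentation for the regressor.
    """
    out = np.rot90(crops, k % 4, axes=(2, 3))
    if k >= 4:
        out = out[:, :, :, ::-1]
    return np.ascontiguousarray(out)


def train_stage2(scenes: list, model: GLEN, cfg: LossConfig, seed: int = 0,
                 iterations: int | None = None, log_path=None,
                 require_stage1: bool = True) -> TrainingLog:
    """Train the length regressor on frozen features (hybrid L2/L1 loss)."""
    if require_stage1 and not getattr(model, "stage1_trained", False):
        raise RuntimeError(
            "stage 2 requires a stage-1 checkpoint: train stage 1 first or "
            "load a stage-1 checkpoint"
        )
    iterations = cfg.iterations_stage2 if iterations is None else iterations
    rng = np.random.default_rng([seed, 2])
    crops, targets, owners = precompute_stage2_inputs(scenes, model,
                                                      seed=seed)
    params = model.regressor_parameters()
    opt = SGD(params, lr=cfg.lr_stage2, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    checksum_before = model.extractor_checksum()
    log = TrainingLog()
    n_scenes = int(owners.max()) + 1
    for m in (model.length.bn1, model.length.bn2):
        m.training = True
    for it in range(iterations):
        opt.lr = warmup_lr(cfg.lr_stage2, it, min(cfg.warmup_iterations, 100))
        pick = rng.integers(0, n_scenes, size=2 * cfg.batch_size)
        sel = np.nonzero(np.isin(owners, pick))[0]
        if len(sel) == 0:
            continue
        if len(sel) > 48:  # cap the crop batch; jittered copies triple it
            sel = rng.choice(sel, size=48, replace=False)
        batch = Tensor(_dihedral(crops[sel], int(rng.integers(0, 8))))
        opt.zero_grad()
        pred = model.length.regress(batch)
        loss = stage2_loss(targets[sel], pred, beta=cfg.beta)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"stage-2 loss diverged at {it}")
        loss.backward()
        grad_norm = clip_grad_norm(params, cfg.grad_clip_norm)
        opt.step()
        log.append(iteration=it, loss=float(loss.data),
                   grad_norm=min(grad_norm, cfg.grad_clip_norm),
                   pre_clip_grad_norm=grad_norm, lr=opt.lr)
    # recalibrate the regressor's BN running statistics on the full crop
    # set so eval-mode normalization matches the training distribution
    for m in (model.length.bn1, model.length.bn2):
        m.momentum = 1.0
    model.length.regress(Tensor(crops))
    for m in (model.length.bn1, model.length.bn2):
        m.momentum = 0.1
    model.eval()
    checksum_after = model.extractor_checksum()
    if checksum_before != checksum_after:
        raise RuntimeError("extractor parameters changed during stage 2")
    if log_path is not None:
        log.to_csv(log_path)
    return log


def fit(scenes: list, model: GLEN, cfg: LossConfig, seed: int = 0,
        iterations_stage1: int | None = None,
        iterations_stage2: int | None = None):
    """Run both stages in sequence; returns (stage1_log, stage2_log)."""
    log1 = train_stage1(scenes, model, cfg, seed=seed,
                        iterations=iterations_stage1)
    log2 = train_stage2(scenes, model, cfg, seed=seed,
                        iterations=iterations_stage2)
    return log1, log2
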