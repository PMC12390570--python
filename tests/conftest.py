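"""Shared fixtures, including the desk-scale two-stage training study."""

import numpy as np
import pytest

from radiclen import simgerm, training
from radiclen.conf import ModelConfig
from radiclen.instnet import box_iou_matrix
from radiclen.losses import LossConfig
from radiclen.model import GLEN


@pytest.fixture(scope="session")
def desk_run():
    """Train the tiny profile end to end on synthetic scenes.

    200 training and 60 held-out 192x192 scenes at 2 px/mm; stage 1 trains
    both extractors, stage 2 the frozen-feature length regressor.  Returns
    the model, both training logs, and held-out pipeline measurements
    (greedy box-IoU matching at 0.3 of predictions to ground truth).
    """
    gcfg = simgerm.GeneratorConfig.tiny()
    train = [simgerm.generate_scene(gcfg, seed=s) for s in range(200)]
    held = [simgerm.generate_scene(gcfg, seed=s) for s in range(200, 260)]

    model = GLEN(ModelConfig.tiny(), seed=1)
    cfg = LossConfig.tiny()
    log1 = training.train_stage1(train, model, cfg, seed=0)
    extractor_state = {
        name: p.data.copy()
        for name, p in list(model.pixel.named_parameters())
        + [("inst." + n, p) for n, p in model.inst.named_parameters()]
        + [("aux." + n, p) for n, p in model.aux.named_parameters()]
    }
    log2 = training.train_stage2(train, model, cfg, seed=0)

    gt_len, pred_len, mask_ious = [], [], []
    n_gt = n_matched = 0
    for scene in held:
        results = model.predict(scene.image)
        n_gt += len(scene.boxes)
        if not results:
            continue
        pred_boxes = np.array([r["box"] for r in results])
        iou = box_iou_matrix(scene.boxes, pred_boxes)
        used = set()
        for gi in range(len(scene.boxes)):
            for pi in np.argsort(-iou[gi]):
                if pi in used:
                    continue
                if iou[gi, pi] >= 0.3:
                    used.add(pi)
                    n_matched += 1
                    gt_len.append(scene.lengths_px[gi])
                    pred_len.append(results[pi]["length_px"])
                    inter = np.logical_and(scene.masks[gi],
                                           results[pi]["mask"]).sum()
                    union = np.logical_or(scene.masks[gi],
                                          results[pi]["mask"]).sum()
                    mask_ious.append(inter / union)
                break
    return {
        "model": model,
        "train": train,
        "held": held,
        "log1": log1,
        "log2": log2,
        "extractor_state": extractor_state,
        "gt_lengths_px": np.array(gt_len),
        "pred_lengths_px": np.array(pred_len),
        "train_lengths_px": np.concatenate(
            [s.lengths_px for s in train]),
        "mask_ious": np.array(mask_ious),
        "n_gt": n_gt,
        "n_matched": n_matched,
        "px_per_mm": gcfg.px_per_mm,
    }
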