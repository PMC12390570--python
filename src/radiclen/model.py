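"""The dual-path radicle measurement model: assembly and inference.

``GLEN`` couples the pixel-level extractor (backbone + FPN + SE + basis
decoder), the instance-level extractor (shared dense heads + NMS +
attention), and the length head (RoIAlign + blending + mask emission +
regression).  Auxiliary stage-1 supervision heads (a shared 1x1 foreground
projection applied to every pyramid level and a 1x1 semantic classifier on
the basis tensor) live in ``AuxHeads``; they are trained in stage 1 and
frozen afterwards together with both extractors.
"""

from __future__ import annotations

import json

import numpy as np

from .conf import ModelConfig
from .instnet import InstNet, read_attention, select_instances
from .lengthhead import LengthHead, blend, predict_instance_mask, roi_crop
from .nnet import Conv2d, Module, Tensor
from .pixelnet import PixelNet, pad_to_stride


def normalize_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> (1,3,H,W) float32 in roughly [-0.5, 0.5]."""
    x = np.asarray(image, dtype=np.float32) / 255.0 - 0.5
    return x.transpose(2, 0, 1)[None]


class AuxHeads(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.seg_proj = Conv2d(rng, cfg.fpn_channels, 1, 1)
        self.sem_head = Conv2d(rng, cfg.k, 2, 1)


class GLEN(Module):
    """End-to-end model; construction is reproducible from (config, seed)."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.seed = seed
        rng = np.random.default_rng([seed, 0x61EA])
        self.pixel = PixelNet(rng, self.cfg)
        self.inst = InstNet(rng, self.cfg)
        self.aux = AuxHeads(rng, self.cfg)
        self.length = LengthHead(rng, self.cfg)

    # -- parameter groups ---------------------------------------------------
    def extractor_parameters(self):
        """Everything frozen during stage 2 (extractors, aux, mask projection)."""
        params = list(self.pixel.parameters()) + list(self.inst.parameters())
        params += list(self.aux.parameters())
        params += [p for _, p in self.length.mask_proj.named_parameters()]
        return params

    def regressor_parameters(self):
        mods = [self.length.conv1, self.length.bn1, self.length.conv2,
                self.length.bn2, self.length.fc1, self.length.fc2]
        out = []
        for m in mods:
            out.extend(m.parameters())
        return out

    def extractor_checksum(self) -> float:
        return float(sum(np.float64(np.abs(p.data).sum())
                         for p in self.extractor_parameters()))

    # -- feature plumbing ---------------------------------------------------
    def basis_feature(self, feats: dict):
        if self.cfg.basis_source == "B":
            return feats["B"], 4.0
        return feats["F3"], 8.0

    def forward_features(self, image: np.ndarray):
        x = Tensor(pad_to_stride(normalize_image(np.asarray(image))))
        feats = self.pixel(x)
        outputs = self.inst(feats)
        return feats, outputs

    # -- inference ----------------------------------------------------------
    def predict(self, image: np.ndarray, pitch_px: float | None = None,
                grid_mm: float = 10.0) -> list[dict]:
        """Detect radicles and measure their lengths on one RGB image.

        Returns one record per instance: box, score, binary mask, predicted
        length in input pixels and (when a grid pitch is known) in mm.
        """
        self.eval()
        h, w = image.shape[:2]
        feats, outputs = self.forward_features(image)
        det = select_instances(outputs, self.inst)
        if len(det) == 0:
            return []
        feature, stride = self.basis_feature(feats)
        crops, kept = roi_crop(feature, det.boxes, self.cfg.roi_size,
                               stride, image_size=(h, w))
        blended = blend(crops, det.attention[kept])
        mask_logits = self.length.mask_logits(blended).detach().numpy()
        lengths = self.length.regress(blended).detach().numpy()
        results = []
        for row, k in enumerate(kept):
            box = det.boxes[k]
            mask = predict_instance_mask(
                mask_logits[row, 0], box, (h, w), self.cfg.mask_threshold)
            rec = {
                "box": box.tolist(),
                "score": float(det.scores[k]),
                "mask": mask,
                "length_px": float(lengths[row]),
            }
            if pitch_px:
                rec["length_mm"] = float(lengths[row]) * grid_mm / pitch_px
            results.append(rec)
        return results

    def length_vector(self, results: list[dict]) -> np.ndarray:
        return self.length.length_vector(
            [r["length_px"] for r in results],
            [r["score"] for r in results])

    # -- GT-driven crops (training mode / stage 2) --------------------------
    def crops_for_gt(self, image: np.ndarray, gt_boxes: np.ndarray,
                     as_tensor: bool = True):
        """Blended crops at ground-truth boxes (training-mode attention)."""
        from .instnet import assign_gt_levels

        feats, outputs = self.forward_features(image)
        level_shapes = {
            lvl: outputs[lvl]["cls"].shape[-2:] for lvl in outputs
        }
        assigned = assign_gt_levels(gt_boxes, self.cfg, level_shapes)
        levels = [a[0] for a in assigned]
        cells = [(a[1], a[2]) for a in assigned]
        atts = read_attention(outputs, levels, cells,
                              self.cfg.attention_size, as_tensor=as_tensor)
        feature, stride = self.basis_feature(feats)
        crops, kept = roi_crop(feature, gt_boxes, self.cfg.roi_size, stride,
                               image_size=image.shape[:2])
        if as_tensor:
            from .nnet import stack
            att_t = stack([atts[int(i)] for i in kept], axis=0)
        else:
            att_t = np.stack([atts[int(i)] for i in kept])
        blended = blend(crops, att_t)
        return blended, kept, feats, outputs

    # -- persistence ---------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        state = self.state_dict()
        meta = {
            "model_config": self.cfg.__dict__, "seed": self.seed,
            **(extra or {}),
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "GLEN":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        model = cls(ModelConfig(**meta["model_config"]), seed=meta["seed"])
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
        model.load_state_dict(state)
        model.meta = meta
        return model
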