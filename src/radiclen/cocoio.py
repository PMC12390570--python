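"""Dataset I/O: COCO-dialect annotations, RLE masks, manifests, splits.

Annotations are standard COCO JSON extended with additive per-annotation
fields ``length_mm``, ``length_px``, ``n_dev`` and a per-image field
``grid_pitch_px``; stock COCO readers ignore the extras.  Masks are stored as
uncompressed COCO RLE (column-major run lengths starting with background);
polygon segmentations are accepted on input and rasterized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .simgerm import AnnotatedScene, GeneratorConfig, LengthLaw, generate_scene

CATEGORY = {"id": 1, "name": "radicle"}


# ---------------------------------------------------------------------------
# RLE masks
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major runs, first count is background."""
    m = np.asarray(mask, dtype=bool)
    flat = m.flatten(order="F").astype(np.int8)
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    total = int(np.sum(counts))
    if total != h * w:
        raise ValueError(
            f"RLE counts sum to {total}, expected {h}x{w}={h * w}"
        )
    vals = np.zeros(total, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            vals[pos:pos + c] = True
        pos += c
        val = not val
    return vals.reshape((h, w), order="F")


def polygon_to_mask(polygons, height: int, width: int) -> np.ndarray:
    """Rasterize COCO polygon segmentation (list of flat [x0,y0,x1,y1,...])."""
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros((height, width), dtype=bool)
    for flat in polygons:
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(height, width))
        mask[rr, cc] = True
    return mask


def segmentation_to_mask(seg, height: int, width: int) -> np.ndarray:
    if isinstance(seg, dict):
        mask = rle_decode(seg)
        if mask.shape != (height, width):
            raise ValueError(
                f"RLE mask of size {mask.shape} does not match image "
                f"({height}, {width})"
            )
        return mask
    return polygon_to_mask(seg, height, width)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def config_to_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    law = d.pop("length_law", None)
    kwargs = {}
    if law is not None:
        kwargs["length_law"] = LengthLaw(**law)
    for key in ("category_weights", "instances_range"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**kwargs, **d)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """Image directory + COCO-dialect annotations + manifest + 80:20 split."""

    root: Path
    coco: dict
    manifest: dict

    @property
    def images(self):
        return self.coco["images"]

    @property
    def annotations(self):
        return self.coco["annotations"]

    def annotations_for(self, image_id: int):
        return [a for a in self.annotations if a["image_id"] == image_id]

    def load_image(self, image_id: int) -> np.ndarray:
        rec = next(i for i in self.images if i["id"] == image_id)
        return np.asarray(Image.open(self.root / rec["file_name"]).convert("RGB"))

    def masks_for(self, image_id: int):
        rec = next(i for i in self.images if i["id"] == image_id)
        return [
            segmentation_to_mask(a["segmentation"], rec["height"], rec["width"])
            for a in self.annotations_for(image_id)
        ]

    @property
    def train_ids(self):
        return list(self.manifest["split"]["train"])

    @property
    def val_ids(self):
        return list(self.manifest["split"]["val"])


def make_split(image_ids, seed: int, train_frac: float = 0.8):
    """Deterministic disjoint, exhaustive 80:20 train-validation split."""
    ids = list(image_ids)
    order = np.random.default_rng([seed, 0xC0FFEE]).permutation(len(ids))
    n_train = int(round(train_frac * len(ids)))
    train = sorted(ids[i] for i in order[:n_train])
    val = sorted(ids[i] for i in order[n_train:])
    return train, val


def scene_to_records(scene: AnnotatedScene, image_id: int, file_name: str,
                     ann_start: int):
    h, w = scene.image.shape[:2]
    image_rec = {
        "id": image_id, "file_name": file_name, "width": w, "height": h,
        "grid_pitch_px": scene.grid_pitch_px,
    }
    anns = []
    for k, mask in enumerate(scene.masks):
        x1, y1, x2, y2 = scene.boxes[k]
        anns.append({
            "id": ann_start + k, "image_id": image_id,
            "category_id": CATEGORY["id"],
            "segmentation": rle_encode(mask),
            "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
            "area": float(mask.sum()), "iscrowd": 0,
            "length_mm": float(scene.lengths_mm[k]),
            "length_px": float(scene.lengths_px[k]),
            "n_dev": int(scene.n_dev[k]),
        })
    return image_rec, anns


def write_generated_dataset(cfg: GeneratorConfig, n_images: int,
                            out_dir) -> dict:
    """Render ``n_images`` scenes and persist them; returns the manifest."""
    root = Path(out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    images, annotations, rows = [], [], []
    ann_id = 1
    for i in range(n_images):
        scene = generate_scene(cfg, seed=i)
        fname = f"images/scene_{i:05d}.png"
        Image.fromarray(scene.image).save(root / fname)
        img_rec, anns = scene_to_records(scene, i + 1, fname, ann_id)
        ann_id += len(anns)
        images.append(img_rec)
        annotations.extend(anns)
        for a in anns:
            rows.append({
                "image_id": a["image_id"], "annotation_id": a["id"],
                "length_mm": a["length_mm"], "length_px": a["length_px"],
                "n_dev": a["n_dev"], "grid_pitch_px": scene.grid_pitch_px,
            })
    coco = {
        "images": images, "annotations": annotations,
        "categories": [CATEGORY],
    }
    train, val = make_split([im["id"] for im in images], cfg.seed)
    manifest = {
        "generator_config": config_to_dict(cfg),
        "seed": cfg.seed, "n_images": n_images,
        "split": {"train": train, "val": val},
    }
    with open(root / "annotations.json", "w") as fh:
        json.dump(coco, fh)
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    pd.DataFrame(rows).to_csv(root / "instances.csv", index=False)
    return manifest


def write_dataset(bundle: DatasetBundle, out_dir) -> None:
    root = Path(out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    for rec in bundle.images:
        src = bundle.root / rec["file_name"]
        dst = root / rec["file_name"]
        if src.resolve() != dst.resolve():
            dst.write_bytes(src.read_bytes())
    with open(root / "annotations.json", "w") as fh:
        json.dump(bundle.coco, fh)
    with open(root / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


def read_dataset(path) -> DatasetBundle:
    """Load and validate a dataset directory written by this package."""
    root = Path(path)
    ann_path = root / "annotations.json"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.json under {root}")
    with open(ann_path) as fh:
        coco = json.load(fh)
    manifest = {}
    man_path = root / "manifest.json"
    if man_path.exists():
        with open(man_path) as fh:
            manifest = json.load(fh)
    if "split" not in manifest:
        ids = [im["id"] for im in coco["images"]]
        train, val = make_split(ids, int(manifest.get("seed", 0)))
        manifest["split"] = {"train": train, "val": val}
    by_id = {}
    for rec in coco["images"]:
        img_path = root / rec["file_name"]
        if not img_path.exists():
            raise FileNotFoundError(
                f"image {rec['file_name']!r} referenced by image id "
                f"{rec['id']} is missing"
            )
        by_id[rec["id"]] = rec
    for ann in coco["annotations"]:
        rec = by_id.get(ann["image_id"])
        if rec is None:
            raise ValueError(
                f"annotation {ann['id']} references unknown image "
                f"{ann['image_id']}"
            )
        seg = ann.get("segmentation")
        if isinstance(seg, dict):
            h, w = seg["size"]
            if (h, w) != (rec["height"], rec["width"]):
                raise ValueError(
                    f"annotation {ann['id']}: RLE size {(h, w)} does not "
                    f"match image {(rec['height'], rec['width'])}"
                )
            if int(np.sum(seg["counts"])) != h * w:
                raise ValueError(
                    f"annotation {ann['id']}: undecodable RLE"
                )
    return DatasetBundle(root=root, coco=coco, manifest=manifest)
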