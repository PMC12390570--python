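"""Instance-level extractor: box decoding, NMS oracle, attention maps."""

import numpy as np
import pytest

from radiclen.conf import ModelConfig
from radiclen.instnet import (InstNet, assign_gt_levels,
                              box_iou_matrix, decode_boxes, fcos_targets,
                              level_locations, nms, read_attention,
                              select_instances)
from radiclen.model import GLEN


def brute_force_nms(boxes, scores, thr):
    """O(n^2) oracle: repeatedly take the best-scoring unsuppressed box."""
    n = len(boxes)
    alive = list(range(n))
    # stable score ordering with index tie-break
    alive.sort(key=lambda i: (-scores[i], i))
    kept = []
    while alive:
        best = alive.pop(0)
        kept.append(best)
        survivors = []
        for j in alive:
            if box_iou_matrix(boxes[best], boxes[j])[0, 0] <= thr:
                survivors.append(j)
        alive = survivors
    return kept


class TestGeometry:
    def test_grid_cell_to_image_point(self):
        locs = level_locations(4, 6, stride=8)
        assert tuple(locs[0, 0]) == (4.0, 4.0)
        assert tuple(locs[2, 3]) == ((3 + 0.5) * 8, (2 + 0.5) * 8)

    def test_five_tuple_box_decoding(self):
        box = decode_boxes(np.array([100.0, 100.0]),
                           np.array([10.0, 10.0, 10.0, 10.0]))
        np.testing.assert_array_equal(box, [90, 90, 110, 110])

    def test_decoded_ltrb_nonnegative_by_construction(self):
        net = InstNet(np.random.default_rng(0), ModelConfig.tiny())
        raw = np.random.default_rng(1).normal(size=(5, 4)) * 50
        ltrb = net.decode_ltrb(3, raw)
        assert np.all(ltrb > 0)

    def test_decoded_boxes_translation_equivariant(self):
        locs = level_locations(6, 6, stride=8)
        ltrb = np.full((6, 6, 4), 12.0)
        boxes = decode_boxes(locs, ltrb)
        # one grid cell to the right = one stride in x
        np.testing.assert_allclose(
            boxes[:, 1:, :] - boxes[:, :-1, :],
            np.broadcast_to([8.0, 0, 8.0, 0], (6, 5, 4)))
        np.testing.assert_allclose(
            boxes[1:, :, :] - boxes[:-1, :, :],
            np.broadcast_to([0, 8.0, 0, 8.0], (5, 6, 4)))


class TestNMS:
    def test_single_candidate_kept(self):
        keep = nms(np.array([[0, 0, 10, 10.0]]), np.array([0.7]), 0.3)
        assert keep.tolist() == [0]

    def test_duplicate_boxes_keep_higher_score(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        keep = nms(boxes, np.array([0.8, 0.9]), 0.3)
        assert keep.tolist() == [1]

    def test_score_ties_break_by_lower_index(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11.0]])
        keep = nms(boxes, np.array([0.5, 0.5]), 0.3)
        assert keep[0] == 0

    def test_matches_brute_force_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        for case in range(100):
            n = rng.integers(1, 21)
            xy = rng.uniform(0, 80, size=(n, 2))
            wh = rng.uniform(5, 40, size=(n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.uniform(0.1, 1.0, size=n)
            thr = rng.uniform(0.2, 0.6)
            got = nms(boxes, scores, thr).tolist()
            want = brute_force_nms(boxes, scores, thr)
            assert got == want, f"case {case}"


@pytest.fixture(scope="module")
def tiny_model():
    return GLEN(ModelConfig.tiny(), seed=3).eval()


class TestSelection:
    def test_selection_validates_parameters(self, tiny_model):
        img = np.random.default_rng(0).integers(
            0, 255, size=(96, 96, 3), dtype=np.uint8)
        _, outputs = tiny_model.forward_features(img)
        with pytest.raises(ValueError):
            select_instances(outputs, tiny_model.inst, d=0)
        with pytest.raises(ValueError):
            select_instances(outputs, tiny_model.inst, nms_threshold=1.5)

    def test_kept_set_respects_nms_and_cap(self, tiny_model):
        img = np.random.default_rng(1).integers(
            0, 255, size=(96, 96, 3), dtype=np.uint8)
        _, outputs = tiny_model.forward_features(img)
        det = select_instances(outputs, tiny_model.inst, vote_iou=0)
        assert len(det) <= tiny_model.cfg.max_instances
        if len(det) > 1:
            iou = box_iou_matrix(det.boxes, det.boxes)
            off_diag = iou[~np.eye(len(det), dtype=bool)]
            assert off_diag.max() <= tiny_model.cfg.nms_threshold + 1e-9

    def test_attention_maps_are_7x7_softmax(self, tiny_model):
        img = np.random.default_rng(2).integers(
            0, 255, size=(96, 96, 3), dtype=np.uint8)
        _, outputs = tiny_model.forward_features(img)
        det = select_instances(outputs, tiny_model.inst)
        assert det.attention.shape[1:] == (7, 7)
        np.testing.assert_allclose(det.attention.sum(axis=(1, 2)), 1.0,
                                   rtol=1e-5)

    def test_training_mode_uses_gt_boxes(self, tiny_model):
        img = np.random.default_rng(3).integers(
            0, 255, size=(96, 96, 3), dtype=np.uint8)
        _, outputs = tiny_model.forward_features(img)
        shapes = {lvl: outputs[lvl]["cls"].shape[-2:] for lvl in outputs}
        gt = np.array([[5, 5, 40, 30], [50, 40, 90, 90], [10, 60, 30, 80.0]])
        assigned = assign_gt_levels(gt, tiny_model.cfg, shapes)
        assert len(assigned) == 3
        maps = read_attention(outputs, [a[0] for a in assigned],
                              [(a[1], a[2]) for a in assigned], 7)
        assert maps.shape == (3, 7, 7)
        np.testing.assert_allclose(maps.sum(axis=(1, 2)), 1.0, rtol=1e-5)


class TestTargets:
    def test_center_cell_positive_with_unit_centerness(self):
        cfg = ModelConfig.tiny()
        # box centered exactly on a stride-8 cell center
        box = np.array([[20.0 - 16, 20.0 - 16, 20.0 + 16, 20.0 + 16]])
        shapes = {3: (8, 8), 4: (4, 4), 5: (2, 2), 6: (1, 1), 7: (1, 1)}
        tgt = fcos_targets(box, shapes, cfg)
        assert tgt[3]["pos"][2, 2]
        assert tgt[3]["centerness"][2, 2] == pytest.approx(1.0)
        # regression targets at the center cell are the exact edge distances
        np.testing.assert_allclose(tgt[3]["ltrb"][2, 2], [16, 16, 16, 16])
        # cells outside the center-sampling radius stay negative
        assert not tgt[3]["pos"][0].any()

    def test_no_gt_gives_all_negative(self):
        cfg = ModelConfig.tiny()
        tgt = fcos_targets(np.empty((0, 4)), {3: (4, 4), 4: (2, 2),
                                              5: (1, 1), 6: (1, 1),
                                              7: (1, 1)}, cfg)
        assert not any(tgt[lvl]["pos"].any() for lvl in tgt)
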