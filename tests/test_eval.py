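"""Evaluation: AP oracle equivalence, matching, metrics, skeleton, ranks."""

import itertools

import numpy as np
import pytest

from radiclen import evaluate as ev
from radiclen.instnet import box_iou_matrix


def brute_force_ap(scores, ious, n_gt, thr):
    """Exhaustive PR oracle: greedy matching in score order, then the
    101-point interpolated area under the precision-recall staircase."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    matched = set()
    tp = []
    for i in order:
        best, best_iou = None, thr
        for g in range(ious.shape[1]):
            if g in matched:
                continue
            if ious[i, g] >= best_iou:
                best, best_iou = g, ious[i, g]
        if best is not None:
            matched.add(best)
            tp.append(1)
        else:
            tp.append(0)
    tp = np.array(tp)
    ctp = np.cumsum(tp)
    recall = ctp / n_gt
    precision = ctp / np.arange(1, len(tp) + 1)
    best_prec = np.zeros(101)
    pts = np.linspace(0, 1, 101)
    for k, r in enumerate(pts):
        sel = precision[recall >= r - 1e-12]
        best_prec[k] = sel.max() if len(sel) else 0.0
    return float(best_prec.mean())


def _as_records(boxes, scores):
    return {"boxes": np.asarray(boxes, float).reshape(-1, 4),
            "scores": np.asarray(scores, float)}


class TestAP:
    def test_single_perfect_detection(self):
        gt = [{"boxes": np.array([[0, 0, 10, 10.0]]), "masks": []}]
        pred = [_as_records([[0, 0, 10, 10]], [0.9])]
        out = ev.coco_ap(pred, gt)
        assert out["bbox"]["AP50"] == pytest.approx(1.0)

    def test_no_detections_gives_zero(self):
        gt = [{"boxes": np.array([[0, 0, 10, 10.0]]), "masks": []}]
        pred = [_as_records(np.empty((0, 4)), [])]
        assert ev.coco_ap(pred, gt)["bbox"]["AP50"] == 0.0

    def test_no_ground_truth_reported_absent(self):
        assert ev.coco_ap([_as_records([[0, 0, 1, 1]], [0.5])],
                          [{"boxes": np.empty((0, 4)), "masks": []}]) == \
            {"bbox": None, "segm": None}

    def test_five_detections_three_gt_hand_case(self):
        gt_boxes = np.array([[0, 0, 10, 10], [20, 0, 30, 10],
                             [40, 0, 50, 10.0]])
        pred_boxes = np.array([
            [0, 0, 10, 10],      # hit GT0, score .9
            [20, 1, 30, 11],     # hit GT1 (IoU ~0.82), score .8
            [60, 60, 70, 70],    # miss, score .7
            [40, 6, 50, 16],     # IoU 0.25 with GT2 -> miss at 0.5, score .6
            [41, 0, 51, 10],     # hit GT2 (IoU ~0.82), score .5
        ])
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        ious = box_iou_matrix(pred_boxes, gt_boxes)
        want = brute_force_ap(scores, ious, 3, 0.5)
        got = ev.coco_ap([{**_as_records(pred_boxes, scores)}],
                         [{"boxes": gt_boxes, "masks": []}])
        assert got["bbox"]["AP50"] == pytest.approx(want, abs=1e-9)

    def test_oracle_equivalence_on_random_small_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n_det = rng.integers(1, 7)
            n_gt = rng.integers(1, 5)
            gt_xy = rng.uniform(0, 50, (n_gt, 2))
            gt = np.concatenate([gt_xy, gt_xy + rng.uniform(5, 20, (n_gt, 2))],
                                axis=1)
            det_xy = rng.uniform(0, 50, (n_det, 2))
            det = np.concatenate([det_xy,
                                  det_xy + rng.uniform(5, 20, (n_det, 2))],
                                 axis=1)
            scores = rng.uniform(0.1, 1, n_det)
            ious = box_iou_matrix(det, gt)
            for thr in (0.5, 0.75):
                want = brute_force_ap(scores, ious, n_gt, thr)
                got = ev.average_precision(
                    [{"image": 0, "index": i, "score": float(scores[i]),
                      "n_gt_image": n_gt} for i in range(n_det)],
                    n_gt, thr, lambda img, d, g: ious[d, g])
                assert got == pytest.approx(want, abs=1e-9)


class TestMatching:
    def test_identical_masks_match_with_unit_iou(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 3:8] = True
        pairs, up, ug = ev.match_instances([m], [0.9], [m.copy()])
        assert pairs == [(0, 0, 1.0)] and not up and not ug

    def test_low_iou_pair_stays_unmatched(self):
        a = np.zeros((10, 10), bool)
        a[0:3, 0:10] = True
        b = np.zeros((10, 10), bool)
        b[2:4, 0:10] = True  # IoU = 10/50 = 0.2
        pairs, up, ug = ev.match_instances([a], [0.9], [b], iou_thr=0.5)
        assert not pairs and up == [0] and ug == [0]

    def test_greedy_by_score_takes_best_available_gt(self):
        base = np.zeros((12, 12), bool)
        g1 = base.copy(); g1[0:6, :] = True
        g2 = base.copy(); g2[6:12, :] = True
        p1 = base.copy(); p1[0:6, :] = True   # matches g1 exactly
        p2 = base.copy(); p2[5:11, :] = True  # overlaps both, best g2
        pairs, _, _ = ev.match_instances([p1, p2], [0.5, 0.9], [g1, g2])
        # higher-scoring p2 picks first: best available is g2
        assert sorted(pairs) == [(0, 0, 1.0), (1, 1, pytest.approx(5 / 7))]


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = ev.regression_metrics([1, 2, 3.0], [1, 2, 3.0])
        assert m["MAE"] == 0 and m["RMSE"] == 0
        assert m["pearson"] == pytest.approx(1.0)
        assert m["R2"] == pytest.approx(1.0)

    def test_constant_offset(self):
        m = ev.regression_metrics([10, 20, 30.0], [12, 22, 32.0])
        assert m["MAE"] == pytest.approx(2.0)
        assert m["RMSE"] == pytest.approx(2.0)
        assert m["pearson"] == pytest.approx(1.0)

    def test_hand_pairs_match_direct_formulas(self):
        gt = np.array([10, 20, 30, 40.0])
        pred = np.array([12, 18, 33, 37.0])
        m = ev.regression_metrics(gt, pred)
        err = pred - gt
        assert m["MAE"] == pytest.approx(np.mean(np.abs(err)))
        assert m["RMSE"] == pytest.approx(np.sqrt(np.mean(err**2)))
        sx = gt - gt.mean()
        sy = pred - pred.mean()
        r = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert m["pearson"] == pytest.approx(r)
        assert m["R2"] == pytest.approx(1 - (err**2).sum() / (sx**2).sum())
        assert m["RMSE"] >= m["MAE"]

    def test_zero_variance_gt_reports_absent_correlation(self):
        m = ev.regression_metrics([5, 5, 5.0], [4, 5, 6.0])
        assert m["pearson"] is None and m["R2"] is None


class TestSkeleton:
    @staticmethod
    def tapered_tube(length=100, r0=3.5, r1=1.5):
        from skimage.draw import disk

        mask = np.zeros((60, length + 60), bool)
        for i, x in enumerate(np.linspace(20, 20 + length, 4 * length)):
            r = r0 + (r1 - r0) * i / (4 * length)
            rr, cc = disk((30, x), max(r, 1.0), shape=mask.shape)
            mask[rr, cc] = True
        return mask

    def test_straight_tube_both_modes_near_truth(self):
        mask = self.tapered_tube(100)
        assert ev.skeleton_length(mask, "count") == pytest.approx(100, abs=3)
        assert ev.skeleton_length(mask, "corrected") == pytest.approx(100, abs=3)

    def test_one_pixel_mask_counts_one(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert ev.skeleton_length(m, "count") == 1.0

    def test_diagonal_tube_lattice_geometry(self):
        from skimage.draw import disk

        n = 90
        mask = np.zeros((n + 40, n + 40), bool)
        for i in np.linspace(0, n, 4 * n):
            rr, cc = disk((20 + i, 20 + i), 3.0, shape=mask.shape)
            mask[rr, cc] = True
        euclid = n * np.sqrt(2)
        corrected = ev.skeleton_length(mask, "corrected")
        count = ev.skeleton_length(mask, "count")
        assert corrected == pytest.approx(euclid, rel=0.05)
        # raw pixel counting under-measures diagonals by about sqrt(2)
        assert count == pytest.approx(euclid / np.sqrt(2), rel=0.08)

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ev.skeleton_length(np.zeros((5, 5), bool)) == 0.0

    def test_two_components_summed_with_warning(self):
        m = np.zeros((40, 80), bool)
        m[10:14, 5:25] = True
        m[30:34, 40:70] = True
        with pytest.warns(UserWarning, match="components"):
            total = ev.skeleton_length(m, "count")
        assert total > 30


class TestBaseline:
    def test_oracle_masks_on_empty_image(self):
        out = ev.baseline_segment_and_measure(np.zeros((20, 20), bool), 80.0)
        assert out == []

    def test_semantic_map_split_into_components(self):
        m = np.zeros((40, 90), bool)
        m[10:14, 5:35] = True
        m[30:34, 40:80] = True
        out = ev.baseline_segment_and_measure(m, pitch_px=80.0)
        assert len(out) == 2
        for rec in out:
            assert rec["length_mm"] == pytest.approx(
                rec["length_px"] / 8.0, rel=1e-9)


class TestGroupedReport:
    @staticmethod
    def pairs():
        rng = np.random.default_rng(0)
        out = []
        for i in range(30):
            gt = rng.uniform(12, 60)
            out.append(ev.MatchedPair(i, i, 0.9, gt, gt + rng.normal(0, 2),
                                      n_dev=int(rng.integers(0, 5))))
        return out

    def test_single_group_totals_equal_overall(self):
        pairs = [ev.MatchedPair(i, i, 1.0, 20.0 + i, 21.0 + i, n_dev=1)
                 for i in range(5)]
        df = ev.grouped_report(pairs)
        overall = df[df.group == "all"].iloc[0]
        grp = df[(df.grouping == "n_dev")].iloc[0]
        assert grp["MAE"] == pytest.approx(overall["MAE"])
        assert grp["n"] == overall["n"]

    def test_group_counts_sum_to_total(self):
        pairs = self.pairs()
        df = ev.grouped_report(pairs)
        for grouping in ("n_dev", "length_mm"):
            sub = df[df.grouping == grouping]
            assert sub["n"].sum() == len(pairs)


class TestRankCorrelation:
    def test_perfectly_monotone(self):
        out = ev.rank_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10],
                                  n_perm=200)
        assert out["spearman"] == pytest.approx(1.0)
        assert out["kendall"] == pytest.approx(1.0)
        assert out["p_spearman"] < 0.05

    def test_reversed(self):
        out = ev.rank_correlation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2],
                                  n_perm=100)
        assert out["spearman"] == pytest.approx(-1.0)
        assert out["kendall"] == pytest.approx(-1.0)

    def test_tied_example_matches_textbook_formulas(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0, 0, 1, 1, 2, 2]
        out = ev.rank_correlation(x, y, n_perm=50)
        # Spearman with ties = Pearson correlation of mid-ranks
        rx = np.array([1, 2, 3, 4, 5, 6.0])
        ry = np.array([1.5, 1.5, 3.5, 3.5, 5.5, 5.5])
        sx, sy = rx - rx.mean(), ry - ry.mean()
        rho = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert out["spearman"] == pytest.approx(rho, rel=1e-9)
        # Kendall tau-b with tie correction
        conc = disc = 0
        for (i, j) in itertools.combinations(range(6), 2):
            s = np.sign((x[j] - x[i]) * (y[j] - y[i]))
            conc += s > 0
            disc += s < 0
        n0 = 15
        t1 = 0  # no ties in x
        t2 = 3 * 1  # three tied pairs in y
        tau_b = (conc - disc) / np.sqrt((n0 - t1) * (n0 - t2))
        assert out["kendall"] == pytest.approx(tau_b, rel=1e-9)

    def test_constant_input_reported_absent(self):
        with pytest.warns(UserWarning):
            out = ev.rank_correlation([1, 2, 3], [5, 5, 5], n_perm=10)
        assert out["spearman"] is None

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ev.rank_correlation([1, 2], [1, 2])
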