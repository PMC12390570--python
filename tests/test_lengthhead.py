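"""Length head: RoIAlign oracle, multiplicative blending, slots, masks."""

import numpy as np
import pytest

from radiclen.conf import ModelConfig
from radiclen.lengthhead import (LengthHead, blend, predict_instance_mask,
                                 roi_crop)
from radiclen.nnet import Tensor, roi_align

RNG = np.random.default_rng(0)


class TestRoiAlign:
    def test_constant_feature_gives_constant_crop(self):
        feat = Tensor(np.full((3, 8, 8), 2.75, np.float32))
        out = roi_align(feat, np.array([[4.0, 4.0, 30.0, 20.0]]),
                        out_size=5, stride=4.0)
        np.testing.assert_allclose(out.numpy(), 2.75, rtol=1e-6)

    def test_output_size_is_r(self):
        feat = Tensor(RNG.normal(size=(2, 16, 16)))
        out = roi_align(feat, np.array([[0, 0, 64, 64.0]]), out_size=14,
                        stride=4.0)
        assert out.shape == (1, 2, 14, 14)

    def test_matches_direct_bilinear_interpolation_oracle(self):
        feat = RNG.normal(size=(1, 4, 4))
        box = np.array([[0.8, 1.2, 3.1, 3.9]])
        r = 3
        out = roi_align(Tensor(feat), box, out_size=r, stride=1.0).numpy()

        def bilinear(img, y, x):
            y = np.clip(y, 0, img.shape[0] - 1)
            x = np.clip(x, 0, img.shape[1] - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1 = min(y0 + 1, img.shape[0] - 1)
            x1 = min(x0 + 1, img.shape[1] - 1)
            fy, fx = y - y0, x - x0
            return ((1 - fy) * (1 - fx) * img[y0, x0]
                    + (1 - fy) * fx * img[y0, x1]
                    + fy * (1 - fx) * img[y1, x0]
                    + fy * fx * img[y1, x1])

        bw = (box[0, 2] - box[0, 0]) / r
        bh = (box[0, 3] - box[0, 1]) / r
        for i in range(r):
            for j in range(r):
                sy = box[0, 1] + (i + 0.5) * bh - 0.5
                sx = box[0, 0] + (j + 0.5) * bw - 0.5
                assert out[0, 0, i, j] == pytest.approx(
                    bilinear(feat[0], sy, sx), rel=1e-6)

    def test_degenerate_boxes_dropped_with_error_when_all_gone(self):
        feat = Tensor(RNG.normal(size=(1, 8, 8)))
        boxes = np.array([[2.0, 2.0, 2.0, 6.0]])  # zero width
        with pytest.raises(ValueError):
            roi_crop(feat, boxes, r=4, stride=1.0)
        # mixed: the good box survives, the degenerate one is dropped
        mixed = np.array([[2.0, 2.0, 2.0, 6.0], [1.0, 1.0, 6.0, 6.0]])
        crops, kept = roi_crop(feat, mixed, r=4, stride=1.0)
        assert kept.tolist() == [1]
        assert crops.shape == (1, 1, 4, 4)


class TestBlend:
    def test_unit_attention_is_identity(self):
        fi = Tensor(RNG.normal(size=(2, 3, 6, 6)))
        ai = np.ones((2, 7, 7))
        np.testing.assert_allclose(blend(fi, ai).numpy(), fi.numpy(),
                                   rtol=1e-6)

    def test_zero_attention_zeroes_features(self):
        fi = Tensor(RNG.normal(size=(1, 3, 6, 6)))
        out = blend(fi, np.zeros((1, 7, 7)))
        np.testing.assert_array_equal(out.numpy(), 0.0)

    def test_matches_elementwise_loop_oracle(self):
        from radiclen.nnet import bilinear_resize

        fi = RNG.normal(size=(1, 2, 5, 5))
        ai = RNG.uniform(size=(1, 7, 7))
        out = blend(Tensor(fi), ai).numpy()
        ai_up = bilinear_resize(Tensor(ai), 5, 5).numpy()
        expect = np.empty_like(fi)
        for c in range(2):
            for i in range(5):
                for j in range(5):
                    expect[0, c, i, j] = fi[0, c, i, j] * ai_up[0, i, j]
        np.testing.assert_allclose(out, expect, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        fi = Tensor(RNG.normal(size=(2, 3, 6, 6)))
        with pytest.raises(ValueError):
            blend(fi, np.ones((3, 7, 7)))  # wrong instance count


class TestRegressor:
    @pytest.fixture()
    def head(self):
        return LengthHead(np.random.default_rng(1), ModelConfig.tiny())

    def test_output_vector_has_64_slots_with_zeros_beyond(self, head):
        vec = head.length_vector([120.0, 80.0, 95.0], [0.5, 0.9, 0.7])
        assert vec.shape == (64,)
        # score order: 80 (0.9), 95 (0.7), 120 (0.5)
        np.testing.assert_array_equal(vec[:3], [80.0, 95.0, 120.0])
        np.testing.assert_array_equal(vec[3:], 0.0)

    def test_zero_instances_gives_all_zero_vector(self, head):
        vec = head.length_vector([], [])
        assert vec.shape == (64,) and not vec.any()

    def test_zero_features_with_final_bias(self, head):
        head.eval()
        for p in (head.conv1.weight, head.conv2.weight, head.fc1.weight,
                  head.fc1.bias, head.fc2.weight):
            p.data[:] = 0.0
        head.fc2.bias.data[:] = 3.25
        crops = Tensor(np.zeros((5, head.in_channels, 14, 14), np.float32))
        out = head.regress(crops).numpy()
        np.testing.assert_allclose(out, 3.25, rtol=1e-6)

    def test_gap_dimension_is_64(self, head):
        head.eval()
        crops = Tensor(RNG.normal(
            size=(2, head.in_channels, 14, 14)).astype(np.float32))
        x = head.bn2(head.conv2(head.bn1(
            head.conv1(crops)).relu())).relu()
        pooled = x.mean(axis=(2, 3))
        assert pooled.shape == (2, 64)


class TestMaskEmission:
    def test_large_positive_logits_fill_the_box(self):
        logits = np.full((14, 14), 20.0)
        mask = predict_instance_mask(logits, [10, 20, 30, 44], (64, 64))
        assert mask[20:44, 10:30].all()
        assert mask.sum() == 24 * 20

    def test_pixels_outside_box_are_background(self):
        logits = np.full((14, 14), 20.0)
        mask = predict_instance_mask(logits, [10, 20, 30, 44], (64, 64))
        outside = mask.copy()
        outside[20:44, 10:30] = False
        assert not outside.any()

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            predict_instance_mask(np.zeros((4, 4)), [0, 0, 4, 4], (8, 8),
                                  threshold=1.5)
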