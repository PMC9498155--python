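"""Sliding-window segmentation, aggregation, rendering and overlays."""

import numpy as np
import pytest

from tileseg import (SlideImage, binarize, overlay, predictions_per_pixel,
                     render, segment_slide, sliding_positions)
from tileseg.errors import DataError, ParameterError

from _oracles import brute_aggregate, brute_anchor_axis
from conftest import ConstantModel, HashModel, UntrainedModel


def _slide(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return SlideImage(rng.integers(0, 256, (h, w, 3)).astype(np.uint8))


class TestSlidingPositions:
    def test_exact_fit_single_anchor(self):
        assert sliding_positions(128, 128, 128, 128) == [(0, 0)]

    def test_two_by_two_grid(self):
        assert sliding_positions(256, 256, 128, 128) == [
            (0, 0), (0, 128), (128, 0), (128, 128)]

    @pytest.mark.parametrize("h,w,step", [(200, 200, 64), (300, 250, 32),
                                          (129, 301, 128)])
    def test_matches_brute_force_with_border_clamp(self, h, w, step):
        got = sliding_positions(h, w, 128, step)
        expected = [(r, c) for r in brute_anchor_axis(h, 128, step)
                    for c in brute_anchor_axis(w, 128, step)]
        assert got == expected

    def test_every_pixel_covered(self):
        h, w, window, step = 200, 310, 128, 48
        cov = np.zeros((h, w), dtype=int)
        for r, c in sliding_positions(h, w, window, step):
            cov[r:r + window, c:c + window] += 1
        assert (cov >= 1).all()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            sliding_positions(100, 100, 128, 32)


class TestPredictionsPerPixel:
    @pytest.mark.parametrize("step,expected", [(128, 1), (64, 4), (32, 16),
                                               (16, 64), (8, 256)])
    def test_interior_coverage_counts(self, step, expected):
        assert predictions_per_pixel(128, step) == expected

    def test_non_divisor_rejected(self):
        with pytest.raises(ParameterError):
            predictions_per_pixel(128, 48)


class TestSegmentSlide:
    def test_constant_model_constant_map(self):
        slide = _slide(200, 260)
        cmap, mask = segment_slide(slide, ConstantModel(0.7), step=64,
                                   threshold=0.5)
        assert np.allclose(cmap.mean_confidence, 0.7)
        assert mask.mask.all()
        _, mask2 = segment_slide(slide, ConstantModel(0.3), step=64,
                                 threshold=0.5)
        assert not mask2.mask.any()

    def test_single_window_slide_broadcasts_one_prediction(self):
        slide = _slide(128, 128)
        model = HashModel()
        conf = float(model.predict(slide.pixels[None])[0])
        cmap, _ = segment_slide(slide, model, step=128)
        assert np.allclose(cmap.mean_confidence, conf)
        assert (cmap.coverage == 1).all()

    def test_matches_brute_force_double_loop(self):
        slide = _slide(300, 300, seed=5)
        model = HashModel()
        cmap, _ = segment_slide(slide, model, step=32)
        expected_mean, expected_cnt = brute_aggregate(slide.pixels, model, 128, 32)
        np.testing.assert_allclose(cmap.mean_confidence, expected_mean,
                                   atol=1e-9)
        np.testing.assert_array_equal(cmap.coverage, expected_cnt)

    def test_coverage_conservation(self):
        slide = _slide(200, 330, seed=2)
        cmap, _ = segment_slide(slide, ConstantModel(0.5), step=64)
        n_anchors = len(sliding_positions(200, 330, 128, 64))
        assert cmap.coverage.sum() == 128 * 128 * n_anchors

    def test_interior_coverage_equals_predictions_per_pixel(self):
        slide = _slide(384, 384)
        cmap, _ = segment_slide(slide, ConstantModel(0.1), step=32)
        assert cmap.coverage[192, 192] == predictions_per_pixel(128, 32)

    def test_step_invariance_for_constant_model(self):
        slide = _slide(256, 256, seed=3)
        maps = [segment_slide(slide, ConstantModel(0.42), step=s)[0]
                for s in (128, 64, 32)]
        for m in maps[1:]:
            np.testing.assert_allclose(m.mean_confidence,
                                       maps[0].mean_confidence, atol=1e-12)

    def test_threshold_monotonicity(self):
        slide = _slide(256, 320, seed=4)
        cmap, _ = segment_slide(slide, HashModel(), step=64)
        prev = binarize(cmap, 0.0).mask
        for t in (0.2, 0.5, 0.8, 1.0):
            cur = binarize(cmap, t).mask
            assert not (cur & ~prev).any()  # raising t never adds pixels
            prev = cur

    def test_untrained_model_rejected(self):
        with pytest.raises(DataError):
            segment_slide(_slide(128, 128), UntrainedModel(), step=128)


class TestRendering:
    def _map(self, value, shape=(4, 6)):
        from tileseg.segmentation import ConfidenceMap
        return ConfidenceMap(np.full(shape, value, dtype=float),
                             np.ones(shape, dtype=int), 128, 128)

    def test_grayscale_endpoints_and_midpoint(self):
        assert (render(self._map(0.0), "grayscale") == 255).all()
        assert (render(self._map(1.0), "grayscale") == 0).all()
        # 0.5 -> 127.5 -> ties-to-even -> 128
        assert (render(self._map(0.5), "grayscale") == 128).all()

    def test_jet_endpoints_blue_to_red(self):
        lo = render(self._map(0.0), "jet")[0, 0]
        hi = render(self._map(1.0), "jet")[0, 0]
        assert lo[2] > lo[0]  # blue end
        assert hi[0] > hi[2]  # red end

    def test_uncovered_pixels_get_sentinel_color(self):
        from tileseg.segmentation import ConfidenceMap, SENTINEL_COLOR
        cmap = ConfidenceMap(np.full((3, 3), -1.0), np.zeros((3, 3), int),
                             128, 128)
        img = render(cmap, "grayscale")
        assert (img == SENTINEL_COLOR).all(axis=2).all()

    def test_unknown_palette_rejected(self):
        with pytest.raises(ParameterError):
            render(self._map(0.5), "viridis")


class TestOverlay:
    def test_empty_mask_leaves_slide_unchanged(self):
        from tileseg.segmentation import SegmentationMask
        slide = _slide(30, 40)
        mask = SegmentationMask(np.zeros((30, 40), bool), 0.5, 32)
        np.testing.assert_array_equal(overlay(slide, mask), slide.pixels)

    def test_full_mask_tints_everything(self):
        from tileseg.segmentation import SegmentationMask
        slide = SlideImage(np.zeros((10, 10, 3), dtype=np.uint8))
        mask = SegmentationMask(np.ones((10, 10), bool), 0.5, 32)
        out = overlay(slide, mask, color=(255, 255, 0), alpha=0.5)
        assert (out == (128, 128, 0)).all(axis=2).all()

    def test_tint_support_equals_mask(self):
        from tileseg.segmentation import SegmentationMask
        slide = _slide(20, 20, seed=1)
        m = np.zeros((20, 20), bool)
        m[5:10, 3:12] = True
        out = overlay(slide, SegmentationMask(m, 0.5, 32))
        changed = (out != slide.pixels).any(axis=2)
        np.testing.assert_array_equal(changed & ~m, np.zeros_like(m))
        assert changed[5:10, 3:12].any()
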