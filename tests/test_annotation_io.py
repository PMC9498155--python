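"""Slide I/O, background masking, downsampling and rasterization."""

import numpy as np
import pytest

from tileseg import (AnnotationSet, Region, SlideImage, downsample,
                     mask_background, rasterize_annotations, read_annotations,
                     write_annotations, read_slide, write_slide)
from tileseg.errors import (AnnotationValidationError, FormatError,
                            ParameterError)

from _oracles import brute_rasterize, make_simple_polygon


def _slide(pixels):
    return SlideImage(np.asarray(pixels, dtype=np.uint8))


def rect(x0, y0, x1, y1):
    """Closed rectangle polygon through the given corner pixel centers."""
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


class TestMaskBackground:
    def test_pure_white_is_all_background(self):
        slide = _slide(np.full((5, 7, 3), 255))
        assert not mask_background(slide).any()

    def test_black_is_all_tissue(self):
        slide = _slide(np.zeros((5, 7, 3)))
        assert mask_background(slide).all()

    def test_rectangle_on_white_matches_per_pixel_rule(self, rng):
        pixels = np.full((40, 60, 3), 255, dtype=np.uint8)
        pixels[10:25, 20:50] = rng.integers(0, 200, (15, 30, 3))
        slide = _slide(pixels)
        threshold = 220
        got = mask_background(slide, threshold)
        expected = np.zeros((40, 60), dtype=bool)
        for r in range(40):
            for c in range(60):
                expected[r, c] = int(pixels[r, c].min()) < threshold
        np.testing.assert_array_equal(got, expected)

    def test_background_plus_tissue_partitions_image(self, rng):
        pixels = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        tissue = mask_background(_slide(pixels))
        assert np.all(tissue | ~tissue)
        assert not np.any(tissue & ~tissue)

    def test_non_rgb_rejected(self):
        with pytest.raises(FormatError):
            SlideImage(np.zeros((5, 5), dtype=np.uint8))


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        slide = _slide(rng.integers(0, 256, (8, 12, 3)))
        out = downsample(slide, 1)
        np.testing.assert_array_equal(out.pixels, slide.pixels)

    def test_constant_block_mean(self):
        slide = _slide(np.full((8, 8, 3), 77))
        out = downsample(slide, 4)
        assert out.pixels.shape == (2, 2, 3)
        assert (out.pixels == 77).all()
        assert out.downsample_factor == 4

    def test_checkerboard_averages_to_midgray(self):
        board = np.zeros((2, 2, 3), dtype=np.uint8)
        board[0, 1] = board[1, 0] = 255
        out = downsample(_slide(board), 2)
        # mean 127.5, ties-to-even rounding -> 128
        assert out.pixels.shape == (1, 1, 3)
        assert (out.pixels == 128).all()

    def test_ceil_dimensions_and_partial_blocks(self):
        pixels = np.zeros((5, 7, 3), dtype=np.uint8)
        pixels[4, :, :] = 200  # last row forms its own partial block
        out = downsample(_slide(pixels), 2)
        assert out.pixels.shape == (3, 4, 3)
        assert (out.pixels[2, 0] == 200).all()

    def test_invalid_factor_rejected(self):
        slide = _slide(np.zeros((4, 4, 3)))
        with pytest.raises(ParameterError):
            downsample(slide, 0)

    @pytest.mark.parametrize("a,b", [(2, 2), (2, 4), (4, 2)])
    def test_composition_dimensions(self, rng, a, b):
        slide = _slide(rng.integers(0, 256, (16, 32, 3)))
        once = downsample(slide, a * b)
        twice = downsample(downsample(slide, a), b)
        assert once.pixels.shape == twice.pixels.shape
        assert once.downsample_factor == twice.downsample_factor


class TestRasterize:
    def test_empty_set_gives_empty_masks(self):
        masks = rasterize_annotations(AnnotationSet(), (10, 10))
        assert not masks.tumor_mask.any() and not masks.normal_mask.any()
        assert not masks.annotated_mask.any()

    def test_rectangle_matches_even_odd_oracle(self):
        region = Region(rect(10, 10, 20, 20), "tumor")
        masks = rasterize_annotations(AnnotationSet([region]), (30, 30))
        expected = brute_rasterize([region.polygon], (30, 30))
        # boundary pixels are included by spec; the crossing-number oracle
        # excludes the top/left boundary, so compare via a half-pixel shrink
        assert masks.tumor_mask[10:21, 10:21].all()
        assert masks.tumor_mask.sum() == 11 * 11
        assert expected.sum() <= masks.tumor_mask.sum()

    def test_random_polygons_match_even_odd_oracle(self, rng):
        for _ in range(8):
            poly = make_simple_polygon(rng, 40)
            region = Region(poly, "tumor")
            masks = rasterize_annotations(AnnotationSet([region]), (40, 40))
            expected = brute_rasterize([poly], (40, 40))
            np.testing.assert_array_equal(masks.tumor_mask, expected)

    def test_disjoint_labels_union(self):
        tumor = Region(rect(1, 1, 5, 5), "tumor")
        normal = Region(rect(10, 10, 14, 14), "normal")
        masks = rasterize_annotations(AnnotationSet([tumor, normal]), (20, 20))
        assert not (masks.tumor_mask & masks.normal_mask).any()
        np.testing.assert_array_equal(
            masks.annotated_mask, masks.tumor_mask | masks.normal_mask)

    def test_overlapping_labels_rejected_with_pairs(self):
        tumor = Region(rect(1, 1, 10, 10), "tumor")
        normal = Region(rect(5, 5, 14, 14), "normal")
        with pytest.raises(AnnotationValidationError) as exc:
            rasterize_annotations(AnnotationSet([tumor, normal]), (20, 20))
        assert exc.value.offending_pairs == [(0, 1)]

    def test_hole_excluded_from_mask(self):
        region = Region(rect(0.5, 0.5, 19.5, 19.5), "tumor",
                        holes=[rect(5.5, 5.5, 10.5, 10.5)])
        masks = rasterize_annotations(AnnotationSet([region]), (21, 21))
        expected = brute_rasterize([region.polygon] + region.holes, (21, 21))
        np.testing.assert_array_equal(masks.tumor_mask, expected)
        assert not masks.tumor_mask[6:11, 6:11].any()

    def test_region_order_irrelevant(self):
        a = Region(rect(1, 1, 5, 5), "tumor")
        b = Region(rect(8, 8, 12, 12), "tumor")
        m1 = rasterize_annotations(AnnotationSet([a, b]), (15, 15))
        m2 = rasterize_annotations(AnnotationSet([b, a]), (15, 15))
        np.testing.assert_array_equal(m1.tumor_mask, m2.tumor_mask)


class TestAnnotationIO:
    def test_roundtrip_identity(self, tmp_path):
        regions = [
            Region(rect(1, 2, 8, 9), "tumor"),
            Region(rect(20, 20, 30, 25), "normal",
                   holes=[rect(22, 21, 24, 23)]),
        ]
        path = tmp_path / "ann.geojson"
        write_annotations(AnnotationSet(regions), path)
        loaded = read_annotations(path)
        assert len(loaded) == 2
        for orig, back in zip(regions, loaded.regions):
            assert back.label == orig.label
            np.testing.assert_allclose(back.polygon, orig.polygon)
            assert len(back.holes) == len(orig.holes)

    def test_case_insensitive_class_names(self, tmp_path):
        path = tmp_path / "ann.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature",'
            '"geometry": {"type": "Polygon", "coordinates":'
            '[[[0,0],[5,0],[5,5],[0,5]]]},'
            '"properties": {"classification": {"name": "TUMOR"}}}]}'
        )
        assert read_annotations(path).regions[0].label == "tumor"

    def test_missing_class_property_rejected(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature",'
            '"geometry": {"type": "Polygon", "coordinates":'
            '[[[0,0],[5,0],[5,5],[0,5]]]}, "properties": {}}]}'
        )
        with pytest.raises(FormatError):
            read_annotations(path)

    def test_unknown_class_rejected(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature",'
            '"geometry": {"type": "Polygon", "coordinates":'
            '[[[0,0],[5,0],[5,5],[0,5]]]},'
            '"properties": {"classification": {"name": "Stroma"}}}]}'
        )
        with pytest.raises(FormatError):
            read_annotations(path)


class TestSlideIO:
    @pytest.mark.parametrize("name", ["slide.png", "slide.tiff"])
    def test_roundtrip(self, tmp_path, rng, name):
        slide = _slide(rng.integers(0, 256, (12, 17, 3)))
        write_slide(slide, tmp_path / name)
        back = read_slide(tmp_path / name)
        np.testing.assert_array_equal(back.pixels, slide.pixels)

    def test_annotation_scaling_for_downsampled_slide(self):
        ann = AnnotationSet([Region(rect(0, 0, 40, 20), "tumor")])
        scaled = ann.scaled(4)
        np.testing.assert_allclose(scaled.regions[0].polygon,
                                   rect(0, 0, 10, 5))
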