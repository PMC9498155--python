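"""Shared fixtures and mock models for the tileseg test suite."""

import numpy as np
import pytest

from tileseg import (PatchDataset, SyntheticSlideSpec, balance_classes,
                     extract_patches, generate_cohort, rasterize_annotations)


class ConstantModel:
    """Mock classifier returning the same confidence for every tile."""

    is_trained = True

    def __init__(self, confidence: float):
        self.confidence = confidence

    def predict(self, tiles):
        tiles = np.asarray(tiles)
        n = 1 if tiles.ndim == 3 else tiles.shape[0]
        return np.full(n, self.confidence, dtype=np.float64)


class HashModel:
    """Mock classifier: deterministic pseudo-random confidence per tile content."""

    is_trained = True

    def predict(self, tiles):
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        sums = tiles.reshape(tiles.shape[0], -1).astype(np.float64).sum(axis=1)
        return (sums * 0.6180339887498949) % 1.0


class UntrainedModel:
    is_trained = False

    def predict(self, tiles):  # pragma: no cover - never reached
        raise AssertionError("predict called on untrained mock")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mini_world():
    """Six small two-class slides with rasterized masks and 32 px patches.

    Desk-scale fixture shared by training and pipeline tests: slides are
    256 x 320 px with two tumor and two normal rectangles each, patches cut
    on a disjoint 32 px grid.
    """
    spec = SyntheticSlideSpec(height=256, width=320, n_tumor_regions=2,
                              n_normal_regions=2, region_size_range=(64, 96))
    cohort = generate_cohort(6, spec, master_seed=5)
    slides, masks, dataset = [], [], PatchDataset()
    for slide, annotations in cohort:
        gt = rasterize_annotations(annotations, (slide.height, slide.width))
        slides.append(slide)
        masks.append(gt)
        dataset = dataset.merged_with(
            extract_patches(slide, gt, tile_size=32, stride=32))
    dataset = balance_classes(dataset, seed=0)
    return {"slides": slides, "masks": masks, "patches": dataset}
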