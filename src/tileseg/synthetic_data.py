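"""Synthetic annotated slides with two texturally distinct tissue classes.

The method was developed on a private collection of H&E-stained bright-field
breast-tissue scans, so nothing in this package can ship real data. This
module generates a stand-in that preserves the properties the pipeline
actually exercises: large 8-bit RGB images on a pure-white background,
non-overlapping labeled regions of two classes whose textures differ in
second-order statistics at the 128 x 128 tile scale, and annotation polygons
that exactly bound the generated regions.

The texture model is deliberately simple: each region is a cytoplasm-colored
field with additive Gaussian color jitter, scattered with disc "nuclei" of
random radius. Tumor regions emulate hypercellularity — denser, larger,
darker nuclei — which is the dominant visual cue a pathologist uses at this
scale. The generator makes no attempt at photorealism (no stain variation,
no stroma, no gland architecture), so a classifier that aces these slides
has only been shown to learn separable local texture, not breast histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk

from .annotation_io import AnnotationSet, Region, SlideImage, TUMOR, NORMAL
from .errors import DataError, ParameterError

BACKGROUND_COLOR = (255, 255, 255)


@dataclass
class ClassTexture:
    """Texture parameters of one tissue class."""

    nucleus_density: float          # nuclei per 1000 px^2
    nucleus_radius: tuple[int, int]  # min/max radius in px
    nucleus_color: tuple[int, int, int]
    cytoplasm_color: tuple[int, int, int]
    jitter_sd: float = 8.0          # additive Gaussian color noise, 8-bit units


#: hypercellular class: dense, large, dark basophilic nuclei
TUMOR_TEXTURE = ClassTexture(
    nucleus_density=12.0, nucleus_radius=(3, 6),
    nucleus_color=(70, 40, 110), cytoplasm_color=(185, 130, 170),
)
#: sparse small nuclei on an eosinophilic field
NORMAL_TEXTURE = ClassTexture(
    nucleus_density=3.0, nucleus_radius=(2, 4),
    nucleus_color=(130, 90, 160), cytoplasm_color=(235, 190, 205),
)


@dataclass
class SyntheticSlideSpec:
    """World description for one synthetic slide.

    The default canvas (1024 x 1536) is a desk-scale stand-in for real
    whole-slide scans (~29,000 x 17,000 px); region sizes default to a range
    that holds a handful of disjoint 128 px tiles each.
    """

    height: int = 1024
    width: int = 1536
    n_tumor_regions: int = 3
    n_normal_regions: int = 3
    region_size_range: tuple[int, int] = (160, 320)
    tumor_texture: ClassTexture = field(default_factory=lambda: replace(TUMOR_TEXTURE))
    normal_texture: ClassTexture = field(default_factory=lambda: replace(NORMAL_TEXTURE))
    seed: int = 0
    margin: int = 8                 # minimum gap between regions and to borders

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("slide dimensions must be positive")
        if self.n_tumor_regions < 0 or self.n_normal_regions < 0:
            raise ParameterError("region counts must be nonnegative")
        lo, hi = self.region_size_range
        if lo < 1 or hi < lo:
            raise ParameterError("invalid region_size_range")


def _fill_texture(pixels: np.ndarray, r0: int, r1: int, c0: int, c1: int,
                  tex: ClassTexture, rng: np.random.Generator) -> None:
    h, w = r1 - r0, c1 - c0
    block = np.empty((h, w, 3), dtype=np.float64)
    block[:] = tex.cytoplasm_color
    block += rng.normal(0.0, tex.jitter_sd, size=block.shape)
    n_nuclei = rng.poisson(tex.nucleus_density * h * w / 1000.0)
    for _ in range(n_nuclei):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius = rng.uniform(tex.nucleus_radius[0], tex.nucleus_radius[1])
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        color = np.asarray(tex.nucleus_color, dtype=float) + rng.normal(0.0, 5.0, 3)
        block[rr, cc] = color
    pixels[r0:r1, c0:c1] = np.clip(np.rint(block), 0, 255).astype(np.uint8)


def _place_regions(spec: SyntheticSlideSpec, rng: np.random.Generator,
                   max_attempts: int = 500):
    """Non-overlapping axis-aligned rectangles [r0, r1) x [c0, c1) with labels."""
    placed: list[tuple[int, int, int, int, str]] = []
    wanted = [TUMOR] * spec.n_tumor_regions + [NORMAL] * spec.n_normal_regions
    lo, hi = spec.region_size_range
    m = spec.margin
    for label in wanted:
        for _attempt in range(max_attempts):
            rh = int(rng.integers(lo, hi + 1))
            rw = int(rng.integers(lo, hi + 1))
            if spec.height - rh - 2 * m <= 0 or spec.width - rw - 2 * m <= 0:
                continue
            r0 = int(rng.integers(m, spec.height - rh - m + 1))
            c0 = int(rng.integers(m, spec.width - rw - m + 1))
            r1, c1 = r0 + rh, c0 + rw
            clash = any(
                r0 - m < pr1 and pr0 < r1 + m and c0 - m < pc1 and pc0 < c1 + m
                for pr0, pr1, pc0, pc1, _ in placed
            )
            if not clash:
                placed.append((r0, r1, c0, c1, label))
                break
        else:
            raise DataError(
                f"could not place a {label} region without overlap after "
                f"{max_attempts} attempts; shrink regions or enlarge the canvas"
            )
    return placed


def generate_slide(spec: SyntheticSlideSpec,
                   slide_id: str | None = None) -> tuple[SlideImage, AnnotationSet]:
    """Render one synthetic slide and its exact annotations, seed-deterministic.

    Annotation polygons pass through the corner pixel centers of each region,
    so pixel-center rasterization reproduces the painted rectangle exactly.
    """
    rng = np.random.default_rng(spec.seed)
    pixels = np.full((spec.height, spec.width, 3), BACKGROUND_COLOR, dtype=np.uint8)
    regions = []
    for r0, r1, c0, c1, label in _place_regions(spec, rng):
        tex = spec.tumor_texture if label == TUMOR else spec.normal_texture
        _fill_texture(pixels, r0, r1, c0, c1, tex, rng)
        polygon = np.array([
            [c0, r0], [c1 - 1, r0], [c1 - 1, r1 - 1], [c0, r1 - 1],
        ], dtype=float)
        regions.append(Region(polygon=polygon, label=label))
    slide = SlideImage(pixels, downsample_factor=1, slide_id=slide_id)
    return slide, AnnotationSet(regions=regions)


def generate_cohort(n_slides: int, spec: SyntheticSlideSpec | None = None,
                    master_seed: int = 0):
    """Generate ``n_slides`` reproducible slides with per-slide derived seeds.

    Returns a list of ``(SlideImage, AnnotationSet)``; slide ids are
    ``slide_000``, ``slide_001``, ... Layout and jitter vary per slide.
    """
    if n_slides < 1:
        raise ParameterError("n_slides must be positive")
    template = spec or SyntheticSlideSpec()
    seed_rng = np.random.default_rng(master_seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=n_slides)
    cohort = []
    for i, child in enumerate(child_seeds):
        slide_spec = replace(template, seed=int(child))
        cohort.append(generate_slide(slide_spec, slide_id=f"slide_{i:03d}"))
    return cohort
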