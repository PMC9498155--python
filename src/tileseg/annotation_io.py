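"""Slide and annotation I/O, background masking, rasterization, downsampling.

Whole-slide scans arrive as flat 8-bit RGB rasters (TIFF/PNG) accompanied by
area-based expert annotations: polygons marking regions that are *surely*
tumor or *surely* normal, with everything ambiguous left unannotated.
Annotations travel as GeoJSON FeatureCollections in the QuPath export dialect
(each Feature carries ``properties.classification.name``).

Conventions used throughout the package:

* arrays are indexed ``(row, col)`` = ``(y, x)``, 0-based, half-open ranges;
* annotation vertices are stored in ``(x, y)`` order as GeoJSON dictates and
  kept at native resolution — they are scaled by ``1/factor`` when paired
  with a downsampled slide;
* a pixel belongs to a polygon iff its center ``(x=col, y=row)`` lies inside
  or on the boundary (even-odd rule; interior rings are holes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import AnnotationValidationError, FormatError, ParameterError

TUMOR = "tumor"
NORMAL = "normal"
LABELS = (TUMOR, NORMAL)

#: default whiteness threshold for background masking (8-bit intensity)
DEFAULT_WHITENESS_THRESHOLD = 220


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SlideImage:
    """An 8-bit RGB slide raster with resolution metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
    downsample_factor : int
        Reduction relative to the native scan (1 = native).
    pixel_size : float, optional
        Micrometers per pixel at this resolution.
    slide_id : str, optional
        Provenance identifier carried into extracted patches.
    """

    pixels: np.ndarray
    downsample_factor: int = 1
    pixel_size: float | None = None
    slide_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"slide must be H x W x 3 RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"slide must be 8-bit, got dtype {self.pixels.dtype}")
        if self.height < 1 or self.width < 1:
            raise FormatError("slide must have positive dimensions")
        if self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Region:
    """One labeled polygon in slide pixel coordinates.

    ``polygon`` is the exterior ring as an (N, 2) array of (x, y) vertices;
    ``holes`` are optional interior rings excluded from the region.
    """

    polygon: np.ndarray
    label: str
    holes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise AnnotationValidationError(
                "polygon must be an (N>=3, 2) array of (x, y) vertices"
            )
        if self.label not in LABELS:
            raise AnnotationValidationError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )
        self.holes = [np.asarray(h, dtype=float) for h in self.holes]

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.polygon, [h for h in self.holes])


@dataclass
class AnnotationSet:
    """Area-based annotations for one slide: disjoint tumor/normal polygons."""

    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def validate_disjoint(self) -> None:
        """Raise if any tumor polygon's interior overlaps any normal polygon's."""
        tumor = [(i, r.to_shapely()) for i, r in enumerate(self.regions) if r.label == TUMOR]
        normal = [(i, r.to_shapely()) for i, r in enumerate(self.regions) if r.label == NORMAL]
        offending = []
        for i, pt in tumor:
            for j, pn in normal:
                if pt.intersection(pn).area > 0:
                    offending.append((i, j))
        if offending:
            raise AnnotationValidationError(
                f"tumor/normal regions overlap: region pairs {offending}",
                offending_pairs=offending,
            )

    def scaled(self, factor: float) -> "AnnotationSet":
        """Annotations divided by ``factor``, for pairing with a downsampled slide."""
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        return AnnotationSet(
            regions=[
                Region(r.polygon / factor, r.label, [h / factor for h in r.holes])
                for r in self.regions
            ]
        )


@dataclass
class LabelMasks:
    """Rasterized ground truth: per-label boolean masks plus a tissue mask."""

    tumor_mask: np.ndarray
    normal_mask: np.ndarray
    tissue_mask: np.ndarray | None = None

    @property
    def annotated_mask(self) -> np.ndarray:
        return self.tumor_mask | self.normal_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.tumor_mask.shape

    def mask_for(self, label: str) -> np.ndarray:
        if label == TUMOR:
            return self.tumor_mask
        if label == NORMAL:
            return self.normal_mask
        raise ParameterError(f"unknown label {label!r}")


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def read_slide(path, downsample_factor: int = 1, pixel_size: float | None = None,
               slide_id: str | None = None) -> SlideImage:
    """Read a TIFF/PNG slide raster into a :class:`SlideImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    pixels = np.ascontiguousarray(pixels)
    if pixels.ndim == 2:
        raise FormatError(f"{path}: expected RGB, got a single-channel image")
    if slide_id is None:
        slide_id = path.stem
    return SlideImage(pixels.astype(np.uint8, copy=False), downsample_factor,
                      pixel_size, slide_id)


def write_slide(slide: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.pixels, photometric="rgb")
    else:
        Image.fromarray(slide.pixels).save(path)


def write_mask(mask: np.ndarray, path) -> None:
    """Persist a boolean mask as an 8-bit 0/255 PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


# ---------------------------------------------------------------------------
# background masking
# ---------------------------------------------------------------------------

def mask_background(slide: SlideImage,
                    whiteness_threshold: int = DEFAULT_WHITENESS_THRESHOLD) -> np.ndarray:
    """Tissue mask: a pixel is background iff ``min(R, G, B) >= threshold``.

    Bright-field scans have a near-white glass background; requiring all three
    channels to be bright is robust to faint single-channel tints. Returns the
    *tissue* (non-background) mask, so ``background = ~mask``.
    """
    if not 0 <= whiteness_threshold <= 255:
        raise ParameterError("whiteness_threshold must be in [0, 255]")
    return slide.pixels.min(axis=2) < whiteness_threshold


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample(slide: SlideImage, factor: int) -> SlideImage:
    """Area-average downsampling by an integer factor.

    Output dimensions are ``ceil(input / factor)``; each output pixel is the
    mean of its (possibly partial, at the bottom/right edge) source block,
    rounded to the nearest integer with ties to even.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return SlideImage(slide.pixels.copy(), slide.downsample_factor,
                          slide.pixel_size, slide.slide_id)
    h, w = slide.height, slide.width
    ri = np.arange(0, h, factor)
    ci = np.arange(0, w, factor)
    acc = np.add.reduceat(slide.pixels.astype(np.float64), ri, axis=0)
    acc = np.add.reduceat(acc, ci, axis=1)
    rcount = np.diff(np.append(ri, h))
    ccount = np.diff(np.append(ci, w))
    counts = rcount[:, None] * ccount[None, :]
    mean = acc / counts[:, :, None]
    out = np.rint(mean).astype(np.uint8)
    pixel_size = None if slide.pixel_size is None else slide.pixel_size * factor
    return SlideImage(out, slide.downsample_factor * factor, pixel_size, slide.slide_id)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _rasterize_polygon(poly: _ShapelyPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers intersect the polygon (boundary in)."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, w)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, h)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(rows.shape)
    return mask


def rasterize_annotations(annotations: AnnotationSet, shape: tuple[int, int],
                          tissue_mask: np.ndarray | None = None) -> LabelMasks:
    """Rasterize labeled polygons to per-label boolean masks.

    Pixel-center inclusion with boundary pixels included; holes (interior
    rings) are excluded. Raises :class:`AnnotationValidationError` if tumor
    and normal regions overlap, listing the offending region index pairs.
    """
    annotations.validate_disjoint()
    h, w = shape
    masks = {lab: np.zeros((h, w), dtype=bool) for lab in LABELS}
    for region in annotations.regions:
        masks[region.label] |= _rasterize_polygon(region.to_shapely(), (h, w))
    overlap = masks[TUMOR] & masks[NORMAL]
    if overlap.any():
        raise AnnotationValidationError(
            "tumor and normal rasterized masks overlap at "
            f"{int(overlap.sum())} pixels"
        )
    return LabelMasks(tumor_mask=masks[TUMOR], normal_mask=masks[NORMAL],
                      tissue_mask=tissue_mask)


# ---------------------------------------------------------------------------
# GeoJSON annotation I/O (QuPath export dialect)
# ---------------------------------------------------------------------------

def _label_from_classification(name: str) -> str:
    lowered = str(name).strip().lower()
    if lowered in LABELS:
        return lowered
    raise FormatError(
        f"unknown annotation class {name!r}; expected Tumor or Normal"
    )


def read_annotations(path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of labeled polygons.

    Each Feature must be a Polygon with ``properties.classification.name``
    equal to Tumor or Normal (case-insensitive). The first ring is the
    exterior; further rings are holes.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        classification = props.get("classification")
        if not classification or "name" not in classification:
            raise FormatError(
                f"{path}: feature missing properties.classification.name"
            )
        label = _label_from_classification(classification["name"])
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(
                f"{path}: unsupported geometry type {geom.get('type')!r}"
            )
        rings = geom["coordinates"]
        regions.append(Region(polygon=np.asarray(rings[0], dtype=float),
                              label=label,
                              holes=[np.asarray(r, dtype=float) for r in rings[1:]]))
    return AnnotationSet(regions=regions)


def write_annotations(annotations: AnnotationSet, path) -> None:
    features = []
    for region in annotations.regions:
        rings = [region.polygon.tolist()] + [h.tolist() for h in region.holes]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": rings},
            "properties": {
                "classification": {"name": region.label.capitalize()},
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
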