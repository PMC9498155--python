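"""Whole-slide segmentation: sliding window, per-pixel averaging, rendering.

A trained tile classifier only sees 128 x 128 windows; the slide-level
segmentation slides that window across the image on a stride grid, evaluates
every placement, and averages the tumor confidences of all windows covering
each pixel. Smaller steps give more overlapping predictions per pixel —
(window/step)^2 for interior pixels — at quadratically growing cost. The
averaged map is binarized at a threshold (chosen on validation data by the
optimization module) and can be rendered as a grayscale or jet heatmap or as
an overlay on the original slide.

Border policy: anchors sit at multiples of ``step``; when the last multiple
does not reach the image border an extra anchor flush with the border is
appended per axis, so every pixel is covered at least once (border pixels
simply average over fewer windows). Pixels never covered (impossible with
this policy, but maps can be cropped) carry the sentinel value -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .annotation_io import SlideImage
from .errors import DataError, ParameterError

DEFAULT_WINDOW = 128
STEP_SIZES = (128, 64, 32, 16, 8)
UNCOVERED = -1.0
#: color for pixels with no covering window in rendered maps
SENTINEL_COLOR = (255, 0, 255)


@dataclass
class ConfidenceMap:
    """Per-pixel mean tumor confidence plus window coverage counts."""

    mean_confidence: np.ndarray   # H x W float, in [0,1] where covered, else -1
    coverage: np.ndarray          # H x W int, number of covering windows
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_WINDOW

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0


@dataclass
class SegmentationMask:
    """Binary tumor mask (1 = tumor) with the parameters that produced it."""

    mask: np.ndarray
    threshold: float
    step: int


def sliding_positions(height: int, width: int, window: int = DEFAULT_WINDOW,
                      step: int = DEFAULT_WINDOW) -> list[tuple[int, int]]:
    """Ordered (row, col) top-left anchors of the sliding window.

    Anchors lie at multiples of ``step``; one extra flush-to-border anchor is
    appended per axis when needed so the union of footprints covers the whole
    image.
    """
    if window > height or window > width:
        raise ParameterError(
            f"window {window} exceeds image dimensions ({height}, {width})"
        )
    if not 1 <= step <= window:
        raise ParameterError("step must satisfy 1 <= step <= window")

    def axis_anchors(extent: int) -> list[int]:
        anchors = list(range(0, extent - window + 1, step))
        if anchors[-1] != extent - window:
            anchors.append(extent - window)
        return anchors

    return [(r, c) for r in axis_anchors(height) for c in axis_anchors(width)]


def predictions_per_pixel(window: int = DEFAULT_WINDOW, step: int = 32) -> int:
    """Number of stride-grid window placements covering a fixed interior pixel.

    Counted by enumeration: on an unbounded stride grid, the anchors whose
    footprint contains a pixel far from every border are those within one
    window length before it, per axis. Requires ``step`` to divide ``window``;
    the count is then (window/step)^2 (1 at step 128, 4 at 64, 16 at 32,
    64 at 16, 256 at 8 for the default window).
    """
    if window % step != 0:
        raise ParameterError("step must divide window")
    # pixel placed far from borders on a long axis; count covering anchors
    pixel = 10 * window
    along_axis = sum(
        1 for a in range(0, pixel + window, step) if a <= pixel < a + window
    )
    return along_axis ** 2


def segment_slide(slide: SlideImage, model, step: int = 32,
                  threshold: float = 0.5, window: int = DEFAULT_WINDOW,
                  batch_size: int = 64) -> tuple[ConfidenceMap, SegmentationMask]:
    """Slide the classifier over the image and average per-pixel confidences.

    ``mean_confidence[p]`` is the arithmetic mean of the confidences of every
    window whose footprint contains ``p``; the mask is ``mean >= threshold``
    restricted to covered pixels (ties binarize to tumor).
    """
    if not getattr(model, "is_trained", True):
        raise DataError("model is untrained; train or load weights first")
    positions = sliding_positions(slide.height, slide.width, window, step)
    acc = np.zeros((slide.height, slide.width), dtype=np.float64)
    count = np.zeros((slide.height, slide.width), dtype=np.int64)
    for start in range(0, len(positions), batch_size):
        chunk = positions[start:start + batch_size]
        tiles = np.stack([
            slide.pixels[r:r + window, c:c + window] for r, c in chunk
        ])
        confs = np.atleast_1d(model.predict(tiles))
        for (r, c), conf in zip(chunk, confs):
            acc[r:r + window, c:c + window] += conf
            count[r:r + window, c:c + window] += 1
    covered = count > 0
    mean = np.full((slide.height, slide.width), UNCOVERED, dtype=np.float64)
    mean[covered] = acc[covered] / count[covered]
    cmap = ConfidenceMap(mean_confidence=mean, coverage=count,
                         window=window, step=step)
    mask = binarize(cmap, threshold)
    return cmap, mask


def binarize(cmap: ConfidenceMap, threshold: float) -> SegmentationMask:
    """Tumor mask: mean confidence >= threshold, on covered pixels only."""
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must be in [0, 1]")
    mask = (cmap.mean_confidence >= threshold) & cmap.covered
    return SegmentationMask(mask=mask, threshold=threshold, step=cmap.step)


def render(cmap: ConfidenceMap, palette: str = "grayscale") -> np.ndarray:
    """Render a confidence map to an RGB image.

    grayscale maps confidence 0 -> white and 1 -> black, linearly (rounding
    ties to even); jet runs blue (0) to red (1). Uncovered pixels get the
    magenta sentinel color.
    """
    c = np.clip(cmap.mean_confidence, 0.0, 1.0)
    if palette == "grayscale":
        gray = np.rint((1.0 - c) * 255.0).astype(np.uint8)
        rgb = np.repeat(gray[:, :, None], 3, axis=2)
    elif palette == "jet":
        rgb = np.rint(colormaps["jet"](c)[:, :, :3] * 255.0).astype(np.uint8)
    else:
        raise ParameterError(f"unknown palette {palette!r}")
    rgb[~cmap.covered] = SENTINEL_COLOR
    return rgb


def overlay(slide: SlideImage, mask: SegmentationMask,
            color: tuple[int, int, int] = (255, 255, 0),
            alpha: float = 0.5) -> np.ndarray:
    """Tint tumor pixels on the original slide; non-tumor pixels untouched."""
    if mask.mask.shape != (slide.height, slide.width):
        raise DataError("mask shape does not match slide")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be in (0, 1]")
    out = slide.pixels.astype(np.float64).copy()
    tint = np.asarray(color, dtype=np.float64)
    out[mask.mask] = (1 - alpha) * out[mask.mask] + alpha * tint
    return np.rint(out).astype(np.uint8)
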