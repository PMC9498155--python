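"""Tile extraction, class balancing and slide-level dataset splitting.

Training examples are small square tiles (default 128 x 128 px) cut from the
annotated regions only: a tile is emitted iff its *entire* footprint lies
inside a single-label mask, because area-based annotations mark regions that
are surely tumor or surely normal — a tile straddling a region boundary would
dilute that certainty. With stride = tile size the extracted footprints are
pairwise disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotation_io import LabelMasks, SlideImage, TUMOR, NORMAL
from .errors import DataError, ParameterError

LABEL_CODES = {NORMAL: 0, TUMOR: 1}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

DEFAULT_TILE_SIZE = 128
SPLIT_FRACTIONS = (0.70, 0.10, 0.20)
SPLIT_TAGS = ("train", "validation", "test")


@dataclass
class Patch:
    """One labeled tile with provenance back to its slide."""

    tile: np.ndarray              # tile_size x tile_size x 3, uint8
    origin: tuple[int, int]       # (row, col) of the top-left corner
    label: int                    # 0 = normal, 1 = tumor
    slide_id: str | None = None
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.tile)
        if t.ndim != 3 or t.shape[0] != t.shape[1] or t.shape[2] != 3:
            raise ParameterError(f"tile must be S x S x 3, got {t.shape}")
        if self.label not in (0, 1):
            raise ParameterError("label must be 0 (normal) or 1 (tumor)")


@dataclass
class PatchDataset:
    """A collection of labeled patches, optionally tagged with its split."""

    patches: list[Patch] = field(default_factory=list)
    split_tag: str | None = None

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patches], dtype=int)

    @property
    def tiles(self) -> np.ndarray:
        if not self.patches:
            return np.zeros((0, DEFAULT_TILE_SIZE, DEFAULT_TILE_SIZE, 3), dtype=np.uint8)
        return np.stack([p.tile for p in self.patches])

    def label_counts(self) -> dict[str, int]:
        labels = self.labels
        return {NORMAL: int((labels == 0).sum()), TUMOR: int((labels == 1).sum())}

    def subset(self, indices) -> "PatchDataset":
        return PatchDataset([self.patches[i] for i in indices], self.split_tag)

    def merged_with(self, other: "PatchDataset") -> "PatchDataset":
        return PatchDataset(self.patches + other.patches, self.split_tag)


def extract_patches(slide: SlideImage, masks: LabelMasks,
                    tile_size: int = DEFAULT_TILE_SIZE,
                    stride: int | None = None) -> PatchDataset:
    """Cut labeled tiles from the annotated regions of one slide.

    The tile grid is anchored at (0, 0). A tile at ``(i*stride, j*stride)``
    is emitted with a label iff every pixel of its footprint lies inside that
    label's mask. A tile size larger than the image yields an empty dataset.
    """
    if stride is None:
        stride = tile_size
    if tile_size < 1 or stride < 1:
        raise ParameterError("tile_size and stride must be positive")
    if masks.shape != (slide.height, slide.width):
        raise DataError(
            f"mask shape {masks.shape} != slide shape {(slide.height, slide.width)}"
        )
    patches: list[Patch] = []
    if tile_size > slide.height or tile_size > slide.width:
        return PatchDataset(patches)

    rows = np.arange(0, slide.height - tile_size + 1, stride)
    cols = np.arange(0, slide.width - tile_size + 1, stride)
    full = tile_size * tile_size
    for label_name, code in ((TUMOR, 1), (NORMAL, 0)):
        mask = masks.mask_for(label_name)
        # summed-area table: footprint is fully inside iff its sum == tile_size^2
        sat = np.zeros((slide.height + 1, slide.width + 1), dtype=np.int64)
        np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
        for r in rows:
            for c in cols:
                s = (sat[r + tile_size, c + tile_size] - sat[r, c + tile_size]
                     - sat[r + tile_size, c] + sat[r, c])
                if s == full:
                    patches.append(Patch(
                        tile=slide.pixels[r:r + tile_size, c:c + tile_size].copy(),
                        origin=(int(r), int(c)),
                        label=code,
                        slide_id=slide.slide_id,
                        downsample_factor=slide.downsample_factor,
                    ))
    return PatchDataset(patches)


def balance_classes(dataset: PatchDataset, seed: int) -> PatchDataset:
    """Equalize class counts by uniform undersampling of the majority class.

    Deterministic given ``seed``; patch order within the dataset is preserved.
    """
    labels = dataset.labels
    n_normal = int((labels == 0).sum())
    n_tumor = int((labels == 1).sum())
    if n_normal == 0 or n_tumor == 0:
        empty = NORMAL if n_normal == 0 else TUMOR
        raise DataError(f"cannot balance: class {empty!r} is empty")
    if n_normal == n_tumor:
        return PatchDataset(list(dataset.patches), dataset.split_tag)
    minority = min(n_normal, n_tumor)
    majority_code = 0 if n_normal > n_tumor else 1
    rng = np.random.default_rng(seed)
    majority_idx = np.flatnonzero(labels == majority_code)
    keep_major = np.sort(rng.choice(majority_idx, size=minority, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(labels != majority_code), keep_major]))
    return dataset.subset(keep.tolist())


def split_dataset(slide_ids, fractions=SPLIT_FRACTIONS, seed: int = 0):
    """Partition slide ids into train/validation/test lists, BY SLIDE.

    All patches of a slide share a split so no tissue leaks across splits.
    Validation and test sizes are the fractions rounded to the nearest
    integer; training takes the remainder. Deterministic given ``seed``.
    """
    slide_ids = list(slide_ids)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("fractions must be three numbers summing to 1")
    n = len(slide_ids)
    if n == 0:
        raise DataError("no slide ids to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train <= 0 or (n_val == 0 and n_test == 0):
        warnings.warn(
            f"degenerate split for {n} slide(s): all assigned to training",
            stacklevel=2,
        )
        if n_train <= 0:
            return slide_ids, [], []
    shuffled = [slide_ids[i] for i in order]
    train = sorted(shuffled[:n_train])
    val = sorted(shuffled[n_train:n_train + n_val])
    test = sorted(shuffled[n_train + n_val:])
    return train, val, test


# ---------------------------------------------------------------------------
# persistence: directory of PNG tiles + CSV manifest
# ---------------------------------------------------------------------------

def save_dataset(dataset: PatchDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, p in enumerate(dataset.patches):
        fname = f"patch_{i:06d}.png"
        Image.fromarray(p.tile).save(directory / fname)
        records.append({
            "file": fname,
            "slide_id": p.slide_id,
            "row": p.origin[0],
            "col": p.origin[1],
            "label": p.label,
            "factor": p.downsample_factor,
        })
    manifest = pd.DataFrame.from_records(
        records, columns=["file", "slide_id", "row", "col", "label", "factor"]
    )
    manifest.to_csv(directory / "manifest.csv", index=False)


def load_dataset(directory, split_tag: str | None = None) -> PatchDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    patches = []
    for rec in manifest.itertuples():
        tile = np.asarray(Image.open(directory / rec.file).convert("RGB"))
        slide_id = None if pd.isna(rec.slide_id) else str(rec.slide_id)
        patches.append(Patch(tile=tile, origin=(int(rec.row), int(rec.col)),
                             label=int(rec.label), slide_id=slide_id,
                             downsample_factor=int(rec.factor)))
    return PatchDataset(patches, split_tag)
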