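"""Pipeline configuration and staged end-to-end orchestration.

The pipeline mirrors the study workflow: generate or ingest slides ->
extract labeled tiles at one or more downsampling factors -> train the
compact CNN -> sweep the binarization threshold on validation patches ->
segment the test slides -> report kernel- and pixel-level metrics. Each
stage is idempotent: it writes its artifacts plus a provenance file carrying
a hash of the configuration, is skipped when that provenance already matches,
and refuses to mix artifacts produced under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io as aio
from . import patching
from .classifier import (ClassifierConfig, build_classifier, load_model,
                         predict_patches, save_model, train_classifier)
from .errors import ConfigError, DataError
from .evaluation import kernel_metrics, macro_average, pixel_metrics
from .optimization import threshold_sweep
from .segmentation import overlay, render, segment_slide
from .synthetic_data import SyntheticSlideSpec, generate_cohort

logger = logging.getLogger("tileseg")

STAGES = ("synth", "extract", "train", "sweep", "segment", "evaluate")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    workspace: str = "tileseg_workspace"
    n_slides: int = 10
    slide_height: int = 1024
    slide_width: int = 1536
    n_tumor_regions: int = 3
    n_normal_regions: int = 3
    region_size_range: tuple[int, int] = (160, 320)
    tile_size: int = 128
    stride: int = 128
    downsample_factors: tuple[int, ...] = (4, 6, 8)
    segment_factor: int | None = None      # default: first downsample factor
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    sweep_grid_step: float = 0.01
    step_sizes: tuple[int, ...] = (128, 64, 32, 16, 8)
    segment_step: int = 32
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed_synth: int = 11
    seed_split: int = 12
    seed_balance: int = 13
    seed_init: int = 14
    seed_train: int = 15

    def __post_init__(self) -> None:
        if self.stride > self.tile_size:
            raise ConfigError("stride must not exceed tile_size")
        if self.tile_size < 1 or self.stride < 1:
            raise ConfigError("tile_size and stride must be positive")
        if self.n_slides < 1:
            raise ConfigError("n_slides must be positive")
        if any(f < 1 for f in self.downsample_factors):
            raise ConfigError("downsample factors must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")
        if not 0 < self.sweep_grid_step <= 1:
            raise ConfigError("sweep_grid_step must be in (0, 1]")
        if any(s < 1 or s > self.tile_size for s in self.step_sizes):
            raise ConfigError("step sizes must be in [1, tile_size]")
        if self.segment_step not in self.step_sizes:
            raise ConfigError("segment_step must be one of step_sizes")
        if self.classifier.tile_size != self.tile_size:
            self.classifier = replace(self.classifier, tile_size=self.tile_size)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "classifier" in kwargs and isinstance(kwargs["classifier"], dict):
            cl = kwargs["classifier"]
            unknown_cl = set(cl) - set(ClassifierConfig.__dataclass_fields__)
            if unknown_cl:
                raise ConfigError(f"unknown classifier keys: {sorted(unknown_cl)}")
            try:
                kwargs["classifier"] = ClassifierConfig(**cl)
            except Exception as exc:
                raise ConfigError(str(exc)) from exc
        for key in ("region_size_range", "downsample_factors", "split_fractions",
                    "step_sizes"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(canon.encode()).hexdigest()[:16]

    @property
    def effective_segment_factor(self) -> int:
        return self.segment_factor or self.downsample_factors[0]


# ---------------------------------------------------------------------------
# provenance helpers
# ---------------------------------------------------------------------------

def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    return Path(cfg.workspace) / stage


def _provenance(cfg: PipelineConfig, stage: str) -> Path:
    return _stage_dir(cfg, stage) / "provenance.json"


def _stage_done(cfg: PipelineConfig, stage: str) -> bool:
    prov = _provenance(cfg, stage)
    if not prov.exists():
        return False
    with open(prov) as fh:
        recorded = json.load(fh).get("config_hash")
    if recorded != cfg.config_hash():
        raise ConfigError(
            f"stage {stage!r} artifacts were produced under a different "
            f"configuration (hash {recorded} != {cfg.config_hash()}); "
            "clear the workspace or restore the original config"
        )
    return True


def _mark_done(cfg: PipelineConfig, stage: str) -> None:
    with open(_provenance(cfg, stage), "w") as fh:
        json.dump({"config_hash": cfg.config_hash(), "stage": stage}, fh)


def _require(cfg: PipelineConfig, stage: str) -> None:
    if not _stage_done(cfg, stage):
        raise DataError(f"missing artifacts from stage {stage!r}; rerun it first")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: PipelineConfig) -> None:
    out = _stage_dir(cfg, "synth")
    out.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSlideSpec(
        height=cfg.slide_height, width=cfg.slide_width,
        n_tumor_regions=cfg.n_tumor_regions,
        n_normal_regions=cfg.n_normal_regions,
        region_size_range=cfg.region_size_range,
    )
    for slide, annotations in generate_cohort(cfg.n_slides, spec, cfg.seed_synth):
        aio.write_slide(slide, out / f"{slide.slide_id}.png")
        aio.write_annotations(annotations, out / f"{slide.slide_id}.geojson")
    _mark_done(cfg, "synth")


def _slide_ids(cfg: PipelineConfig) -> list[str]:
    return [f"slide_{i:03d}" for i in range(cfg.n_slides)]


def _load_slide(cfg: PipelineConfig, slide_id: str, factor: int):
    src = _stage_dir(cfg, "synth")
    slide = aio.read_slide(src / f"{slide_id}.png")
    annotations = aio.read_annotations(src / f"{slide_id}.geojson")
    if factor > 1:
        slide = aio.downsample(slide, factor)
        annotations = annotations.scaled(factor)
    return slide, annotations


def stage_extract(cfg: PipelineConfig) -> None:
    _require(cfg, "synth")
    out = _stage_dir(cfg, "extract")
    out.mkdir(parents=True, exist_ok=True)
    ids = _slide_ids(cfg)
    train_ids, val_ids, test_ids = patching.split_dataset(
        ids, cfg.split_fractions, seed=cfg.seed_split)
    per_slide: dict[str, patching.PatchDataset] = {}
    for slide_id in ids:
        collected = patching.PatchDataset()
        for factor in cfg.downsample_factors:
            slide, annotations = _load_slide(cfg, slide_id, factor)
            masks = aio.rasterize_annotations(annotations, (slide.height, slide.width))
            ds = patching.extract_patches(slide, masks, cfg.tile_size, cfg.stride)
            collected = collected.merged_with(ds)
        per_slide[slide_id] = collected
    for tag, id_list in zip(patching.SPLIT_TAGS, (train_ids, val_ids, test_ids)):
        merged = patching.PatchDataset(split_tag=tag)
        for slide_id in id_list:
            merged = merged.merged_with(per_slide[slide_id])
        if len(merged) and all(merged.label_counts().values()):
            merged = patching.balance_classes(merged, seed=cfg.seed_balance)
        patching.save_dataset(merged, out / tag)
        logger.info("extract: %s -> %d patches %s", tag, len(merged),
                    merged.label_counts() if len(merged) else {})
    with open(out / "splits.json", "w") as fh:
        json.dump({"train": train_ids, "validation": val_ids, "test": test_ids}, fh)
    _mark_done(cfg, "extract")


def stage_train(cfg: PipelineConfig) -> None:
    _require(cfg, "extract")
    out = _stage_dir(cfg, "train")
    out.mkdir(parents=True, exist_ok=True)
    train_set = patching.load_dataset(_stage_dir(cfg, "extract") / "train", "train")
    if len(train_set) == 0:
        raise DataError("training dataset is empty; check extract stage inputs")
    model = build_classifier(cfg.classifier, seed=cfg.seed_init)
    model, history = train_classifier(model, train_set, seed=cfg.seed_train)
    save_model(model, out)
    pd.DataFrame({
        "epoch": np.arange(history.n_epochs),
        "train_loss": history.train_loss,
        "val_loss": history.val_loss,
    }).to_csv(out / "history.csv", index=False)
    logger.info("train: %d epochs, best %d (val loss %.4g)", history.n_epochs,
                history.best_epoch, history.val_loss[history.best_epoch])
    _mark_done(cfg, "train")


def stage_sweep(cfg: PipelineConfig) -> None:
    _require(cfg, "extract")
    _require(cfg, "train")
    out = _stage_dir(cfg, "sweep")
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(_stage_dir(cfg, "train"))
    val_set = patching.load_dataset(
        _stage_dir(cfg, "extract") / "validation", "validation")
    if len(val_set) == 0:
        raise DataError("validation dataset is empty; cannot sweep threshold")
    confidences = predict_patches(model, val_set)
    result = threshold_sweep(confidences, val_set.labels, cfg.sweep_grid_step)
    result.to_frame().to_csv(out / "sweep.csv", index=False)
    with open(out / "sweep.json", "w") as fh:
        json.dump({"best_threshold": result.best_threshold,
                   "best_f1": result.best_f1}, fh)
    logger.info("sweep: best threshold %.2f (f1 %.4f)",
                result.best_threshold, result.best_f1)
    _mark_done(cfg, "sweep")


def _best_threshold(cfg: PipelineConfig) -> float:
    with open(_stage_dir(cfg, "sweep") / "sweep.json") as fh:
        return float(json.load(fh)["best_threshold"])


def stage_segment(cfg: PipelineConfig) -> None:
    for upstream in ("synth", "extract", "train", "sweep"):
        _require(cfg, upstream)
    out = _stage_dir(cfg, "segment")
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(_stage_dir(cfg, "train"))
    threshold = _best_threshold(cfg)
    with open(_stage_dir(cfg, "extract") / "splits.json") as fh:
        test_ids = json.load(fh)["test"]
    factor = cfg.effective_segment_factor
    import tifffile
    from PIL import Image
    for slide_id in test_ids:
        slide, _ = _load_slide(cfg, slide_id, factor)
        cmap, mask = segment_slide(slide, model, step=cfg.segment_step,
                                   threshold=threshold, window=cfg.tile_size)
        tifffile.imwrite(out / f"{slide_id}_confidence.tif",
                         cmap.mean_confidence.astype(np.float32))
        aio.write_mask(mask.mask, out / f"{slide_id}_mask.png")
        Image.fromarray(render(cmap, "jet")).save(out / f"{slide_id}_heatmap.png")
        Image.fromarray(overlay(slide, mask)).save(out / f"{slide_id}_overlay.png")
    _mark_done(cfg, "segment")


def stage_evaluate(cfg: PipelineConfig) -> None:
    for upstream in ("extract", "train", "sweep", "segment"):
        _require(cfg, upstream)
    out = _stage_dir(cfg, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(_stage_dir(cfg, "train"))
    threshold = _best_threshold(cfg)
    test_set = patching.load_dataset(_stage_dir(cfg, "extract") / "test", "test")
    if len(test_set) == 0:
        raise DataError("test dataset is empty; cannot evaluate")
    kernel = kernel_metrics(predict_patches(model, test_set), test_set.labels,
                            threshold=threshold)
    with open(_stage_dir(cfg, "extract") / "splits.json") as fh:
        test_ids = json.load(fh)["test"]
    import tifffile
    factor = cfg.effective_segment_factor
    reports = []
    for slide_id in test_ids:
        slide, annotations = _load_slide(cfg, slide_id, factor)
        gt = aio.rasterize_annotations(annotations, (slide.height, slide.width))
        conf = tifffile.imread(_stage_dir(cfg, "segment") / f"{slide_id}_confidence.tif")
        from .segmentation import ConfidenceMap, binarize
        cmap = ConfidenceMap(mean_confidence=conf.astype(np.float64),
                             coverage=(conf >= 0).astype(np.int64),
                             window=cfg.tile_size, step=cfg.segment_step)
        reports.append(pixel_metrics(binarize(cmap, threshold), gt, cmap))
    macro = {k: {"mean": v[0], "sd": v[1]} for k, v in macro_average(reports).items()}
    metrics = {
        "threshold": threshold,
        "kernel": kernel.to_dict(),
        "pixel_per_slide": [r.to_dict() for r in reports],
        "pixel_macro": macro,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    logger.info("evaluate: kernel f1 %.4f, pixel f1 %.4f +/- %.4f",
                kernel.f1, macro["f1"]["mean"], macro["f1"]["sd"])
    _mark_done(cfg, "evaluate")


_STAGE_FUNCS = {
    "synth": stage_synth, "extract": stage_extract, "train": stage_train,
    "sweep": stage_sweep, "segment": stage_segment, "evaluate": stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages in order, skipping those already complete, and return
    the workspace path. Metrics land in ``<workspace>/evaluate/metrics.json``."""
    Path(cfg.workspace).mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if _stage_done(cfg, stage):
            logger.info("%s: up to date, skipping", stage)
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](cfg)
        logger.info("%s: finished in %.1f s", stage, time.perf_counter() - t0)
    return Path(cfg.workspace)
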