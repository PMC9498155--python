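"""Kernel-level (patch) and pixel-level metrics against area-based ground truth.

Two views of performance are reported. *Kernel-level* metrics score the raw
tile predictions against tile labels; *pixel-level* metrics compare the
binarized whole-slide segmentation with the rasterized annotation masks,
restricted to annotated pixels — with area-based annotation the unannotated
tissue carries no ground truth, so it is excluded rather than counted as
negative. The positive class is tumor throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .annotation_io import LabelMasks
from .errors import DataError, ParameterError
from .segmentation import ConfidenceMap, SegmentationMask


@dataclass
class MetricsReport:
    """Scalar metrics plus the 2x2 confusion matrix (positive = tumor).

    ``confusion`` holds raw counts [[TP, FN], [FP, TN]]; ``rates`` is the
    row-normalized version (rows: true tumor, true normal; each row sums to 1
    when its class is present).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    mean_squared_error: float
    confusion: np.ndarray
    n: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def rates(self) -> np.ndarray:
        counts = self.confusion.astype(float)
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, counts / sums, np.nan)

    def to_dict(self) -> dict:
        tp, fn = int(self.confusion[0, 0]), int(self.confusion[0, 1])
        fp, tn = int(self.confusion[1, 0]), int(self.confusion[1, 1])
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auroc": self.auroc,
            "mean_squared_error": self.mean_squared_error,
            "tp": tp, "fn": fn, "fp": fp, "tn": tn, "n": self.n,
        }


def _binary_report(pred: np.ndarray, truth: np.ndarray,
                   confidences: np.ndarray | None = None) -> MetricsReport:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else np.nan
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        warnings.warn("precision + recall = 0; reporting f1 = 0", stacklevel=3)
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if confidences is not None:
        scores = np.asarray(confidences, dtype=float)
        mse = float(np.mean((scores - truth.astype(float)) ** 2))
        if len(np.unique(truth)) < 2:
            warnings.warn("single-class labels: AUROC undefined", stacklevel=3)
            auroc = np.nan
        else:
            auroc = float(_skm.roc_auc_score(truth.astype(int), scores))
    else:
        mse = float(np.mean(pred.astype(float) != truth.astype(float)))
        auroc = np.nan
    return MetricsReport(
        accuracy=float(accuracy), precision=float(precision),
        recall=float(recall), f1=float(f1), auroc=auroc,
        mean_squared_error=mse,
        confusion=np.array([[tp, fn], [fp, tn]], dtype=np.int64), n=n,
    )


def kernel_metrics(confidences, labels, threshold: float = 0.5) -> MetricsReport:
    """Patch-level metrics: binarize confidences at ``threshold`` (>= is tumor).

    MSE and AUROC are computed on the raw confidences (threshold-free);
    single-class label sets yield a NaN AUROC with a warning.
    """
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels)
    if confidences.shape != labels.shape:
        raise DataError("confidences and labels must have equal length")
    if confidences.size == 0:
        raise DataError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ParameterError("labels must be 0 or 1")
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must be in [0, 1]")
    return _binary_report(confidences >= threshold, labels.astype(bool), confidences)


def pixel_metrics(mask: SegmentationMask, gt: LabelMasks,
                  cmap: ConfidenceMap | None = None) -> MetricsReport:
    """Pixel-level metrics on annotated pixels only.

    Unannotated pixels carry no ground truth under area-based annotation and
    are excluded. If the confidence map is supplied, MSE/AUROC are computed
    on the raw per-pixel mean confidences; otherwise on the binary mask.
    """
    if mask.mask.shape != gt.tumor_mask.shape:
        raise DataError(
            f"mask shape {mask.mask.shape} != ground truth shape {gt.tumor_mask.shape}"
        )
    annotated = gt.annotated_mask
    if cmap is not None:
        annotated = annotated & cmap.covered
    if not annotated.any():
        raise DataError("no annotated pixels to evaluate")
    pred = mask.mask[annotated]
    truth = gt.tumor_mask[annotated]
    conf = cmap.mean_confidence[annotated] if cmap is not None else None
    report = _binary_report(pred, truth, conf)
    report.extras["n_annotated"] = int(annotated.sum())
    return report


def roc_curve(confidences, labels):
    """ROC points and AUROC (trapezoidal, equal to the Mann-Whitney statistic).

    Returns ``(fpr, tpr, thresholds, auroc)``.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC requires both classes")
    fpr, tpr, thr = _skm.roc_curve(labels, np.asarray(confidences, dtype=float))
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def macro_average(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-slide macro averages: metric -> (mean, sd) across reports.

    This is the "mean +/- sd over slides" reporting style; the alternative is
    pooling all items into one report before scoring. Both are meaningful —
    macro-averaging weights every slide equally, pooling weights every
    patch/pixel equally — so the package exposes both and labels them.
    """
    if not reports:
        raise DataError("no reports to average")
    out = {}
    for name in ("accuracy", "precision", "recall", "f1", "auroc",
                 "mean_squared_error"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            out[name] = (np.nan, np.nan)
        else:
            out[name] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out
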