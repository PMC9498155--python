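"""Deployment-parameter search: threshold sweep and step-size trade-off.

The tile classifier is trained with a nominal 0.5 decision boundary, but the
deployed binarization threshold is chosen on validation data: the f1 score
is evaluated at every threshold on a hundredths grid over [0, 1] and the
best-scoring threshold is kept (ties resolved toward the lowest threshold,
favoring sensitivity — for a diagnostic aid a false alarm is cheaper than a
miss). The sweep runs on kernel-level confidences; the chosen threshold is
then reused for pixel-level binarization.

The step-size trade-off evaluates whole slides at each sliding-window step
with the chosen threshold, reporting macro-averaged pixel metrics and wall
times. Wall times are informational only — they depend on the machine.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .evaluation import kernel_metrics, macro_average, pixel_metrics
from .segmentation import STEP_SIZES, segment_slide


@dataclass
class SweepResult:
    thresholds: np.ndarray
    f1_per_threshold: np.ndarray
    best_threshold: float
    best_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "f1": self.f1_per_threshold})


@dataclass
class TradeoffRow:
    step: int
    accuracy_mean: float
    accuracy_sd: float
    f1_mean: float
    f1_sd: float
    seconds_mean: float
    n_evaluations: int


@dataclass
class TradeoffTable:
    rows: list[TradeoffRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def threshold_sweep(confidences, labels, grid_step: float = 0.01) -> SweepResult:
    """Evaluate f1 at every threshold on a [0, 1] grid; keep the best.

    The grid is ``0, grid_step, 2*grid_step, ..., 1``; binarization uses the
    ``confidence >= threshold`` rule. Among thresholds attaining the maximal
    f1 the lowest is reported.
    """
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels).astype(int)
    if confidences.shape != labels.shape or confidences.size == 0:
        raise DataError("confidences and labels must be equal-length and non-empty")
    if len(np.unique(labels)) < 2:
        raise DataError("threshold sweep requires both classes")
    if not 0 < grid_step <= 1:
        raise ParameterError("grid_step must be in (0, 1]")
    n_steps = int(round(1.0 / grid_step))
    thresholds = np.linspace(0.0, n_steps * grid_step, n_steps + 1)
    thresholds = np.minimum(thresholds, 1.0)
    f1s = np.empty_like(thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate thresholds give f1 = 0
        for i, t in enumerate(thresholds):
            f1s[i] = kernel_metrics(confidences, labels, threshold=t).f1
    best_idx = int(np.argmax(f1s))  # argmax returns the first = lowest threshold
    return SweepResult(thresholds=thresholds, f1_per_threshold=f1s,
                       best_threshold=float(thresholds[best_idx]),
                       best_f1=float(f1s[best_idx]))


def stepsize_tradeoff(slides_with_gt, model, steps=STEP_SIZES,
                      threshold: float = 0.5, window: int = 128) -> TradeoffTable:
    """Segment every slide at each step size and tabulate accuracy/f1/time.

    ``slides_with_gt`` is a sequence of ``(SlideImage, LabelMasks)`` pairs.
    Metrics are macro-averaged over slides (mean +/- sd); times are wall
    clock and machine-dependent.
    """
    slides_with_gt = list(slides_with_gt)
    if not slides_with_gt:
        raise DataError("no slides to evaluate")
    table = TradeoffTable()
    for step in steps:
        reports, seconds, n_eval = [], [], 0
        for slide, gt in slides_with_gt:
            t0 = time.perf_counter()
            cmap, mask = segment_slide(slide, model, step=step,
                                       threshold=threshold, window=window)
            seconds.append(time.perf_counter() - t0)
            from .segmentation import sliding_positions
            n_eval += len(sliding_positions(slide.height, slide.width, window, step))
            reports.append(pixel_metrics(mask, gt, cmap))
        avg = macro_average(reports)
        table.rows.append(TradeoffRow(
            step=int(step),
            accuracy_mean=avg["accuracy"][0], accuracy_sd=avg["accuracy"][1],
            f1_mean=avg["f1"][0], f1_sd=avg["f1"][1],
            seconds_mean=float(np.mean(seconds)),
            n_evaluations=n_eval,
        ))
    return table
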