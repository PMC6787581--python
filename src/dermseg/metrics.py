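"""Mask post-processing and the segmentation/detection evaluation suite.

Post-processing is plain binary morphology: an opening (erosion then
dilation) removes speckle noise smaller than the structuring element,
a closing (dilation then erosion) fills comparable holes; both use the
same square kernel (default 5×5) and both are idempotent.

Segmentation quality is scored pixel-wise against a ground-truth mask
(lesion = positive):

    Sen = TP/(TP+FN)            Spe = TN/(TN+FP)
    Dic = 2·TP/(2·TP+FP+FN)     Jac = TP/(TP+FP+FN)
    Acc = (TP+TN)/(TP+TN+FP+FN)

Dice and Jaccard are tied by Dic = 2·Jac/(1+Jac).  A metric whose
denominator is zero (e.g. specificity on an all-lesion truth) is
reported as NaN and excluded from dataset means.

Detection is scored by box IOU: a lesion counts as detected when
IOU > threshold (default 0.8, strict), and accuracy is the detected
fraction over *all* images including detection failures, while the mean
IOU is taken over detected images only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .boxes import BoundingBox, iou

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "MetricsError",
    "morph_open",
    "morph_close",
    "postprocess",
    "confusion_counts",
    "metrics_from_counts",
    "segmentation_metrics",
    "detection_accuracy",
    "evaluate_dataset",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts with lesion as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class SegmentationMetrics:
    """Sensitivity, specificity, Dice, Jaccard and pixel accuracy.

    Undefined ratios (zero denominator) are NaN.
    """

    Sen: float
    Spe: float
    Dic: float
    Jac: float
    Acc: float


def _square(kernel_size: int) -> np.ndarray:
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise MetricsError("kernel_size must be odd and >= 1")
    return np.ones((kernel_size, kernel_size), dtype=bool)


def morph_open(mask: np.ndarray, kernel_size: int = 5) -> np.ndarray:
    """Binary opening with a square kernel: removes small speckles.

    Anti-extensive (result ⊆ input) and idempotent.
    """
    s = _square(kernel_size)
    eroded = ndimage.binary_erosion(np.asarray(mask, bool), structure=s, border_value=0)
    return ndimage.binary_dilation(eroded, structure=s, border_value=0)


def morph_close(mask: np.ndarray, kernel_size: int = 5) -> np.ndarray:
    """Binary closing with a square kernel: fills small holes.

    Extensive (input ⊆ result) and idempotent; the erosion treats the
    outside of the frame as foreground so border pixels are not eaten.
    """
    s = _square(kernel_size)
    dilated = ndimage.binary_dilation(np.asarray(mask, bool), structure=s, border_value=0)
    return ndimage.binary_erosion(dilated, structure=s, border_value=1)


def postprocess(mask: np.ndarray, kernel_size: int = 5) -> np.ndarray:
    """Noise cleanup of a segmentation mask: opening then closing."""
    return morph_close(morph_open(mask, kernel_size), kernel_size)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel-wise cross-tabulation of predicted vs ground-truth masks."""
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    if pred.shape != gt.shape:
        raise MetricsError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & gt)),
        FP=int(np.count_nonzero(pred & ~gt)),
        FN=int(np.count_nonzero(~pred & gt)),
        TN=int(np.count_nonzero(~pred & ~gt)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(counts: ConfusionCounts) -> SegmentationMetrics:
    """The five ratio metrics from confusion counts."""
    if counts.total == 0:
        raise MetricsError("all-zero confusion counts")
    return SegmentationMetrics(
        Sen=_ratio(counts.TP, counts.TP + counts.FN),
        Spe=_ratio(counts.TN, counts.TN + counts.FP),
        Dic=_ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN),
        Jac=_ratio(counts.TP, counts.TP + counts.FN + counts.FP),
        Acc=_ratio(counts.TP + counts.TN, counts.total),
    )


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray) -> SegmentationMetrics:
    return metrics_from_counts(confusion_counts(pred, gt))


def detection_accuracy(
    iou_values: Sequence[float], failures: int = 0, threshold: float = 0.8
) -> tuple[float, float]:
    """Detection accuracy at a strict IOU threshold, and mean detected IOU.

    ``iou_values`` are the IOUs of the images where the detector
    returned a box; ``failures`` counts the images where it returned
    none.  Accuracy = #(IOU > threshold) / (#boxes + #failures); an IOU
    exactly at the threshold counts as a miss.  The mean IOU is over
    detected images only (NaN when every image failed).
    """
    if not 0.0 < threshold < 1.0:
        raise MetricsError("threshold must lie in (0, 1)")
    if failures < 0:
        raise MetricsError("failures must be >= 0")
    n_total = len(iou_values) + failures
    if n_total == 0:
        raise MetricsError("no images to evaluate")
    hits = sum(1 for v in iou_values if v > threshold)
    mean_iou = float(np.mean(iou_values)) if len(iou_values) else float("nan")
    return hits / n_total, mean_iou


def evaluate_dataset(
    pred_masks: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    pred_boxes: Optional[Sequence[Optional[BoundingBox]]] = None,
    gt_boxes: Optional[Sequence[BoundingBox]] = None,
    image_ids: Optional[Sequence[str]] = None,
    iou_threshold: float = 0.8,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-image metrics plus an unweighted summary row.

    Rows carry one image each (columns: image_id, detected, iou, Sen,
    Spe, Dic, Jac, Acc); the final ``mean`` row averages each metric
    over the images where it is defined.  Box columns appear only when
    boxes are supplied.  When ``csv_path`` is given the table is also
    written as CSV.
    """
    if len(pred_masks) != len(gt_masks) or len(pred_masks) == 0:
        raise MetricsError("pred and gt mask lists must be non-empty and aligned")
    with_boxes = pred_boxes is not None
    if with_boxes and (gt_boxes is None or len(pred_boxes) != len(pred_masks)):
        raise MetricsError("box lists must align with the mask lists")
    ids = list(image_ids) if image_ids is not None else [
        f"image_{i:04d}" for i in range(len(pred_masks))
    ]
    rows = []
    for i, (pm, gm) in enumerate(zip(pred_masks, gt_masks)):
        m = segmentation_metrics(pm, gm)
        row = {"image_id": ids[i]}
        if with_boxes:
            pb = pred_boxes[i]
            row["iou"] = iou(pb, gt_boxes[i]) if pb is not None else float("nan")
            row["detected"] = bool(pb is not None and row["iou"] > iou_threshold)
        row.update(Sen=m.Sen, Spe=m.Spe, Dic=m.Dic, Jac=m.Jac, Acc=m.Acc)
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {"image_id": "mean"}
    for col in df.columns:
        if col == "image_id":
            continue
        if col == "detected":
            summary[col] = bool(df[col].mean() > 0.5)
        else:
            summary[col] = float(df[col].mean(skipna=True))
    out = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    if csv_path is not None:
        Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(csv_path, index=False)
    return out
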