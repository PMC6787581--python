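"""Grid-based single-shot detection arithmetic as pure functions.

The lesion locator in the full system is a single-class grid detector:
the image is split into an S×S grid, each cell predicts B candidate
boxes (x, y, w, h, confidence) plus C conditional class probabilities,
and the cell containing an object's midpoint is responsible for it.
The functions here implement that arithmetic — confidence scores, the
leaky-ReLU activation, the sum-squared training loss and the detection
kernel filter count — without any network or training loop, so each
formula is unit-testable in isolation.

Shapes used by :func:`yolo_loss` (all ``numpy`` arrays):

- ``boxes``: ``(S, S, B, 5)`` with the last axis ``(x, y, w, h, conf)``
- ``class_probs``: ``(S, S, C)``
- ``responsible``: ``(S, S, B)`` boolean — the 1ᵢⱼ^obj indicator
- ``cell_has_object``: ``(S, S)`` boolean — the 1ᵢ^obj indicator
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "LossWeights",
    "confidence",
    "class_confidence",
    "leaky_relu",
    "yolo_loss",
    "assign_responsibility",
    "detection_filters",
]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry: S cells per side, B boxes per cell, C classes."""

    S: int
    B: int
    C: int

    def __post_init__(self) -> None:
        if min(self.S, self.B, self.C) < 1:
            raise ValueError("S, B and C must all be >= 1")

    @property
    def tensor_size(self) -> int:
        """Number of entries in the prediction tensor, (S×S)·B·(5+C)."""
        return self.S * self.S * self.B * (5 + self.C)


@dataclass(frozen=True)
class LossWeights:
    """Loss balancing constants: λ_coord up-weights coordinates, λ_noobj
    down-weights confidence from empty cells."""

    lambda_coord: float = 5.0
    lambda_noobj: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_coord <= 0 or self.lambda_noobj <= 0:
            raise ValueError("loss weights must be positive")


def confidence(pr_object: float, iou_value: float) -> float:
    """Box confidence: Pr(Object) · IOU with the ground truth.

    Zero when no object is present; equal to the IOU when an object is
    certainly present.
    """
    for name, v in (("pr_object", pr_object), ("iou_value", iou_value)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return pr_object * iou_value


def class_confidence(cond_class_prob: float, box_confidence: float) -> float:
    """Class-specific score Pr(Classᵢ|Object) · Pr(Object) · IOU."""
    return cond_class_prob * box_confidence


def leaky_relu(x):
    """Leaky rectified linear activation: x if x > 0, else 0.1·x."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, 0.1 * x)
    return out if out.ndim else float(out)


def assign_responsibility(x: float, y: float, grid: GridSpec) -> tuple[int, int]:
    """Grid cell responsible for an object with normalized midpoint (x, y).

    The cell is ``(⌊x·S⌋, ⌊y·S⌋)`` clamped to ``[0, S-1]`` so that a
    midpoint exactly on the far edge still maps to the last cell.
    """
    i = min(max(int(np.floor(x * grid.S)), 0), grid.S - 1)
    j = min(max(int(np.floor(y * grid.S)), 0), grid.S - 1)
    return i, j


def detection_filters(num_classes: int) -> int:
    """1×1 detection-kernel filter count: (classes + 5) × 3.

    Each of the three detection scales predicts 3 boxes per cell with 5
    box parameters plus the class scores; a single-class detector
    therefore uses 18 filters at each detection layer.
    """
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    return (num_classes + 5) * 3


def yolo_loss(
    pred_boxes: np.ndarray,
    pred_class_probs: np.ndarray,
    target_boxes: np.ndarray,
    target_class_probs: np.ndarray,
    responsible: np.ndarray,
    cell_has_object: np.ndarray,
    weights: LossWeights = LossWeights(),
    sqrt_wh: bool = True,
) -> float:
    """Sum-squared detection loss over a grid of cell predictions.

    Five terms: λ_coord-weighted midpoint error and width/height error
    (on √w, √h by default) for responsible boxes; confidence error for
    responsible boxes; λ_noobj-weighted confidence error for all other
    boxes; and per-cell classification error where an object is present.

    ``sqrt_wh=False`` selects the literal quadratic (w−ŵ)², (h−ĥ)² form.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=float)
    target_boxes = np.asarray(target_boxes, dtype=float)
    pred_class_probs = np.asarray(pred_class_probs, dtype=float)
    target_class_probs = np.asarray(target_class_probs, dtype=float)
    responsible = np.asarray(responsible, dtype=bool)
    cell_has_object = np.asarray(cell_has_object, dtype=bool)
    if pred_boxes.shape != target_boxes.shape or pred_boxes.shape[:3] != responsible.shape:
        raise ValueError("prediction/target/indicator shapes disagree")

    wh_pred = pred_boxes[..., 2:4]
    wh_tgt = target_boxes[..., 2:4]
    if sqrt_wh:
        if np.any(wh_pred[responsible] < 0) or np.any(wh_tgt[responsible] < 0):
            raise ValueError("negative width/height under the square-root form")
        wh_err = np.sqrt(wh_pred) - np.sqrt(wh_tgt)
    else:
        wh_err = wh_pred - wh_tgt

    xy_err = pred_boxes[..., 0:2] - target_boxes[..., 0:2]
    conf_err = pred_boxes[..., 4] - target_boxes[..., 4]

    coord = np.sum((xy_err[responsible] ** 2)) + np.sum(
        np.where(responsible[..., None], wh_err**2, 0.0)
    )
    obj_conf = np.sum(np.where(responsible, conf_err**2, 0.0))
    noobj_conf = np.sum(np.where(~responsible, conf_err**2, 0.0))
    class_err = pred_class_probs - target_class_probs
    classification = np.sum(
        np.where(cell_has_object[..., None], class_err**2, 0.0)
    )

    return float(
        weights.lambda_coord * coord
        + obj_conf
        + weights.lambda_noobj * noobj_conf
        + classification
    )
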