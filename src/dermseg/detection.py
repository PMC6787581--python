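"""Lesion localization: a pluggable detector interface with a classical
fallback.

The full system localizes the lesion with a trained single-class deep
detector before segmenting it.  Training such a network needs a large
annotated dermoscopy dataset and a GPU, so the pipeline instead accepts
any box source through a small interface:

- :class:`OracleDetector` — returns a known ground-truth box (for
  synthetic fixtures and upper-bound evaluation);
- :class:`LabelFileDetector` — reads boxes from normalized
  center-format label files (e.g. another model's exported output);
- :func:`fallback_detector` — a classical thresholding locator that
  makes the pipeline runnable with no external input at all.

All detectors return a box in original-image pixel coordinates or
``None`` when no lesion can be localized (the pipeline then reports the
image as undetected).
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Optional, Protocol

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import resize

from .boxes import BoundingBox, CenterBox, center_to_corners, read_label_file

__all__ = [
    "Detector",
    "OracleDetector",
    "LabelFileDetector",
    "fallback_detector",
    "detect_lesion",
    "FALLBACK_WORKING_SIZE",
]

FALLBACK_WORKING_SIZE = 512  # detection runs at this internal resolution
_MIN_AREA_FRACTION = 0.002  # components smaller than this are noise


class Detector(Protocol):
    def __call__(self, image: np.ndarray) -> Optional[BoundingBox]: ...


class OracleDetector:
    """Returns a fixed known box regardless of the image content."""

    def __init__(self, box: BoundingBox) -> None:
        self.box = box

    def __call__(self, image: np.ndarray) -> Optional[BoundingBox]:
        return self.box


class LabelFileDetector:
    """Reads the box from a normalized center-format label file."""

    def __init__(self, label_path: str | Path) -> None:
        self.label_path = Path(label_path)

    def __call__(self, image: np.ndarray) -> Optional[BoundingBox]:
        if not self.label_path.exists():
            return None
        h, w = image.shape[:2]
        center: CenterBox = read_label_file(self.label_path)
        return center_to_corners(center, w, h)


def fallback_detector(image: np.ndarray) -> Optional[BoundingBox]:
    """Classical lesion locator: dark-region thresholding.

    Grayscale → percentile contrast normalization → global threshold by
    between-class variance maximization → the largest dark connected
    component touching fewer than 3 image borders → its tight box.  The
    image is analyzed at an internal working resolution and the box is
    mapped back to original pixel coordinates, so the result is
    resolution independent.  Returns ``None`` when no component
    qualifies (flat images, lesions flooding the frame).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    work = resize(
        image, (FALLBACK_WORKING_SIZE, FALLBACK_WORKING_SIZE), anti_aliasing=True
    )
    gray = rgb2gray(work)
    lo, hi = np.percentile(gray, [1.0, 99.0])
    if hi - lo < 1e-6:
        return None
    gray = np.clip((gray - lo) / (hi - lo), 0.0, 1.0)
    try:
        thr = threshold_otsu(gray)
    except ValueError:
        return None
    dark = gray < thr
    labels, n = cc_label(dark, return_num=True)
    if n == 0:
        return None
    size = FALLBACK_WORKING_SIZE
    best = None
    for prop in regionprops(labels):
        if prop.area < _MIN_AREA_FRACTION * size * size:
            continue
        y0, x0, y1, x1 = prop.bbox
        borders = sum(
            (y0 == 0, x0 == 0, y1 == size, x1 == size)
        )
        if borders >= 3:
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        return None
    y0, x0, y1, x1 = best.bbox
    sy, sx = h / size, w / size
    return BoundingBox(x0 * sx, y0 * sy, x1 * sx, y1 * sy)


def detect_lesion(
    image: np.ndarray, detector: Detector | Callable[[np.ndarray], Optional[BoundingBox]]
) -> Optional[BoundingBox]:
    """Run a detector; return its box in original pixel coordinates or None."""
    return detector(np.asarray(image))
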