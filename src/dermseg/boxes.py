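"""Axis-aligned bounding boxes in corner and normalized center formats.

Boxes use the half-open pixel convention ``[x1, x2) × [y1, y2)``: a box
covers the integer pixel columns ``x1 .. x2-1`` and rows ``y1 .. y2-1``,
so its area is ``(x2-x1) * (y2-y1)`` with no ``+1`` correction.  The IOU
below and the detection-label file format both follow this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "BoundingBox",
    "CenterBox",
    "BoxValidationError",
    "corners_to_center",
    "center_to_corners",
    "iou",
    "expand_box",
    "read_label_file",
    "write_label_file",
]


class BoxValidationError(ValueError):
    """Raised for degenerate or out-of-range box coordinates."""


@dataclass(frozen=True)
class BoundingBox:
    """Corner-format box: top-left ``(x1, y1)``, bottom-right ``(x2, y2)``."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise BoxValidationError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class CenterBox:
    """Center-format box: midpoint ``(x, y)``, width ``w``, height ``h``.

    When ``normalized`` is true all fields are divided by the image
    dimensions and must lie in ``[0, 1]`` — the detection training label
    convention (one object line ``class x y w h``).
    """

    x: float
    y: float
    w: float
    h: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise BoxValidationError(f"non-positive extent: w={self.w}, h={self.h}")
        if self.normalized:
            for name in ("x", "y", "w", "h"):
                v = getattr(self, name)
                if not 0.0 <= v <= 1.0:
                    raise BoxValidationError(
                        f"normalized field {name}={v} outside [0, 1]"
                    )


def corners_to_center(
    box: BoundingBox, image_w: int | None = None, image_h: int | None = None
) -> CenterBox:
    """Convert a corner box to center format.

    ``x = (x1+x2)/2``, ``y = (y1+y2)/2``, ``w = x2-x1``, ``h = y2-y1``.
    When image dimensions are given the result is normalized by them.
    """
    x = (box.x1 + box.x2) / 2.0
    y = (box.y1 + box.y2) / 2.0
    w = box.width
    h = box.height
    if image_w is not None or image_h is not None:
        if image_w is None or image_h is None:
            raise BoxValidationError("both image_w and image_h are required to normalize")
        return CenterBox(x / image_w, y / image_h, w / image_w, h / image_h, normalized=True)
    return CenterBox(x, y, w, h, normalized=False)


def center_to_corners(
    box: CenterBox, image_w: int | None = None, image_h: int | None = None
) -> BoundingBox:
    """Exact inverse of :func:`corners_to_center`."""
    if box.normalized:
        if image_w is None or image_h is None:
            raise BoxValidationError("image dimensions required to denormalize")
        x, y, w, h = box.x * image_w, box.y * image_h, box.w * image_w, box.h * image_h
    else:
        x, y, w, h = box.x, box.y, box.w, box.h
    return BoundingBox(x - w / 2.0, y - h / 2.0, x + w / 2.0, y + h / 2.0)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def expand_box(
    box: BoundingBox, margin_fraction: float, image_w: int, image_h: int
) -> BoundingBox:
    """Grow a box by ``margin_fraction`` of its width/height per side.

    Coordinates are clamped to the image bounds; GrabCut hard-constrains
    everything outside the rectangle to background, so a small margin
    guards against a tight box clipping the object.
    """
    if margin_fraction < 0:
        raise BoxValidationError("margin_fraction must be >= 0")
    mx = box.width * margin_fraction
    my = box.height * margin_fraction
    return BoundingBox(
        max(0.0, box.x1 - mx),
        max(0.0, box.y1 - my),
        min(float(image_w), box.x2 + mx),
        min(float(image_h), box.y2 + my),
    )


def write_label_file(path: str | Path, box: CenterBox, class_id: int = 0) -> None:
    """Write one normalized center-format label line ``class x y w h``."""
    if not box.normalized:
        raise BoxValidationError("label files store normalized boxes")
    Path(path).write_text(
        f"{class_id} {box.x:.12f} {box.y:.12f} {box.w:.12f} {box.h:.12f}\n"
    )


def read_label_file(path: str | Path) -> CenterBox:
    """Read the first object line of a normalized center-format label file."""
    text = Path(path).read_text().strip()
    if not text:
        raise BoxValidationError(f"empty label file: {path}")
    fields = text.splitlines()[0].split()
    if len(fields) != 5:
        raise BoxValidationError(f"malformed label line in {path}: {text!r}")
    _, x, y, w, h = fields
    return CenterBox(float(x), float(y), float(w), float(h), normalized=True)
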