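"""Hair-occlusion removal for dermoscopic images.

Thin dark hairs crossing a lesion disturb both localization and
segmentation.  The classical remedy implemented here works in three
steps on each color channel:

1. *Detect*: grayscale morphological closing with linear structuring
   elements at several orientations fills thin dark structures; pixels
   where the closing raises the intensity by more than a threshold are
   hair candidates.
2. *Verify*: candidate connected components are kept only if they are
   long (skeleton length) and thin (distance-transform thickness) —
   this rejects lesion edges and small dark spots.
3. *Replace*: each verified pixel is replaced by distance-weighted
   linear interpolation between the nearest clean pixels on either
   side, sampled perpendicular to the local hair direction; the
   replaced pixels are then smoothed by an adaptive median filter.

Pixels outside the verified hair mask are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, skeletonize

__all__ = [
    "HairRemovalParams",
    "HairRemovalError",
    "detect_hair_mask",
    "verify_hair_structures",
    "inpaint_hairs",
    "smooth_replaced",
    "remove_hairs",
]


class HairRemovalError(ValueError):
    pass


@dataclass(frozen=True)
class HairRemovalParams:
    """Tunable hair-removal parameters (all lengths in pixels).

    Defaults target thin dark elongated structures: linear closing
    elements of length 9 at four orientations, an 8-bit detection
    threshold of 20, and verification limits of 15 px minimum skeleton
    length and 9 px maximum thickness.  The thickness ceiling is
    measured on the *detected* component: closing widens a hair by a
    pixel or two per side, and crossing hairs bulge at junctions, so
    the ceiling sits near three times the physical hair width while
    remaining far below any lesion-sized blob.
    """

    line_length: int = 9
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    closing_threshold: int = 20
    min_hair_length: int = 15
    max_hair_thickness: int = 9
    median_max_window: int = 7

    def __post_init__(self) -> None:
        if self.line_length < 3:
            raise HairRemovalError("line_length must be >= 3")
        if not self.orientations:
            raise HairRemovalError("orientations must be non-empty")
        if self.closing_threshold <= 0 or self.min_hair_length <= 0:
            raise HairRemovalError("thresholds must be positive")
        if self.max_hair_thickness <= 0:
            raise HairRemovalError("max_hair_thickness must be positive")
        if self.median_max_window < 3 or self.median_max_window % 2 == 0:
            raise HairRemovalError("median_max_window must be odd and >= 3")


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Binary linear structuring element of given length and orientation."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    t = np.arange(-np.ceil(half), np.ceil(half) + 1)
    ys = np.rint(-t * np.sin(theta)).astype(int)
    xs = np.rint(t * np.cos(theta)).astype(int)
    ys -= ys.min()
    xs -= xs.min()
    fp = np.zeros((ys.max() + 1, xs.max() + 1), dtype=bool)
    fp[ys, xs] = True
    return fp


def detect_hair_mask(image: np.ndarray, params: HairRemovalParams) -> np.ndarray:
    """Candidate hair mask from multi-orientation grayscale closing.

    A pixel is marked if, on any channel and any orientation, closing
    raises its intensity by more than ``closing_threshold`` — closing
    only fills structures darker than their surroundings, so bright
    lines are never detected.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise HairRemovalError("expected an H×W×3 image")
    h, w = image.shape[:2]
    footprints = [_line_footprint(params.line_length, a) for a in params.orientations]
    for fp in footprints:
        if fp.shape[0] > h or fp.shape[1] > w:
            raise HairRemovalError("image smaller than the structuring element")
    mask = np.zeros((h, w), dtype=bool)
    for ch in range(3):
        plane = image[..., ch]
        for fp in footprints:
            diff = closing(plane, fp).astype(np.int16) - plane.astype(np.int16)
            mask |= diff > params.closing_threshold
    return mask


def verify_hair_structures(mask: np.ndarray, params: HairRemovalParams) -> np.ndarray:
    """Keep only components that are long and thin enough to be hairs.

    Length is the component's skeleton pixel count; thickness is twice
    the maximum distance-transform value inside the component.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = cc_label(mask, return_num=True)
    dist = ndimage.distance_transform_edt(mask)
    out = np.zeros_like(mask)
    for i in range(1, n + 1):
        comp = labels == i
        if int(skeletonize(comp).sum()) < params.min_hair_length:
            continue
        if 2.0 * float(dist[comp].max()) > params.max_hair_thickness:
            continue
        out |= comp
    return out


def _perpendicular_direction(orientation_rad: float) -> tuple[int, int]:
    """Quantized step direction perpendicular to a hair's axis.

    ``orientation_rad`` follows the regionprops convention (angle
    between the row axis and the major axis, in (-pi/2, pi/2]).  Ties
    between sectors break toward the horizontal step.
    """
    # component axis direction as (dy, dx)
    dy, dx = -np.cos(orientation_rad), np.sin(orientation_rad)
    # perpendicular
    py, px = -dx, dy
    ang = np.arctan2(py, px) % np.pi  # fold to [0, pi)
    sector = int(np.floor((ang + np.pi / 8) / (np.pi / 4))) % 4
    return [(0, 1), (1, 1), (1, 0), (-1, 1)][sector]


def _walk(mask: np.ndarray, y: int, x: int, dy: int, dx: int) -> tuple[int, int] | None:
    h, w = mask.shape
    d = 1
    while True:
        ny, nx = y + dy * d, x + dx * d
        if not (0 <= ny < h and 0 <= nx < w):
            return None
        if not mask[ny, nx]:
            return ny, nx
        d += 1


def inpaint_hairs(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by perpendicular distance-weighted interpolation.

    For each masked pixel the two nearest unmasked pixels along the
    direction perpendicular to its component's axis are found; the
    replacement is their linear interpolation weighted by inverse
    distance.  If one side runs off the image the other side's value is
    used; if the perpendicular fails entirely, the orthogonal direction
    is tried before giving up.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    out = image.copy()
    if not mask.any():
        return out
    labels, n = cc_label(mask, return_num=True)
    props = {p.label: p for p in regionprops(labels)}
    flat = image.reshape(-1, image.shape[2]).astype(float)
    h, w = mask.shape
    orthogonal = {(0, 1): (1, 0), (1, 0): (0, 1), (1, 1): (-1, 1), (-1, 1): (1, 1)}
    for i in range(1, n + 1):
        dy, dx = _perpendicular_direction(props[i].orientation)
        fallback = orthogonal[(dy, dx)]
        ys, xs = np.nonzero(labels == i)
        for y, x in zip(ys, xs):
            for sdy, sdx in ((dy, dx), fallback):
                a = _walk(mask, y, x, sdy, sdx)
                b = _walk(mask, y, x, -sdy, -sdx)
                if a is None and b is None:
                    continue
                if a is None:
                    val = flat[b[0] * w + b[1]]
                elif b is None:
                    val = flat[a[0] * w + a[1]]
                else:
                    da = max(abs(a[0] - y), abs(a[1] - x))
                    db = max(abs(b[0] - y), abs(b[1] - x))
                    va = flat[a[0] * w + a[1]]
                    vb = flat[b[0] * w + b[1]]
                    val = (db * va + da * vb) / (da + db)
                out[y, x] = np.clip(np.rint(val), 0, 255).astype(np.uint8)
                break
            else:
                raise HairRemovalError(
                    "masked region spans the image in both directions"
                )
    return out


def smooth_replaced(
    image: np.ndarray, mask: np.ndarray, params: HairRemovalParams = HairRemovalParams()
) -> np.ndarray:
    """Adaptive median filter applied only at masked pixels.

    The window grows from 3×3 to ``median_max_window`` until the window
    median separates from the window extremes; the pixel keeps its value
    if it is not itself an impulse extreme, otherwise it takes the
    median.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    out = image.copy()
    if not mask.any():
        return out
    h, w = image.shape[:2]
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        for ch in range(image.shape[2]):
            win = 3
            while True:
                r = win // 2
                patch = image[max(0, y - r) : y + r + 1, max(0, x - r) : x + r + 1, ch]
                zmin, zmed, zmax = (
                    int(patch.min()),
                    int(np.median(patch)),
                    int(patch.max()),
                )
                z = int(image[y, x, ch])
                if zmin < zmed < zmax:
                    out[y, x, ch] = z if zmin < z < zmax else zmed
                    break
                if win >= params.median_max_window:
                    out[y, x, ch] = zmed
                    break
                win += 2
    return out


def remove_hairs(
    image: np.ndarray, params: HairRemovalParams = HairRemovalParams()
) -> np.ndarray:
    """Full three-step hair removal: detect → verify → inpaint → smooth.

    Returns a new image; only pixels inside the verified hair mask can
    differ from the input.  An image with no verified hairs is returned
    unchanged.
    """
    mask = verify_hair_structures(detect_hair_mask(image, params), params)
    if not mask.any():
        return np.asarray(image).copy()
    return smooth_replaced(inpaint_hairs(image, mask), mask, params)
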