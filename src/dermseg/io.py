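"""PNG image/mask reading and writing.

Images are 8-bit RGB; masks are single-channel PNGs with values {0, 255}
where 255 marks lesion/foreground.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_image", "save_image", "load_mask", "save_mask"]


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an H×W×3 uint8 array (grayscale is expanded)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an H×W×3 uint8 image")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image, mode="RGB").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG as an H×W boolean array (any nonzero pixel is true)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected an H×W boolean mask")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)
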