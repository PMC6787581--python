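"""Seeded generator of dermoscopy-like images with ground truth.

Real dermoscopic images are hard to segment because of fuzzy lesion
boundaries, hair occlusion, and acquisition artifacts (ruler marks, gel
bubbles, dark vignetted corners).  This module emulates exactly those
difficulties on demand: a smoothly varying skin-tone background, one
darker star-convex lesion blob with a blurred boundary, thin dark hair
curves, and optional artifacts — together with the exact ground-truth
lesion mask, tight bounding box and hair mask, so every downstream stage
(hair removal, detection, segmentation, metrics) has deterministic,
fully labelled fixtures without any external dataset.

Everything is a pure function of :class:`SynthConfig`; the seed fully
determines the output bitwise.  Composition order is fixed: background →
lesion → hairs → artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon
from skimage.filters import gaussian
from skimage.measure import label as cc_label

from .boxes import BoundingBox, corners_to_center, write_label_file
from .io import save_image, save_mask

__all__ = [
    "SynthConfig",
    "SynthSample",
    "ConfigurationError",
    "generate_background",
    "generate_lesion",
    "add_hairs",
    "add_artifacts",
    "make_sample",
    "make_dataset",
    "tight_box",
]

ARTIFACT_KINDS = frozenset({"ruler", "bubble", "dark_corner"})

# rng stream indices: one child seed per composition stage so that each
# public operation re-derives the same stream when called standalone
_BG, _LESION, _HAIR, _ARTIFACT, _TEXTURE = 0, 1, 2, 3, 4


class ConfigurationError(ValueError):
    """Raised when a SynthConfig cannot produce a valid sample."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dermoscopy sample.

    Sizes are pixels; ``lesion_irregularity`` is a dimensionless 0–1
    perturbation amplitude of the lesion radius profile;
    ``background_variation`` is the 8-bit amplitude of the low-frequency
    skin-tone modulation.  The seed fully determines the output.
    """

    width: int = 128
    height: int = 128
    lesion_radius_range: tuple[float, float] = (22.0, 40.0)
    lesion_irregularity: float = 0.35
    skin_color: tuple[int, int, int] = (224, 172, 150)
    lesion_color: tuple[int, int, int] = (110, 64, 58)
    boundary_blur_sigma: float = 1.5
    background_variation: float = 6.0
    n_hairs: int = 5
    hair_thickness_range: tuple[int, int] = (1, 3)
    artifact_flags: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ConfigurationError("image dimensions must be >= 64")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lesion_radius_range must be positive ascending")
        if not 0.0 <= self.lesion_irregularity <= 1.0:
            raise ConfigurationError("lesion_irregularity must lie in [0, 1]")
        if self.n_hairs < 0:
            raise ConfigurationError("n_hairs must be >= 0")
        unknown = set(self.artifact_flags) - ARTIFACT_KINDS
        if unknown:
            raise ConfigurationError(f"unknown artifact kinds: {sorted(unknown)}")
        # the lesion must fit with a 2 px margin even at maximal perturbation
        reach = hi * (1.0 + self.lesion_irregularity) + 2 + 2 * self.boundary_blur_sigma
        if 2 * reach >= min(self.width, self.height):
            raise ConfigurationError("lesion_radius_range too large for the image")


@dataclass(frozen=True)
class SynthSample:
    """One generated image with its ground truth.

    ``hairless_image`` is the same composition without the hair-drawing
    step — the reference for judging hair-removal restoration quality.
    """

    image: np.ndarray
    gt_mask: np.ndarray
    gt_box: BoundingBox
    hair_mask: np.ndarray
    hairless_image: np.ndarray


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    return np.random.default_rng(ss)


def tight_box(mask: np.ndarray) -> BoundingBox:
    """Tight half-open bounding rectangle of a nonempty boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return BoundingBox(
        float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)
    )


def generate_background(config: SynthConfig) -> np.ndarray:
    """Skin-tone background with smooth low-frequency color variation."""
    rng = _rng(config, _BG)
    h, w = config.height, config.width
    # coarse Gaussian noise upsampled with a cubic spline -> smooth field
    coarse = rng.normal(size=(h // 16 + 3, w // 16 + 3, 3))
    out = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        zoom = (h / coarse.shape[0], w / coarse.shape[1])
        out[..., ch] = ndimage.zoom(coarse[..., ch], zoom, order=3)[:h, :w]
    out = np.asarray(config.skin_color, dtype=float) + config.background_variation * out
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _lesion_field(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Soft lesion alpha field in [0, 1] and the thresholded binary mask."""
    rng = _rng(config, _LESION)
    h, w = config.height, config.width
    lo, hi = config.lesion_radius_range
    a, b = rng.uniform(lo, hi, size=2)  # ellipse semi-axes
    reach = max(a, b) * (1.0 + config.lesion_irregularity) + 2 + 2 * config.boundary_blur_sigma
    if 2 * reach >= min(w, h):
        raise ConfigurationError("lesion cannot fit inside the image")
    cx = rng.uniform(reach, w - reach)
    cy = rng.uniform(reach, h - reach)
    theta = rng.uniform(0, 2 * np.pi)  # ellipse tilt

    phi = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    base = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    # smooth periodic perturbation: a short random Fourier series,
    # normalized to unit peak so the radius stays within the reach bound
    noise = np.zeros_like(phi)
    for k in range(2, 7):
        ck, dk = rng.normal(size=2) / k
        noise += ck * np.cos(k * phi) + dk * np.sin(k * phi)
    peak = np.max(np.abs(noise))
    if peak > 0:
        noise /= peak
    r = base * (1.0 + config.lesion_irregularity * noise)

    xs = cx + r * np.cos(phi + theta)
    ys = cy + r * np.sin(phi + theta)
    rr, cc = polygon(ys, xs, shape=(h, w))
    hard = np.zeros((h, w), dtype=float)
    hard[rr, cc] = 1.0
    soft = gaussian(hard, sigma=config.boundary_blur_sigma, preserve_range=True)
    soft = np.clip(soft, 0.0, 1.0)
    mask = soft > 0.5
    # blur + threshold can in principle pinch off slivers; keep the
    # largest component so the ground truth is a single region
    labels = cc_label(mask)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
        soft = np.where(mask | (soft <= 0.5), soft, 0.0)
    if not mask.any():
        raise ConfigurationError("lesion mask came out empty")
    return soft, mask


def generate_lesion(config: SynthConfig) -> tuple[np.ndarray, BoundingBox]:
    """Binary lesion mask and its tight bounding box."""
    _, mask = _lesion_field(config)
    return mask, tight_box(mask)


def _compose_lesion(
    background: np.ndarray, soft: np.ndarray, config: SynthConfig
) -> np.ndarray:
    rng = _rng(config, _TEXTURE)
    color = np.asarray(config.lesion_color, dtype=float)
    texture = rng.normal(scale=3.0, size=background.shape)
    out = background.astype(float) * (1.0 - soft[..., None]) + (
        color + texture
    ) * soft[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def add_hairs(image: np.ndarray, config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_hairs`` thin dark cubic curves; return image and hair mask.

    Anti-aliasing is deliberately off so the returned mask is exact:
    every drawn pixel is strictly darker than it was, pixel for pixel.
    """
    h, w = image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    if config.n_hairs == 0:
        return image, mask
    rng = _rng(config, _HAIR)
    t_lo, t_hi = config.hair_thickness_range
    radii = [r for r in range(0, 8) if t_lo <= 2 * r + 1 <= t_hi] or [max(0, (t_lo - 1) // 2)]
    for _ in range(config.n_hairs):
        # cubic Bezier through 4 random control points spanning the frame
        pts = rng.uniform([-0.1 * h, -0.1 * w], [1.1 * h, 1.1 * w], size=(4, 2))
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        curve = (
            (1 - t) ** 3 * pts[0]
            + 3 * (1 - t) ** 2 * t * pts[1]
            + 3 * (1 - t) * t**2 * pts[2]
            + t**3 * pts[3]
        )
        radius = int(rng.choice(radii))
        for y, x in np.rint(curve).astype(int):
            if radius == 0:
                if 0 <= y < h and 0 <= x < w:
                    mask[y, x] = True
            else:
                rr, cc = disk((y, x), radius + 0.5, shape=(h, w))
                mask[rr, cc] = True
    out = image.copy()
    darker = image[mask].astype(np.int16) // 4  # strictly darker wherever > 0
    out[mask] = np.minimum(darker, np.maximum(image[mask].astype(np.int16) - 1, 0)).astype(
        np.uint8
    )
    return out, mask


def add_artifacts(image: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Apply the enabled acquisition artifacts (ruler, bubble, dark corner)."""
    if not config.artifact_flags:
        return image
    rng = _rng(config, _ARTIFACT)
    h, w = image.shape[:2]
    out = image.astype(float)
    if "ruler" in config.artifact_flags:
        y0 = 4
        for x in range(8, w - 4, 12):  # evenly spaced dark ticks on the top edge
            out[y0 : y0 + 7, x : x + 2] = 60.0
    if "bubble" in config.artifact_flags:
        cy = rng.uniform(0.3 * h, 0.7 * h)
        cx = rng.uniform(0.3 * w, 0.7 * w)
        radius = 0.12 * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - cy, xx - cx)
        ring = np.abs(d - radius) < 1.5
        out[ring] += 60.0
    if "dark_corner" in config.artifact_flags:
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
        r0 = 0.55 * min(h, w)
        falloff = np.clip((d - r0) / max(d.max() - r0, 1.0), 0.0, 1.0)
        out *= (1.0 - 0.6 * falloff)[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def make_sample(config: SynthConfig) -> SynthSample:
    """Compose one full sample: background → lesion → hairs → artifacts."""
    background = generate_background(config)
    soft, gt_mask = _lesion_field(config)
    clean = _compose_lesion(background, soft, config)
    hairy, hair_mask = add_hairs(clean, config)
    return SynthSample(
        image=add_artifacts(hairy, config),
        gt_mask=gt_mask,
        gt_box=tight_box(gt_mask),
        hair_mask=hair_mask,
        hairless_image=add_artifacts(clean, config),
    )


def _sample_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def make_dataset(
    n: int, config: SynthConfig, out_dir: str | Path | None = None
) -> list[SynthSample]:
    """Generate ``n`` samples with per-sample seeds derived from the master.

    Seeds are derived by a counter-based scheme, so sample ``i`` is the
    same regardless of how many other samples are generated.  When
    ``out_dir`` is given, writes ``images/``, ``masks/`` and ``labels/``
    (PNG images, {0,255} PNG masks, normalized center-format label
    files).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    samples = []
    for i in range(n):
        cfg = replace(config, seed=_sample_seed(config.seed, i))
        samples.append(make_sample(cfg))
    if out_dir is not None:
        out = Path(out_dir)
        for i, s in enumerate(samples):
            stem = f"sample_{i:04d}"
            save_image(out / "images" / f"{stem}.png", s.image)
            save_mask(out / "masks" / f"{stem}.png", s.gt_mask)
            (out / "labels").mkdir(parents=True, exist_ok=True)
            write_label_file(
                out / "labels" / f"{stem}.txt",
                corners_to_center(s.gt_box, config.width, config.height),
            )
    return samples
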