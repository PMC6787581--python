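"""End-to-end four-stage segmentation pipeline.

Stage order is fixed: (1) hair removal, (2) lesion localization,
(3) rectangle-initialized GrabCut at the input resolution, (4)
morphological cleanup.  The output mask always has the input image's
extent; when detection fails the image is reported as undetected and an
empty mask is emitted.

For very large inputs GrabCut can optionally run at a capped working
resolution (``grabcut_max_size``), with the mask upsampled back by
nearest neighbor; by default segmentation runs at full resolution.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage.transform import resize

from .boxes import BoundingBox, expand_box
from .detection import LabelFileDetector, OracleDetector, detect_lesion, fallback_detector
from .grabcut import GrabCutConfig, grabcut_segment
from .hair_removal import HairRemovalParams, remove_hairs
from .io import load_image, load_mask, save_mask
from .metrics import evaluate_dataset
from .synthetic import tight_box

__all__ = ["PipelineConfig", "PipelineResult", "segment_image", "run_batch", "parse_config_file"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs with documented defaults.

    ``detector`` selects the box source: "fallback" (classical
    locator), "oracle" (ground-truth boxes from the dataset's label
    files) or "labels" (boxes from an external label directory).
    ``margin_fraction`` grows the detected box per side before GrabCut.
    """

    hair_removal: bool = True
    hair_params: HairRemovalParams = field(default_factory=HairRemovalParams)
    detector: str = "fallback"
    labels_dir: Optional[str] = None
    margin_fraction: float = 0.05
    grabcut: GrabCutConfig = field(default_factory=GrabCutConfig)
    grabcut_max_size: Optional[int] = None
    postprocess_kernel: int = 5
    do_postprocess: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detector not in ("fallback", "oracle", "labels"):
            raise ValueError(f"unknown detector: {self.detector}")
        if self.margin_fraction < 0:
            raise ValueError("margin_fraction must be >= 0")


@dataclass
class PipelineResult:
    mask: np.ndarray
    box: Optional[BoundingBox]
    detected: bool
    timings: dict[str, float]


# flat config file keys -> (section, field, parser)
_CONFIG_KEYS = {
    "hair_removal": ("root", "hair_removal", lambda v: v.lower() in ("1", "true", "yes", "on")),
    "detector": ("root", "detector", str),
    "labels_dir": ("root", "labels_dir", str),
    "margin_fraction": ("root", "margin_fraction", float),
    "postprocess_kernel": ("root", "postprocess_kernel", int),
    "do_postprocess": ("root", "do_postprocess", lambda v: v.lower() in ("1", "true", "yes", "on")),
    "grabcut_max_size": ("root", "grabcut_max_size", int),
    "seed": ("root", "seed", int),
    "grabcut.components": ("grabcut", "components", int),
    "grabcut.gamma": ("grabcut", "gamma", float),
    "grabcut.iterations": ("grabcut", "max_iterations", int),
    "grabcut.tolerance": ("grabcut", "tolerance", float),
    "grabcut.connectivity": ("grabcut", "connectivity", int),
    "hair.line_length": ("hair", "line_length", int),
    "hair.closing_threshold": ("hair", "closing_threshold", int),
    "hair.min_hair_length": ("hair", "min_hair_length", int),
    "hair.max_hair_thickness": ("hair", "max_hair_thickness", int),
    "hair.median_max_window": ("hair", "median_max_window", int),
}


def parse_config_file(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    root: dict = {}
    grabcut: dict = {}
    hair: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown config key: {key}")
        section, name, parse = _CONFIG_KEYS[key]
        {"root": root, "grabcut": grabcut, "hair": hair}[section][name] = parse(value)
    cfg = PipelineConfig(**root)
    if grabcut:
        cfg = replace(cfg, grabcut=replace(cfg.grabcut, **grabcut))
    if hair:
        cfg = replace(cfg, hair_params=replace(cfg.hair_params, **hair))
    return cfg


def _grabcut_at_scale(
    image: np.ndarray, rect: BoundingBox, config: PipelineConfig
) -> np.ndarray:
    h, w = image.shape[:2]
    cap = config.grabcut_max_size
    gc = replace(config.grabcut, seed=config.seed)
    if cap is None or max(h, w) <= cap:
        return grabcut_segment(image, rect, gc)
    scale = cap / max(h, w)
    wh, ww = max(2, round(h * scale)), max(2, round(w * scale))
    small = np.clip(
        np.rint(resize(image, (wh, ww), anti_aliasing=True, preserve_range=True)),
        0,
        255,
    ).astype(np.uint8)
    srect = BoundingBox(
        rect.x1 * ww / w, rect.y1 * wh / h, rect.x2 * ww / w, rect.y2 * wh / h
    )
    small_mask = grabcut_segment(small, srect, gc)
    return (
        resize(small_mask.astype(float), (h, w), order=0, preserve_range=True) > 0.5
    )


def segment_image(
    image: np.ndarray | str | Path,
    config: PipelineConfig = PipelineConfig(),
    gt_box: Optional[BoundingBox] = None,
    label_path: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the four-stage pipeline on one image.

    ``gt_box`` feeds the oracle detector; ``label_path`` feeds the
    label-file detector.  The returned mask has the input extent; on
    detection failure it is empty and ``detected`` is false.
    """
    if isinstance(image, (str, Path)):
        image = load_image(image)
    image = np.asarray(image)
    h, w = image.shape[:2]
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.hair_removal:
        working = remove_hairs(image, config.hair_params)
    else:
        working = image
    timings["hair_removal"] = time.perf_counter() - t0
    logger.info("stage=hair_removal enabled=%s elapsed=%.3fs", config.hair_removal, timings["hair_removal"])

    t0 = time.perf_counter()
    if config.detector == "oracle":
        detector = OracleDetector(gt_box) if gt_box is not None else (lambda img: None)
    elif config.detector == "labels":
        detector = (
            LabelFileDetector(label_path) if label_path is not None else (lambda img: None)
        )
    else:
        detector = fallback_detector
    box = detect_lesion(working, detector)
    timings["detection"] = time.perf_counter() - t0
    logger.info("stage=detection detector=%s box=%s elapsed=%.3fs", config.detector, box, timings["detection"])

    if box is None:
        logger.warning("lesion undetected; emitting an empty mask")
        return PipelineResult(np.zeros((h, w), bool), None, False, timings)

    t0 = time.perf_counter()
    rect = expand_box(box, config.margin_fraction, w, h)
    try:
        mask = _grabcut_at_scale(working, rect, config)
    except Exception as exc:  # degenerate rectangles (e.g. full frame)
        logger.warning("grabcut failed (%s); emitting an empty mask", exc)
        return PipelineResult(np.zeros((h, w), bool), box, True, timings)
    timings["grabcut"] = time.perf_counter() - t0
    logger.info("stage=grabcut rect=%s elapsed=%.3fs", rect, timings["grabcut"])

    t0 = time.perf_counter()
    if config.do_postprocess:
        from .metrics import postprocess

        mask = postprocess(mask, config.postprocess_kernel)
    timings["postprocess"] = time.perf_counter() - t0
    logger.info("stage=postprocess elapsed=%.3fs", timings["postprocess"])
    return PipelineResult(mask, box, True, timings)


def run_batch(
    input_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Segment every image under ``input_dir`` and evaluate when possible.

    Expects the dataset layout written by the synthetic generator:
    ``images/*.png`` with optional ``masks/<stem>.png`` ground-truth
    masks and ``labels/<stem>.txt`` box files.  Images are processed in
    sorted order; predicted masks are written to ``out_dir`` when
    given.  The report contains segmentation metrics when ground-truth
    masks are present, and detection columns when label files are.
    """
    input_dir = Path(input_dir)
    image_dir = input_dir / "images" if (input_dir / "images").is_dir() else input_dir
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise ValueError(f"no images found under {image_dir}")

    pred_masks, gt_masks, pred_boxes, gt_boxes, ids, det_rows = [], [], [], [], [], []
    for path in paths:
        stem = path.stem
        mask_path = input_dir / "masks" / f"{stem}.png"
        lab_path = input_dir / "labels" / f"{stem}.txt"
        gt_box = None
        if lab_path.exists():
            img_probe = load_image(path)
            gt_box = LabelFileDetector(lab_path)(img_probe)
        result = segment_image(
            path, config, gt_box=gt_box, label_path=lab_path if lab_path.exists() else None
        )
        ids.append(stem)
        pred_masks.append(result.mask)
        pred_boxes.append(result.box)
        det_rows.append({"image_id": stem, "detected": result.detected})
        if mask_path.exists():
            gt_masks.append(load_mask(mask_path))
        if gt_box is not None:
            gt_boxes.append(gt_box)
        if out_dir is not None:
            save_mask(Path(out_dir) / f"{stem}.png", result.mask)

    have_masks = len(gt_masks) == len(pred_masks)
    have_boxes = len(gt_boxes) == len(pred_boxes)
    if have_masks:
        return evaluate_dataset(
            pred_masks,
            gt_masks,
            pred_boxes if have_boxes else None,
            gt_boxes if have_boxes else None,
            image_ids=ids,
        )
    df = pd.DataFrame(det_rows)
    if have_boxes:
        from .boxes import iou as _iou

        df["iou"] = [
            _iou(pb, gb) if pb is not None else float("nan")
            for pb, gb in zip(pred_boxes, gt_boxes)
        ]
    return df


def mask_box(mask: np.ndarray) -> Optional[BoundingBox]:
    """Tight box of a mask, or None when the mask is empty."""
    try:
        return tight_box(mask)
    except ValueError:
        return None
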