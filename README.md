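# dermseg

Automatic segmentation of skin lesions in dermoscopic images.

Accurate delineation of a pigmented lesion from the surrounding skin is
the first step of computer-aided melanoma diagnosis, and it is hard for
classical thresholding methods: lesion borders are fuzzy, contrast is
low, and images are cluttered with hairs, ruler marks, gel bubbles and
vignetted corners.  `dermseg` implements a fully automatic four-stage
pipeline for this problem, aimed at researchers who need a transparent,
dependency-light baseline and a reproducible evaluation harness:

1. **Hair removal** — dark thin hairs are detected by grayscale
   morphological closing with linear structuring elements at four
   orientations, verified by skeleton length and distance-transform
   thickness, replaced by interpolation perpendicular to the hair axis,
   and smoothed with an adaptive median filter.
2. **Lesion localization** — a pluggable detector returns one bounding
   box per image.  Backends: ground-truth oracle, label files from any
   external detector (e.g. a trained single-class network), or a
   built-in classical fallback (Otsu thresholding of the darkest
   coherent region).
3. **GrabCut segmentation** — the box initializes a trimap (outside =
   background, inside = unknown); two full-covariance RGB Gaussian
   mixture models and a contrast-sensitive smoothness prior define the
   energy

   E(s, c, θ, p) = Σᵢ [−log p(pᵢ | sᵢ, cᵢ, θ) − log π(sᵢ, cᵢ)]
                 + γ Σ_{m,n} [s_m ≠ s_n] · exp(−β‖p_m − p_n‖²),

   which is minimized by iterating component assignment, mixture
   refitting, and an exact min-cut/max-flow on the pixel graph.
4. **Post-processing** — morphological opening and closing with a 5×5
   kernel remove speckle noise and fill small holes.

The package also ships a seeded **synthetic dermoscopy generator**
(smooth skin background, irregular star-convex lesion with blurred
border, hair curves with exact masks, optional ruler/bubble/vignette
artifacts) so the whole pipeline is testable end to end without any
external dataset, and an **evaluation suite** (sensitivity,
specificity, Dice, Jaccard, pixel accuracy, and box-IOU detection
accuracy at the strict IOU > 0.8 criterion).

## Worked example

```python
import numpy as np
from dermseg import SynthConfig, make_dataset, PipelineConfig, segment_image
from dermseg.metrics import segmentation_metrics

samples = make_dataset(3, SynthConfig(seed=7))       # image + mask + box
config = PipelineConfig(detector="oracle")           # use ground-truth boxes
for i, s in enumerate(samples):
    result = segment_image(s.image, config, gt_box=s.gt_box)
    m = segmentation_metrics(result.mask, s.gt_mask)
    print(f"sample_{i:04d}  Sen={m.Sen:.3f} Spe={m.Spe:.3f} "
          f"Dic={m.Dic:.3f} Jac={m.Jac:.3f} Acc={m.Acc:.3f}")
```

prints

```
sample_0000  Sen=1.000 Spe=0.985 Dic=0.961 Jac=0.925 Acc=0.987
sample_0001  Sen=1.000 Spe=0.987 Dic=0.955 Jac=0.914 Acc=0.989
sample_0002  Sen=1.000 Spe=0.981 Dic=0.959 Jac=0.921 Acc=0.985
```

i.e. on synthetic images with hairs, every lesion pixel is recovered
(Sen = 1) and the segmentation overlaps the ground truth at Jaccard
≈ 0.92; the small specificity deficit is the blurred boundary ring
claimed by the foreground model.

The same flow is available from the shell:

```
dermseg synth --n 10 --out data --seed 0 --hairs 5
dermseg segment --in data --out out --detector oracle
dermseg evaluate --pred out --gt data/masks --out report.csv
dermseg hair-removal --in data/images/sample_0000.png --out clean.png
```

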