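# Methods

This note documents the models and numerical choices behind `dermseg`,
module by module, including the places where the design was genuinely
open and what the synthetic benchmark does and does not demonstrate.

## Pipeline model

The pipeline treats lesion segmentation as rectangle-initialized
binary labeling.  Stage order is fixed: hair removal → localization →
GrabCut → morphological cleanup.  Hair removal runs first because both
the locator and the color models are disturbed by dark elongated
occluders.  Localization produces a single axis-aligned box (one lesion
per image is assumed throughout); the box is expanded by a 5% margin
per side before segmentation because GrabCut hard-constrains every
pixel outside the rectangle to background, so a too-tight box would
irrecoverably clip the lesion.  Segmentation runs at the native input
resolution by default — the mask always has the input extent — with an
optional working-resolution cap (`grabcut_max_size`) for very large
images, where the mask is upsampled back by nearest neighbor.

## GrabCut energy and optimization

Color is modelled by two full-covariance RGB Gaussian mixtures
(foreground/background), C = 5 components each.  The energy is the sum
of a data term (negative log density of each pixel under its assigned
component plus the negative log component weight) and a
contrast-sensitive boundary term γ·exp(−β‖Δp‖²) over 8-connected
neighbor pairs with differing labels.  Parameter defaults follow
common practice for this family of models: γ = 50, and β set from the
image as 1/(2·⟨‖Δp‖²⟩) so that the exponential discriminates at the
image's own contrast level (β = 0 on constant images, reducing the
prior to a plain boundary-length penalty).  All of C, γ, connectivity,
iteration count and tolerance are config-exposed.

Optimization is block-coordinate descent: (a) each pixel is assigned
the most probable component of its class (ties to the lowest index, so
runs are deterministic); (b) mixtures are refit in closed form per
group (π = group/class size, ω = group mean, Σ = group covariance
+ 1e-3·I ridge for invertibility); (c) labels are minimized exactly by
a min-cut.  Initial component assignments come from per-class k-means
seeding with a fixed seed.  Iteration stops when labels are unchanged,
the relative energy decrease drops below 1e-3, or after 5 iterations.

The min cut is solved by Dinic's algorithm (`scipy.sparse.csgraph`)
on integer capacities.  Because the solver requires capacities below
2³¹, hard-constrained pixels are contracted into their terminal (their
boundary weights fold into neighbors' terminal capacities) rather than
modelled with huge "infinite" edges, data terms are reparameterized per
pixel by subtracting the cheaper of the two labels (a constant shift of
every cut), the excess is clipped at 1500 — far above any attainable
smoothness cost, so the argmin is unaffected — and energies are scaled
by 2²⁰ before rounding.  The resulting quantization is ~5·10⁻⁷ per
edge; tests compare cut energies to an exhaustive-enumeration oracle at
1e-4 absolute tolerance, orders of magnitude above the rounding and
below any real energy gap.  A guard stops iteration if rounding ever
produced a labeling with (exactly computed) higher energy than the
incumbent, which keeps the reported energy trace non-increasing by
construction while remaining honestly measured.

Degenerate outcomes (all rectangle pixels foreground or background)
are returned as-is with a logged warning rather than raised, since a
caller batch-processing a directory should receive the mask it can
inspect.

## Hair removal

Detection applies grayscale closing with length-9 linear structuring
elements at 0°/45°/90°/135° to each RGB channel and marks pixels whose
intensity the closing raises by more than 20 (8-bit); the union over
channels and orientations is strictly more sensitive than a single
luminance plane.  Verification keeps components with skeleton length
≥ 15 px and distance-transform thickness ≤ 9 px.  The thickness
ceiling is measured on the detected component, which is wider than the
physical hair: closing marks the hair's soft penumbra (±1–2 px per
side) and crossing hairs merge into one component with junction
bulges, so the ceiling sits near three times the physical hair width
while remaining far below lesion-scale blobs; the 15 px length floor
is what actually rejects compact artifacts.  Replacement interpolates
linearly between the two nearest clean pixels perpendicular to the
component's principal axis (quantized to 4 directions, ties toward
horizontal; the orthogonal direction is the fallback at image
borders), followed by an adaptive median filter (3×3 growing to 7×7)
applied only at replaced pixels.  Pixels outside the verified mask are
never touched, and an image with no verified hairs is returned
bit-identical.

## Lesion localization

The detector interface deliberately decouples the pipeline from any
trained model: an oracle (ground-truth boxes), a label-file reader
(normalized center-format `class x y w h` text, the common single-class
detection training format), and a classical fallback.  The fallback
resizes to 512×512, contrast-normalizes the grayscale to the 1–99
percentile range, thresholds by between-class variance maximization,
keeps the largest dark component touching fewer than 3 borders (≥ 3
borders means the "lesion" floods the frame and the image is reported
undetected), and maps the tight box back to input coordinates — hence
resolution independence.  The grid-detector mathematics used by
trained single-class locators (confidence = Pr(Object)·IOU, leaky-ReLU,
the λ-weighted sum-squared loss with λ_coord = 5 and λ_noobj = 0.5,
midpoint cell responsibility, and the (classes+5)×3 detection-layer
filter count) is provided as pure functions so each formula is testable
without a network; the width/height loss terms use √w, √h by default
with a `sqrt_wh=False` switch for the plain quadratic form, since both
appear in the literature.

## Metrics

Pixel metrics treat lesion as positive: Sen = TP/(TP+FN),
Spe = TN/(TN+FP), Dic = 2TP/(2TP+FP+FN), Jac = TP/(TP+FP+FN),
Acc = (TP+TN)/(TP+TN+FP+FN).  Ratios with zero denominators are
reported as NaN and excluded from dataset means; dataset summaries are
unweighted per-image means (the convention of the public challenge
benchmarks), not pixel-pooled.  Detection accuracy counts a box as
correct when IOU with the ground-truth box strictly exceeds 0.8; an
IOU of exactly 0.8 is a miss, and detection failures stay in the
denominator while the mean IOU is taken over detected images only.
Boxes use the half-open convention [x1,x2)×[y1,y2) everywhere, so
areas are w·h with no +1; the IOU tests pin this convention against an
integer-pixel-counting oracle.

## Synthetic generator

Each sample composes background → lesion → hairs → artifacts, all
driven by independent child streams of one seed (counter-based, so
sample i of a dataset is independent of dataset size).  Defaults were
chosen once to resemble a small dermoscopic field of view: 128×128 px,
skin tone (224, 172, 150) with ±6 low-frequency modulation, one
star-convex lesion with elliptical base of semi-axes 22–40 px, radius
profile r(φ) = base(φ)·(1 + 0.35·smooth-noise(φ)) from a short random
Fourier series, Gaussian boundary blur σ = 1.5 thresholded at 0.5
(fuzzy borders being a principal difficulty of real dermoscopy), and 5
hairs of thickness 1–3 px drawn as cubic Bézier curves without
anti-aliasing so the hair mask is exact (every hair pixel is strictly
darker than what it covers).  The ground-truth box is the tight
rectangle of the mask by construction.  Artifacts (ruler ticks, bright
bubble ring, corner vignette) are off by default and never alter the
ground truth.

What the generator does *not* emulate: real melanin/vascular texture,
multi-lobed or multi-focal lesions, specular glare, color charts, and
the color statistics of any clinical dataset.  Passing the synthetic
benchmark therefore demonstrates the correctness and stability of the
algorithmic machinery (energies, cuts, morphology, metrics) and
end-to-end plumbing — not clinical-grade accuracy on real dermoscopy,
which requires a trained locator and real images.

## Problem sizes in the test suite

The suite exercises enumeration oracles on graphs with ≤ 12 unknown
pixels (where 2ᴺ labelings are checkable), GrabCut on 80–128 px
images, and the end-to-end criterion on 25 synthetic samples — sizes
chosen so the full suite completes in about a minute on one core while
still covering every contract.

## Known limitations

- One lesion per image; no multi-object suppression.
- The fallback locator assumes the lesion is the darkest coherent
  region; it fails (by design, reporting "undetected") on low-contrast
  or frame-filling lesions.
- Inpainting quality degrades where many thick hairs cross inside the
  lesion; the adaptive median mitigates but does not remove streaks.
- No border matting: the mask is hard binary, so sub-pixel boundary
  softness is not represented.
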