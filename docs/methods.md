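# Methods

## Registration model

The cross-modality alignment is a full second-order polynomial per output
axis, twelve coefficients in the monomial basis [1, x, y, x², xy, y²],
mapping raw MUSE (moving) coordinates to H&E (fixed) coordinates. The model
is deliberately low-order: FFPE deformation is smooth and sample-specific,
rigid/affine models underfit it, and higher-order or diffeomorphic models
overfit the handful of manually picked landmarks. Landmarks are picked by a
human in both images; the package only fits, applies, inverts and scores
the transform — the point-refinement loop stays human-driven, guided by the
reported tissue-overlap Dice.

Coordinates are 0-based, x = column, y = row, pixel centers at integers.
Before fitting, x is divided by the image width and y by the image height
of the respective image (`per_axis`; a `max_dim` divisor is available).
Unit-scale coordinates keep the quadratic design matrix well conditioned at
whole-sample scales of 10³–10⁴ px; the magnitudes of fitted coefficients on
real samples (constant terms ~0.1, linear terms ~1) are consistent with
this convention, though the convention itself is a package choice — it is
configurable because printed coefficients from other implementations cannot
be reproduced exactly without knowing theirs.

Each axis is solved independently by SVD-based least squares
(`numpy.linalg.lstsq`), never normal equations. The design-matrix condition
number is checked against a cap (default 1e8); exceeding it is a hard
error, because near-degenerate landmark configurations (collinear points,
or points lying on a single conic) extrapolate wildly rather than failing
visibly. Duplicate pairs are removed before the ≥6-pair count check.

Warping follows the output→input convention: the canvas being filled is
swept and each pixel samples the source image at the transformed location
(bilinear for images, nearest for masks — nearest provably preserves
binarity). Out-of-frame samples take the fill value 0, since background is
dark in both modalities after registration. The "inverse registration" that
carries the refined annotation back to raw MUSE space is a separately
fitted transform on role-swapped points, not a numerical inversion: on
mild warps (quadratic coefficients ≲0.05–0.1 in normalized units) the
forward-then-inverse round trip lands within 0.1 px RMS at a 1000-px scale,
and the fit is unconditionally stable.

## Annotation extraction

Extraction is color-agnostic subtraction: a pixel belongs to the drawn
stroke when the maximum per-channel absolute difference between the
annotated and clean exports exceeds a threshold (default 10/255 — JPEG
re-compression leaves small nonzero differences everywhere, and this floor
clears them without losing any real overlay color). Morphological closing
with a disk (default radius 5) re-seals short stroke dropouts; note that
closing bridges gaps only up to roughly the stroke width — it cannot
reconnect the endpoints of an idealized 1-px curve, because the erosion
half removes any thin bridge the dilation builds. Hole filling uses
4-connected background against 8-connected foreground, the dual pairing
that lets a diagonal stroke chain seal its interior. The extracted mask
deliberately keeps background the pathologist enclosed (deeper tissue
layers may harbor tumor); removing it is the refinement stage's job.

## Tissue masking

The chain is: grayscale (Rec. 601 luma) → Canny edges → closing with a disk
element of size 55 → hole fill → Gaussian smoothing (window 63, σ = 53) of
the binary mask as a real image → strict threshold at > 0.1. Element and
window "sizes" are read as widths (diameter-like), the common
structuring-element convention. Canny thresholds default to gradient-
magnitude quantiles (70th/90th, σ = 1 px), which makes the chain invariant
to global intensity scaling; explicit thresholds can be set. The hole fill
sits between closing and smoothing — edges plus closing alone produce a
shell, and the solid region it encloses is what the subsequent smoothing
and thresholding expect. σ = 53 with a 63-px window is an unusual pairing
(σ far exceeds the half-width); the filter is explicitly truncated to the
window, giving near-box behavior, to honor both stated numbers rather than
reinterpret either.

The smoothing-plus-low-threshold step expands the mask outward by a fixed
~20–25 px band. On full-resolution whole-sample images this is negligible;
on small canvases it is a visible scale mismatch. This drives two package
choices: the phantom's default canvas is 1024×1024, the smallest scale at
which these fixed-size parameters operate in their intended regime, and the
refinement erosion (below) need only trim boundary artifacts, not undo the
expansion.

## Refinement and transfer

The refined annotation is the pixelwise intersection of the annotation mask
with the eroded tissue mask (disk erosion, default size 15; outside the
frame counts as background, so border-touching tissue erodes too). The
intersection happens in the fixed frame and only then is the result warped
(nearest) into raw MUSE space, where its boundary — mask minus 1-px
8-connected erosion — is drawn on the raw image as the final overlay.
The pipeline is deterministic end to end: identical inputs and parameters
yield bit-identical masks, and each run records parameter and input
checksums in its provenance block.

## Agreement metrics

Dice is computed on filled region masks (area agreement), with the
both-empty convention 1.0 and one-empty 0.0, flagged in the report.
Hausdorff is the symmetric max-of-directed-suprema between boundary point
sets, Euclidean in pixels, divided by max(height, width) of the shared
frame; a directed variant sits behind a flag. Nearest-neighbor queries use
a k-d tree; the test suite checks exact agreement with an O(n·m)
brute-force enumeration. Feature similarity is the cosine between vectors
from any deterministic image→vector callable. The built-in descriptor
(coarse multiscale intensity histograms plus gradient-orientation
histograms, fixed length) is an offline, bit-reproducible default that
captures layout and texture; it is **not** a learned feature space, and
similarity values from a pretrained CNN adapter (pluggable via the
`FeatureExtractor` contract or the CLI `plugin:` spec) will differ. Batch
summaries use linear-interpolation quantiles and the 1.5·IQR whisker rule.

## Synthetic phantoms

The generator emulates the geometry of real validation pairs, not their
appearance in detail. Tissue is a star-convex blob (radial Fourier
perturbation, total wobble ≤8% of radius, default radius 0.40·min(shape));
the tumor is a second blob at 40% of the tissue radius, offset 25% — deep
enough inside that a real annotation's margin from the tissue edge is
respected. Rendering uses an H&E-like palette (pale background, pink
stroma, purple nuclear speckle) and a fluorescence-like palette (dark
field, red nuclear / green cytoplasmic signal) with additive Gaussian noise
(σ = 0.01). The hidden moving→fixed warp is drawn in frame-centered
coordinates — quadratic coefficients up to `warp_magnitude` (default 0.05,
a mild FFPE-plausible distortion), translation/linear terms at a quarter of
it — and expanded to the standard basis, so bounded draws keep tissue in
frame; a draw that pushes tissue out raises immediately.

Landmarks sit at jittered equally spaced angles on the tissue boundary,
pulled inward by U(0, 0.2) of their distance to the centroid. The inward
scatter is essential, not cosmetic: points lying exactly on a smooth closed
boundary are nearly a conic section, which is a degenerate configuration
for a quadratic fit — the direction "off the conic" is almost
unconstrained, and a 2-px point error then produces ~30 px mapping errors
in the interior. Real picking does not produce such configurations (picked
features are near, not on, an idealized curve, and an interactive
Dice-maximization loop would reject them), so the generator does not
either. Landmark-picking error is modeled as i.i.d. Gaussian displacement
of the moving points only.

Tissue loss emulates the documented FFPE failure mode at its mechanism:
dark disk bites at the tissue edge plus a smooth local collapse of the
surrounding tissue toward each bite, composed with the polynomial warp.
The collapse makes the sample's true deformation locally non-polynomial,
so even exactly picked landmark pairs no longer follow any single degree-2
transform and registration degrades near the lost region — which is why
transfer quality drops sharply with loss while being unaffected by jitter-
free mild warps. Enclosed (non-edge) dropouts are deliberately invisible to
the pipeline: the masking chain's hole fill heals them by design.

What phantom results do not show: real stain variability, resolution and
contrast mismatch between modalities, focal blur, stitching seams, or
annotation styles beyond a single closed outline per region. Passing the
phantom suite demonstrates the geometry and the processing chain are
correct, not that the fixed default parameters are optimal for any
particular scanner or stain.

## Problem sizes and numerical choices

Many-replicate simulations (the 20-seed jitter sweep, determinism and
loss-sensitivity checks) run on 600×600 phantoms, where one full pipeline
pass takes well under a second; single-run checks of the tissue-mask
defaults use the full-scale 1024×1024 canvas. Medians across seeds, with
the same phantom reused across jitter levels (common random numbers), make
the jitter comparison insensitive to per-seed geometry. Tolerances: fitted
coefficients match generating coefficients to 1e-8 (exact interpolation is
limited only by conditioning), six-pair residuals to 1e-9 px, Dice against
counting oracles to 1e-12, Hausdorff against brute force exactly. Strict
inequality is used at the tissue threshold (> 0.1); with a dark background
the choice between strict and non-strict only matters on a measure-zero
set, and strict is documented. All randomness flows from explicit seeds;
there is no hidden global state.

## Known limitations

- The fixed-size morphology defaults (55/63/σ53) assume full-resolution
  whole-sample images; at small canvases the tissue mask over-expands.
  Parameters are configurable per run.
- Outline closing cannot bridge stroke dropouts much wider than the stroke
  itself; such exports need a larger closing radius or a cleaner export.
- The registration model is global; it cannot represent the local
  deformation around severe tissue loss (reproduced directionally by the
  phantom loss model).
- The built-in feature descriptor is not a substitute feature space for a
  pretrained CNN; deep-feature similarity values require plugging one in.
- The CLI consumes flat raster exports only; proprietary slide formats and
  annotation sidecars are out of scope.
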