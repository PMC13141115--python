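# Methods

This note records the models, conventions and design choices behind
`mifprep`, the assumptions each stage makes, and what the synthetic test
conditions do and do not demonstrate about real acquisitions.

## Data model and conventions

All rasters are 2-D unsigned-16-bit arrays in (row, col) coordinates,
0-based, origin top-left. Every arithmetic stage computes in float64,
rounds half-up (`floor(x + 0.5)`), clips to [0, 65535] and casts back, so
no stage can overflow or wrap. 8-bit input is promoted by the exact factor
257 (255 → 65535), which preserves ratios and makes the promotion
invertible. Cycles are 1-based; a manifest (CSV: cycle, channel_name,
marker, fluorophore, exposure_ms, role) must contain exactly one
`nuclear`-role channel per cycle — the pipeline's registration anchor.
The hyperstack container is a multi-page TIFF (cycle-major page order,
pages named `c{cycle}_{marker}`) with a JSON sidecar; round-trips are
bit-exact, which the determinism guarantees below rely on.

## Shading correction

Fluorescence shading is modelled as a smooth multiplicative field.
A shading-reference image (uniform fluorescent target) is floored at its
`floor_quantile` intensity (default 0.01, so dead pixels cannot blow up
the division), mean-normalized, and divided out. Mean normalization means
corrected tiles keep the reference's average brightness scale; a uniform
scene imaged under a 50% corner vignette drops from >10% to <1%
coefficient of variation. No dark-frame term is modelled; cameras with a
significant offset would need one subtracted upstream. Brightfield images
have no meaningful reference, so they are flattened retrospectively by
dividing by a heavy Gaussian blur of themselves (default σ = 50 px, well
above cellular texture at typical magnifications) and rescaling to the
original mean.

## Z-projection (chip samples)

Chip membranes hold cells at varying focal depth, so chip tiles arrive as
z-stacks. Two projections are provided: the per-pixel mean, and a
contrast-weighted mean where each slice's weight at a pixel is
`1e-6 + local variance` in a 3×3 window, normalized across z. The
weighting favours in-focus structure; on a sharp/defocused synthetic pair
it tracks the sharp slice strictly better than the plain mean. Both are
approximations of whatever proprietary weighting an acquisition vendor
uses; neither models the optics.

## Stitching

Tiles are nominally placed at `(r·H·(1−ov), c·W·(1−ov))`. For each
adjacent pair the residual offset is estimated on the nominal overlap
strip, widened by an 8 px stage-jitter margin. Plain and phase-normalized
FFT correlation both proved unreliable here: strips share only part of
their content, and on smooth, haze-dominated strips the circular
correlation peak ties between the true shift and zero. The estimator
therefore uses masked (non-circular) cross-correlation for the integer
offset, iterates the exactly-shared crop until the integer part settles,
then refines subpixel by upsampled phase correlation on that crop. The
aligned-crop Pearson correlation is the pair score; pairs scoring below
`min_correlation` (default 0.3) fall back to the nominal offset and are
flagged in the QC report. Global placement anchors the top-left tile and
accumulates pairwise offsets along a maximum-correlation spanning tree
(Prim's construction), so one bad pair cannot corrupt the grid.

Blending feathers overlaps linearly, each pixel weighted by its distance
to its tile's nearest edge, weights normalized to 1. Tiles are pasted at
integer-rounded origins — the real-valued refinement is kept as placement
metadata but the raster itself is never resampled. This choice trades
sub-pixel placement (estimates are accurate to ~0.1 px anyway) for a hard
guarantee: regions covered by one tile are bit-exact copies of the source,
and cutting a mosaic apart and re-stitching it is lossless. Jitter
recovery is reliable when jitter stays within roughly a quarter of the
overlap width; beyond that the low-score fallback engages.

## Rolling-ball background

The background under a plane is the grayscale opening with a spherical cap
`z(x, y) = sqrt(r² − x² − y²)`: erosion then dilation with the non-flat
structuring element, i.e. the upper envelope of a ball of radius `r`
rolled beneath the intensity surface. Edge handling replicates the border
pixel. The opening is anti-extensive (background ≤ image) and idempotent,
and the exact mode is verified bit-for-bit against a brute-force min/max
oracle. For radii above 16 px the plane is downscaled by `ceil(r/16)`
(local-mean), rolled at the reduced radius, upsampled bilinearly and
clamped below the original — the classical large-radius strategy; the
exact mode remains available everywhere. The default radius of 50 px must
exceed the largest genuine foreground object and is logged with every run.
Subtraction floors at zero.

## Autofluorescence subtraction

Tissue and debris autofluorescence is acquired as its own channel and
subtracted from affected marker channels: `marker − s·af`, floored at
zero. With `s = "auto"` the scale is the least-squares slope of marker on
AF restricted to pixels below the marker's median — signal-poor pixels,
so genuine staining does not inflate the estimate — clipped to [0, 3].
Which marker channels receive the correction is configuration
(`background.af_channels`), since only some fluorophore bands overlap the
autofluorescence spectrum.

## Cross-cycle registration and retention QC

Re-mounted slides drift essentially translationally between cycles, so
registration is translation-only (rotation/affine is out of scope by
design). The shift between the reference cycle's DAPI plane and each
later cycle's DAPI plane is estimated by phase cross-correlation with 10×
upsampling and applied — bilinear, border fill 0 — to *every* channel of
that cycle, keeping channels co-registered by construction. Shifts beyond
`max_shift_frac` (default 10% of the frame) are treated as failures:
flagged, zero-shift fallback, never silently applied. Retention QC
binarizes each cycle's DAPI by Otsu and reports Dice against the
reference cycle plus Pearson correlation over the union support; erasing
a fraction `ℓ` of nuclei predicts Dice `2(1−ℓ)/(2−ℓ)` (0.889 at 20%
loss), which the implementation reproduces within ±0.03. The default
Dice flag threshold (0.7) is a reporting default, not a hard gate.

## Phenotyping

Nuclei are segmented from the (registered) nuclear channel: Gaussian
smoothing (σ = 1.5 px) → Otsu threshold → hole filling → watershed on the
negated distance transform seeded at regional maxima with minimum
separation `ceil(sqrt(min_area))` → area filter (defaults 30–2000 px²) →
contiguous relabelling. External label maps (e.g. from a deep-learning
segmenter) can be imported instead and are relabelled to the same
contract. Marker channels are binarized by Otsu per channel or a fixed
threshold — membrane markers vary too widely for one global rule.

A cell's overlap fraction for marker *m* is the share of its nuclear
pixels inside *m*'s mask. Identity is assigned when a fraction reaches
the threshold (default **0.60**); among several qualifying markers the
largest fraction wins, except that a top-two gap below 0.01 is flagged as
a tie and left unassigned — reporting ambiguity is preferred to
inventing biphenotypic cells. Raising the threshold can only remove
assignments (monotonicity, property-tested). Mean intensities are
recorded for every marker with a validity flag marking values foreign to
the assigned identity: recorded, not deleted, because a macrophage's
"endothelial marker intensity" is measurable but not interpretable.

## Synthetic study conditions

The generator renders soft-edged disc nuclei (400 cells, radius
5.5 ± 0.8 px, two equal classes by default) on a 2×2 grid of 288×288
tiles at 12.5% overlap; membrane markers as dilated footprints (a ring
mode exists for stricter realism, in which the overlap rule is expected
to depend on mask post-processing); nuclear-factor markers over the
nucleus; per-channel vignettes of strength ~0.5; per-tile integer jitter
up to ±5 px; per-cycle drift up to ±8 px; stripping losses as a 0.95
per-cycle retention factor; a broad Gaussian haze (amplitude 400, scale
150 px); autofluorescent debris blobs; an optional chip-pore lattice of
small round objects; and Poisson shot noise plus Gaussian read noise
(σ = 2), all derived deterministically from one master seed. The
generator also knows the evaluation geometry: the pipeline's output frame
is anchored at the reference cycle's top-left tile, so its stage jitter is
removed before matching segmented cells to ground truth.

What passing these conditions shows: each stage inverts the corruption it
targets, parameters injected by the generator are recovered within stated
tolerances, and the complete pipeline assigns ≥95% (in practice ~100%) of
cells their generating class. What it does not show: performance on real
optics (no PSF), real histology texture, dense lymphoid aggregates with
heavy membrane contact, or rotational/nonrigid deformation — all
explicitly outside the pipeline's model.

## Problem sizes and determinism

Default test and acceptance scenes are 540×540 px (2×2 tiles) and
560×560 px (3×3 tiles) with 150–400 cells — large enough that every
stage operates in its intended regime while a full suite run stays in the
tens of seconds. The pipeline itself contains no randomness; all
stochasticity lives in the generator behind the master seed, so identical
configuration and inputs produce bit-identical hyperstacks and cell
tables, which is asserted byte-for-byte.
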