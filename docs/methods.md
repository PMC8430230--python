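# Methods

This note documents the models, parameters and design choices behind
`embryoscreen`: what the pipeline computes, what the synthetic plates
emulate (and what they deliberately do not), and where the numerically
arbitrary choices were made.

## Acquisition model

A plate is a grid of wells (default 8×12), each imaged as
`fields_per_well` overlapping tiles along the well's long axis (default
4 tiles of 512×696 px at 15% nominal overlap) and `z_planes` z-slices per
tile (default 5, 50.6 µm apart). Exactly one channel is brightfield; all
others are fluorescence. Areas are reported in µm² when `pixel_size` is
configured and px² otherwise; the unit is encoded in the results-CSV
column names.

## Preprocessing

- **Focus score**: variance of the Laplacian. Parameter-free, exactly
  invariant to additive offsets, and monotone in high-frequency content.
  Best-slice selection takes the arg-max over z; ties go to the lowest
  index so the choice is deterministic.
- **Maximum intensity projection** is the per-pixel max across z, applied
  per field *before* stitching. MIP is preferred over best-slice for
  fluorescence because spots peak on different z-planes; the generator
  guarantees (and a test asserts) that every single slice carries less
  total spot signal than the projection.
- **Stitching** places tile *i* at offset `i·(L − round(overlap·L))`,
  giving total length `n·L − (n−1)·round(overlap·L)`. Overlap strips are
  blended by linear feathering in brightfield (no seams to confuse the
  segmenter) and by pixel-wise maximum in fluorescence (spot peaks are
  preserved for detection); columns covered by a single tile always equal
  that tile exactly. Optional refinement adjusts each pairwise offset by
  an exhaustive translation search (±10 px default) over the overlap
  strip, minimising mean squared difference, with the nominal offset
  winning ties; it is off by default because the alignment-plate geometry
  leaves offsets near nominal.

## Segmentation

The reference segmenter is classical, operating on the stitched
brightfield strip under the transmitted-light convention (fish darker
than background):

1. Gaussian smoothing (σ=2), then threshold at 0.82× the image median.
   Using a relative threshold makes the mask invariant under intensity
   rescaling; the median is a robust background estimate because the fish
   covers ≲10% of the strip.
2. Morphological closing (disc r=3) with an all-true border on the
   erosion step — so a fish cropped by the image frame keeps touching the
   frame, which the partial-fish QC depends on — followed by hole
   filling.
3. The largest connected component whose area lies within the fish size
   constraints is the fish; no qualifying component means an empty well
   (a valid outcome, not an error).

The **body axis** is a polyline through per-bin centroids along the
principal axis of the mask. The anterior end is the end nearer the eye
centroid, falling back to the wider end when no eye is found.

**Eyes** are dark, high-circularity blobs (≥0.55) in the anterior half,
thresholded at the midpoint between the within-fish median intensity and
the within-fish minimum; at that midpoint the blurred-disc contour sits
at approximately the true radius, which is what makes the eye-area
morphometry accurate to within ~10% down to 6 px radius. **Yolk** is the
largest remaining dark compact region within its size window; its
caudal-most point along the axis is the trunk/tail landmark. **Tail
count** is 1 iff the region distal to that landmark meets the tail
minimum area and touches no image border (a cropped tail counts 0).

**Region partition**: every fish pixel is assigned by its projection
onto the body axis; head/trunk boundary at the posterior eye edge plus
0.05× body length, trunk/tail boundary at the yolk caudal tip,
landmark-free fallback at 0.25/0.55 of the axis span. The three regions
are disjoint and cover the mask by construction. The 0.05 offset and the
fallback fractions are package conventions; the vendor software's
internal rule is not published.

The segmenter sits behind a one-method contract so a learned model can
replace it; the generator's `truth_segmentation` provides the oracle
implementation used to isolate quantification errors from segmentation
errors in tests.

## Granule detection

Fixed operator chain: Gaussian smoothing (σ, 0 disables) → background
subtraction by grey-scale opening with a disc (rolling-ball equivalent;
radius 0 disables) → threshold → 8-connected components → area window →
containment. Containment is **centroid-inside-fish** (robust to granules
touching the outline; whether the vendor counts boundary-touching spots
is unspecified, so this is the package's convention). Thresholds are
either absolute or `median + k·σ̂` of the processed image, σ̂ from the
MAD, floored at half a grey level so noise-free images keep a finite
bar. Intensity metrics are always computed on the original image, so
integrated intensity does not depend on the detection parameters.

For speed the chain runs in a window around the fish bounding box; the
window grows whenever any above-threshold pixel touches its frame, so
the result is identical to full-frame processing (asserted against an
exhaustive flood-fill oracle).

Default parameters (σ=1.6, background radius 8, k=5, area 4–400 px²) and
the per-assay presets are calibrated on the synthetic plates in this
repository and documented as such; they make no claim of fidelity to any
vendor's settings, whose numeric values are not published.

## Quality control

Checks run in fixed order and the first failure is the reported reason:
empty well → eye count ≠ 1 → tail count ≠ 1 → fish area below minimum →
tail-region area below minimum. Excluded wells are exported with their
reason and empty metric cells; filtering happens at summary time.

## Group statistics

Unpaired two-tailed Student t (pooled variance, p from the t distribution
with n₁+n₂−2 df), mean ± sample s.d. (n−1) per condition; Welch's form
is available behind a flag. No multiple-testing correction is applied —
comparisons are reported per pair. Groups with fewer than two included
wells yield explicitly not-computable comparisons.

## The synthetic plate generator

The generator emulates the features the analysis must be robust to, not
photorealism:

- **Body**: a tapered capsule (head half-width 0.145×canvas height,
  tail 0.027×), near-horizontal (±4° jitter, emulating an alignment
  plate), darker than background (×0.62); eyes (×0.24) and yolk with its
  caudal extension (×0.30) darkest; a thin translucent fin margin
  (×0.88) around the posterior body. Presentations: `lateral_left/right`
  (1 eye), `dorsal` (2 eyes), `partial` (tail tip beyond the imaged
  strip), `absent`. Default mix ≈95% lateral / 2% dorsal / 2% partial /
  1% absent, matching the reported few-percent misalignment per plate.
- **Optics**: brightfield z-slices are blurred with σ = 2.5 px ×
  |z − z_focus|; the focus plane jitters ±1 around the stack centre.
  Fluorescent spots are Gaussian profiles (σ=2 px) whose amplitude decays
  across z from their own best slice (σ_z = 0.7 planes), so the MIP is
  genuinely required.
- **Intensities** (16-bit): brightfield background 30 000, fluorescence
  background 300; Poisson shot noise at camera gains 4 and 2 ADU/e⁻ plus
  Gaussian read noise (σ=20). At these counts (≥150 e⁻/px) the Poisson is
  Gaussian-approximated in one draw with the read noise — statistically
  indistinguishable and several times faster. Spot classes: **dim** ≈ 3×
  and **bright** ≈ 10× the single-slice background s.d. (~31), ±8%
  jitter, reproducing the dim-stem-cell vs bright-thrombocyte split.
- **Autofluorescence haze**: amplitude 800 spread over the head and yolk
  footprints with σ = 0.10× canvas height. The haze dwarfs dim spots, so
  a global threshold above it erases them — the confounder the
  local-background chain exists to beat. Its amplitude/scale are free
  generator parameters (unquantified in the field); the scale was fixed
  so that a disc-opening background estimate can absorb the haze, which
  is the regime the detection defaults are calibrated for.
- **Spot placement** samples per-region counts from configurable laws
  (Poisson or constant; the stem-cell preset uses Poisson(30) dim in the
  tail, Poisson(6) bright in the trunk), with ≥8σ pairwise separation
  and an 18 px standoff from region boundaries so that noise-free
  detection is exact and landmark jitter cannot flip region labels.
  Helper samplers build neuromast rows (hair-cell assay) and
  intersegmental-vessel combs (angiogenesis assay).
- **Determinism**: each well derives layout and render streams from the
  master seed; identical arguments and seed give bit-identical tiles and
  truth tables. Tiles are cut from one seamless per-well canvas, so
  overlap regions are identical across neighbouring tiles and stitching
  can be validated against the canvas exactly.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: deformed or curved embryos, touching debris,
pigmentation, circulation/motion blur, stage drift (tiles come from one
canvas, so registration refinement is exercised only on constructed
shifts), uneven illumination beyond a smooth 2% texture field, and any
appearance variation a learned segmenter would be needed for. Results on
real plates depend on replacing or validating the reference segmenter on
real images.

## Problem sizes used in the shipped checks

Count recovery runs on full 96-well plates (noisy and noise-free); QC
exactness on 20 plates of 12 wells (brightfield-only, 3 z-planes, with
the misoriented fraction enriched to 3/12 so every failure mode appears
on every plate); oracle equivalence on 200 random ≤64×64 images;
partition soundness on 3 full-scale wells; morphometry on eye radii
6–16 px; the irradiation contrast at n=40/40 wells (Poisson 30 vs 15).
These sizes are the package's chosen desk-scale study conditions.

## Known limitations

- The reference segmenter assumes a near-horizontal fish (alignment-plate
  geometry); it is not rotation-invariant beyond ~±10°.
- Only eye, yolk sac and tail fin are detected; heart, spine, bladder and
  otic vesicle are reserved labels for richer segmenters.
- Dim spots near the max-projection background (≈3σ single-slice) lose a
  few percent recall under default noise because the projection elevates
  the background; counts remain tightly correlated with truth (r > 0.95)
  but are not exactly equal on noisy plates.
- Registration refinement searches translations along the stitch axis
  only; no rotational or non-rigid registration, and no fluorescence
  deconvolution.
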