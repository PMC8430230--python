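# embryoscreen

Automated image analysis for high-content drug screening of zebrafish
embryos in 96-well plates — from raw per-well z-stack field images to a
per-well results table, with a synthetic plate generator standing in for
the microscope so every stage can be tested at desk scale.

## The problem

Phenotype-based screens image one anaesthetised embryo per well of a
96-well alignment plate, in brightfield plus one or two fluorescence
channels, as four overlapping fields per well and five z-planes per field
(≈3840 raw tiles per plate). Turning those tiles into per-embryo numbers
requires, per well:

1. **z-reduction** — keep the sharpest brightfield plane per field
   (variance-of-Laplacian focus score) and the per-pixel **maximum
   intensity projection** of each fluorescence stack, so labelled cells
   at any depth survive;
2. **stitching** of the four fields into one strip per channel
   (length `n·L − (n−1)·round(overlap·L)`);
3. **segmentation** of the embryo in brightfield: fish outline, eyes,
   yolk sac, and a **head / trunk / tail** partition along the body axis
   (head/trunk boundary behind the eye, trunk/tail boundary at the caudal
   tip of the yolk extension — the landmark for the caudal haematopoietic
   tissue where stem cells reside);
4. **orientation QC** — only side-on fish are analysable; a well is kept
   iff eye count = 1 and tail count = 1 and the fish/tail areas exceed
   minimums (rejects dorsal fish, partially imaged fish and empty wells
   automatically, ~5% of wells per plate);
5. **granule quantification** per fluorescence channel: smoothing →
   rolling-ball background subtraction → thresholding → connected
   components → area constraints, keeping components whose centroid lies
   inside the fish, then counting/measuring them per region. Local
   background subtraction matters because 3 dpf embryos carry strong
   head/yolk autofluorescence: a global threshold above the haze erases
   the dim GFP-lo stem cells of interest.

Group comparisons use unpaired two-tailed Student t-tests on any exported
metric, reported as mean ± s.d. per condition.

Because the screens in question depend on proprietary microscope images,
the package ships a first-class synthetic plate generator
(`embryoscreen.synthplate`) that renders model embryos — lateral, dorsal,
partially-imaged and absent presentations; eyes, yolk with caudal
extension, tail fin; dim/bright fluorescent spot classes on top of a
head/yolk autofluorescence haze; focus-dependent blur across z — with
exhaustive ground truth, so recovery can be scored exactly.

## Worked example

```sh
python examples/01_generate_and_analyze_plate.py
```

```
 well  presentation    status     reason  detected  truth
  A01       partial  excluded tail_count                40
  A02  lateral_left  included         ok      31.0     31
  A03        dorsal  excluded  eye_count                31
  A04 lateral_right  included         ok      21.0     22
  A05        absent  excluded empty_well                 0
  A06 lateral_right  included         ok      40.0     41
  A07  lateral_left  included         ok      35.0     35
  A08  lateral_left  included         ok      30.0     30
```

Each included row is one analysable side-on embryo: `detected` is the
number of fluorescent granules (stem cells) found in the tail region,
`truth` the number the generator placed there. Misoriented wells are
excluded with the failing check as the reason and contribute nothing to
downstream statistics. The other examples cover z-stack preprocessing
(`02`), segmentation + QC per presentation (`03`) and two-group
statistics (`04`).

The same pipeline runs from the shell:

```sh
synthplate --wells 96 --seed 1 --preset hspc --out plate/
embryoscreen run --config cfg.yaml --plate plate/ --out results/
embryoscreen summarize --results results/results.csv \
    --metric GFP_tail_count --groups groups.csv
```

## Layout

- `src/embryoscreen/plate_io.py` — TIFF discovery/naming, results CSV
- `src/embryoscreen/synthplate.py` — synthetic plate generator + truth
- `src/embryoscreen/preprocess.py` — focus selection, MIP, stitching
- `src/embryoscreen/segment.py` — reference segmenter, regions, morphometry
- `src/embryoscreen/quantify.py` — granule operator chain, QC rule
- `src/embryoscreen/screenrun.py` — orchestration, group statistics
- `src/embryoscreen/presets.py` — per-assay parameter bundles
- `docs/methods.md` — model, parameters, calibration and limitations
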