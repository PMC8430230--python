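"""Segment embryos in brightfield and apply the orientation QC rule.

Renders one well per presentation and shows what the reference segmenter
finds: the fish outline area, eye count, tail count and the head/trunk/
tail split — then the QC verdict.  Only side-on (lateral) fish with one
eye and one full tail pass; dorsal (two eyes), partially imaged (cropped
tail) and empty wells are excluded with a reason.
"""

import numpy as np

from embryoscreen import PlateSpec, QCCriteria, ReferenceSegmenter, SizeConstraints
from embryoscreen.preprocess import preprocess_well
from embryoscreen.quantify import apply_qc
from embryoscreen.synthplate import NoiseParams, render_well, sample_layout

spec = PlateSpec()
noise = NoiseParams()
shape = (spec.tile_shape[0], spec.stitched_width)
constraints = SizeConstraints.for_canvas(shape)
criteria = QCCriteria.for_canvas(shape)
segmenter = ReferenceSegmenter()

for presentation in ("lateral_left", "dorsal", "partial", "absent"):
    rng = np.random.default_rng(5)
    layout = sample_layout(presentation, spec, rng)
    well = render_well(layout, [], spec, noise, rng)
    stitched = preprocess_well(well.fields, spec)
    seg = segmenter.segment(stitched.channel("BF"), constraints)
    qc = apply_qc(seg, criteria)
    if seg is None:
        print(f"{presentation:>13}: no fish found -> {qc.reason}")
        continue
    print(f"{presentation:>13}: area={seg.fish_area:7.0f} px2 "
          f"(truth {well.truth.fish_area:7.0f}), eyes={seg.eye_count}, "
          f"tail={seg.tail_count}, regions h/t/t="
          f"{seg.region_area('head'):.0f}/{seg.region_area('trunk'):.0f}/"
          f"{seg.region_area('tail'):.0f} px2 -> "
          f"{'included' if qc.included else 'excluded (' + qc.reason + ')'}")
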