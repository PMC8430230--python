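"""Generator ground-truth consistency, determinism and confounder structure."""

import numpy as np
import pytest
from scipy import ndimage

from embryoscreen.plate_io import ChannelRole, PlateSpec
from embryoscreen.preprocess import max_project, stitch_fields
from embryoscreen.synthplate import (
    NoiseParams,
    SpotLaw,
    allocate_presentations,
    generate_plate,
    render_well,
    sample_layout,
    sample_spots,
    truth_segmentation,
)

from conftest import SMALL_LAWS, make_well


class TestLayouts:
    @pytest.mark.parametrize(
        "presentation,n_eyes", [("lateral_left", 1), ("lateral_right", 1),
                                ("dorsal", 2), ("partial", 1), ("absent", 0)]
    )
    def test_eye_count_by_presentation(self, small_spec, presentation, n_eyes):
        lay = sample_layout(presentation, small_spec, np.random.default_rng(0))
        assert len(lay.eye_centres) == n_eyes

    def test_partial_tail_tip_leaves_canvas(self, small_spec):
        lay = sample_layout("partial", small_spec, np.random.default_rng(0))
        tip_x = lay.to_canvas(lay.length, 0)[0]
        assert tip_x > lay.canvas_shape[1]

    def test_anatomy_inside_body(self, small_spec):
        lay = sample_layout("lateral_left", small_spec, np.random.default_rng(1))
        body = lay.body_mask()
        assert (lay.yolk_mask() & ~body).sum() == 0
        for m in lay.eye_masks():
            assert (m & ~body).sum() == 0

    def test_region_map_partitions_body(self, small_spec):
        lay = sample_layout("lateral_left", small_spec, np.random.default_rng(2))
        body = lay.body_mask()
        rmap = lay.region_map(body)
        assert ((rmap > 0) == body).all()


class TestSpots:
    def test_spot_regions_match_their_positions(self, small_spec, noise):
        rng = np.random.default_rng(0)
        lay = sample_layout("lateral_left", small_spec, rng)
        spots = sample_spots(lay, SMALL_LAWS, small_spec, noise, rng)
        rmap = lay.region_map()
        names = {1: "head", 2: "trunk", 3: "tail"}
        for sp in spots:
            x, y = sp.centre
            assert names[rmap[int(y), int(x)]] == sp.region

    def test_dim_below_bright_amplitude(self, small_spec, noise):
        rng = np.random.default_rng(0)
        lay = sample_layout("lateral_left", small_spec, rng)
        spots = sample_spots(lay, SMALL_LAWS, small_spec, noise, rng)
        dims = [s.amplitude for s in spots if s.amplitude_class == "dim"]
        brights = [s.amplitude for s in spots if s.amplitude_class == "bright"]
        assert dims and brights and max(dims) < min(brights)

    def test_spot_outside_canvas_rejected(self, small_spec, noise):
        rng = np.random.default_rng(0)
        lay = sample_layout("lateral_left", small_spec, rng)
        spots = sample_spots(lay, SMALL_LAWS, small_spec, noise, rng)
        from dataclasses import replace
        bad = replace(spots[0], centre=(1e6, 10.0))
        with pytest.raises(ValueError, match="outside"):
            render_well(lay, [bad], small_spec, noise, rng)


class TestRenderedWells:
    def test_brightfield_polarity_and_darkest_anatomy(self, lateral_well):
        bf = lateral_well.canvases["BF"][lateral_well.truth.layout.z_focus].astype(float)
        lay = lateral_well.truth.layout
        body = lay.body_mask()
        eye = lay.eye_masks()[0]
        background = np.median(bf[~body])
        assert bf[body].mean() < 0.8 * background
        assert bf[eye].mean() < bf[body & ~eye].mean()
        lay._cache.clear()

    def test_absent_well_is_background_only(self, absent_well):
        tr = absent_well.truth
        assert tr.fish_area == 0 and tr.spots == () and tr.eye_areas == ()
        bf = absent_well.canvases["BF"][0].astype(float)
        assert bf.std() / bf.mean() < 0.05  # no large dark object

    def test_haze_confounds_naive_global_threshold(self, small_spec, noise):
        """Zero spots + autofluorescence: naive thresholding finds objects."""
        wr = make_well(small_spec, seed=9, noise=noise, laws=())
        assert wr.truth.counts() == {}
        mip = max_project(list(wr.canvases["GFP"]))
        thr = noise.fl_background + 0.4 * noise.haze_amplitude
        labels, n = ndimage.label(mip > thr)
        head = wr.truth.layout.region_map() == 1
        wr.truth.layout._cache.clear()
        hits = set(np.unique(labels[head])) - {0}
        assert len(hits) > 0

    def test_mip_needed_single_slices_miss_signal(self, lateral_well):
        stack = lateral_well.canvases["GFP"].astype(np.int64)
        mip = stack.max(axis=0)
        for z in range(stack.shape[0]):
            assert stack[z].sum() < mip.sum()

    def test_tiles_are_exact_canvas_crops(self, small_spec, noise_free):
        """Stitch-geometry: tiles equal canvas windows at nominal offsets,
        and stitching them reproduces the canvas outside overlap seams."""
        wr = make_well(small_spec, seed=2, noise=noise_free)
        canvas = wr.canvases["BF"][2]
        tiles = [f.pixels for f in wr.fields
                 if f.channel == "BF" and f.z_index == 2]
        h, w = small_spec.tile_shape
        stride = w - round(small_spec.overlap_fraction * w)
        for i, tile in enumerate(tiles):
            assert (tile == canvas[:, i * stride : i * stride + w]).all()
        stitched, offsets = stitch_fields(tiles, small_spec.overlap_fraction)
        assert stitched.shape == canvas.shape
        cover = np.zeros(canvas.shape[1], dtype=int)
        for off in offsets:
            cover[off : off + w] += 1
        single = cover == 1
        assert (stitched[:, single] == canvas[:, single]).all()


class TestPlateGeneration:
    def test_allocation_honours_integer_counts(self):
        rng = np.random.default_rng(0)
        mix = {"lateral_left": 46, "lateral_right": 45, "dorsal": 2,
               "partial": 2, "absent": 1}
        alloc = allocate_presentations(96, mix, rng)
        assert len(alloc) == 96
        for k, v in mix.items():
            assert alloc.count(k) == v

    def test_allocation_largest_remainder_from_proportions(self):
        rng = np.random.default_rng(0)
        alloc = allocate_presentations(
            10, {"lateral_left": 0.72, "dorsal": 0.28}, rng
        )
        assert alloc.count("lateral_left") == 7 and alloc.count("dorsal") == 3

    def test_negative_mix_rejected(self):
        with pytest.raises(ValueError):
            allocate_presentations(10, {"lateral_left": -1.0}, np.random.default_rng(0))

    def test_determinism_bit_identical(self, small_spec):
        kw = dict(n_wells=3, spec=small_spec, seed=42, laws=SMALL_LAWS)
        p1, p2 = generate_plate(**kw), generate_plate(**kw)
        for well in p1.wells():
            assert p1.truth[well].counts() == p2.truth[well].counts()
            r1, r2 = p1.render(well), p2.render(well)
            for f1, f2 in zip(r1.fields, f2 := r2.fields):
                assert f1.key == f2.key
                assert (f1.pixels == f2.pixels).all()

    def test_different_seeds_differ(self, small_spec):
        p1 = generate_plate(n_wells=1, spec=small_spec, seed=1, laws=SMALL_LAWS)
        p2 = generate_plate(n_wells=1, spec=small_spec, seed=2, laws=SMALL_LAWS)
        a = p1.render("A01").fields[0].pixels
        b = p2.render("A01").fields[0].pixels
        assert (a != b).any()

    def test_truth_tables_self_consistent(self, small_spec):
        plate = generate_plate(n_wells=4, spec=small_spec, seed=7, laws=SMALL_LAWS)
        counts = plate.counts_table()
        for well in plate.wells():
            tally = plate.truth[well].counts()
            sub = counts[counts.well == well]
            for _, row in sub.iterrows():
                assert row["count"] == tally.get((row.channel, row.region), 0)

    def test_constant_zero_law_gives_zero_counts(self, small_spec):
        plate = generate_plate(
            n_wells=2, spec=small_spec, seed=1,
            laws=(SpotLaw("GFP", "tail", "dim", "constant", 0),),
        )
        assert all(plate.truth[w].counts() == {} for w in plate.wells())

    def test_poisson_law_sample_mean(self, small_spec):
        """Mean of per-well truth counts within 3 s.e. of the law mean."""
        plate = generate_plate(
            n_wells=48, spec=small_spec, seed=5,
            presentation_mix={"lateral_left": 1.0},
            laws=(SpotLaw("GFP", "tail", "dim", "poisson", 12.0),),
        )
        xs = [plate.truth[w].count("GFP", "tail") for w in plate.wells()]
        se = np.sqrt(12.0 / len(xs))
        assert abs(np.mean(xs) - 12.0) <= 3 * se

    def test_write_emits_tiles_and_truth(self, small_spec, tmp_path):
        plate = generate_plate(n_wells=1, spec=small_spec, seed=3, laws=SMALL_LAWS)
        out = plate.write(tmp_path)
        tiles = list(out.glob("*.tif"))
        assert len(tiles) == small_spec.fields_per_well * small_spec.z_planes * 2
        assert (out / "truth_counts.csv").exists()
        assert (out / "truth_layout.csv").exists()


class TestTruthSegmentation:
    def test_oracle_matches_truth_geometry(self, small_spec):
        plate = generate_plate(n_wells=1, spec=small_spec, seed=3, laws=SMALL_LAWS,
                               presentation_mix={"lateral_left": 1.0})
        tr = plate.truth["A01"]
        seg = truth_segmentation(tr)
        assert seg.fish_area == tr.fish_area
        assert seg.eye_count == 1
        assert seg.tail_count == 1
        assert seg.region_area("tail") == tr.region_areas["tail"]

    def test_oracle_none_for_absent(self, small_spec):
        plate = generate_plate(n_wells=1, spec=small_spec, seed=3, laws=(),
                               presentation_mix={"absent": 1.0})
        assert truth_segmentation(plate.truth["A01"]) is None
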