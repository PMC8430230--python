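"""Granule operator chain vs flood-fill oracle, region metrics and QC rules."""

import numpy as np
import pytest

from embryoscreen.preprocess import preprocess_well
from embryoscreen.quantify import (
    Granule,
    GranuleParams,
    GranuleSet,
    QCCriteria,
    QCResult,
    apply_qc,
    assign_regions,
    detect_granules,
    region_metrics,
)
from embryoscreen.segment import ReferenceSegmenter, SizeConstraints

from conftest import flood_fill_components, make_well

RAW = GranuleParams(
    smoothing_sigma=0.0, background_radius=0.0,
    threshold_mode="absolute", threshold_value=10.0,
    min_area=1.0, max_area=1e9,
)


def _disc_image(centres, radius=3, value=50, shape=(64, 64)):
    img = np.zeros(shape, dtype=np.float64)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cx, cy) in centres:
        img[(xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2] = value
    return img


class TestDetectGranules:
    def test_area_filter_drops_small_discs(self):
        """10 well-separated discs, 2 below min_area -> count 8."""
        big = [(8 + 14 * i, 10) for i in range(4)] + [(8 + 14 * i, 30) for i in range(4)]
        img = _disc_image(big, radius=3)
        small = _disc_image([(10, 50), (30, 50)], radius=1)
        img = np.maximum(img, small)
        params = GranuleParams(
            smoothing_sigma=0.0, background_radius=0.0,
            threshold_mode="absolute", threshold_value=10.0,
            min_area=10.0, max_area=100.0,
        )
        got = detect_granules(img, params, np.ones_like(img, bool))
        assert len(got) == 8
        oracle = flood_fill_components(img, 10.0)
        assert len([c for c in oracle if 10 <= c["area"] <= 100]) == 8

    def test_centroid_outside_fish_excluded(self):
        img = _disc_image([(10, 10), (40, 40)])
        mask = np.zeros_like(img, bool)
        mask[:20, :20] = True  # only the first disc is inside the fish
        got = detect_granules(img, RAW, mask)
        assert len(got) == 1
        assert got.granules[0].centroid == pytest.approx((10, 10))

    def test_blank_image_empty_set(self):
        got = detect_granules(np.zeros((32, 32)), RAW, np.ones((32, 32), bool))
        assert len(got) == 0

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_granules(np.zeros((8, 8)), RAW, np.ones((9, 8), bool))

    def test_metrics_use_original_image(self):
        """Integrated intensity sums raw pixels even with smoothing on."""
        img = _disc_image([(20, 20)], radius=3, value=200)
        params = GranuleParams(
            smoothing_sigma=1.0, background_radius=0.0,
            threshold_mode="absolute", threshold_value=30.0,
            min_area=1.0, max_area=1e9,
        )
        got = detect_granules(img, params, np.ones_like(img, bool))
        assert len(got) == 1
        g = got.granules[0]
        # component pixels carry either 200 or 0 in the original image
        assert g.integrated_intensity == pytest.approx(
            200.0 * np.count_nonzero(img[img > 0]) , rel=0.35
        )
        assert g.integrated_intensity == g.mean_intensity * g.area

    def test_monotonicity_adding_far_disc_adds_one(self):
        params = GranuleParams(
            smoothing_sigma=1.0, background_radius=5.0,
            threshold_mode="absolute", threshold_value=10.0,
            min_area=3.0, max_area=500.0,
        )
        base = _disc_image([(12, 12), (40, 12)], radius=3, shape=(96, 96))
        n0 = len(detect_granules(base, params, np.ones_like(base, bool)))
        far = np.maximum(base, _disc_image([(70, 70)], radius=3, shape=(96, 96)))
        n1 = len(detect_granules(far, params, np.ones_like(base, bool)))
        assert n1 == n0 + 1

    def test_haze_suppressed_by_local_background_not_by_global(self, noise):
        """Head autofluorescence: k-sigma over the rolling-ball background
        yields zero granules, a low absolute threshold floods the head."""
        from embryoscreen.plate_io import PlateSpec

        full_spec = PlateSpec()  # haze scale the defaults are calibrated for
        wr = make_well(full_spec, seed=21, noise=noise, laws=())
        sw = preprocess_well(wr.fields, full_spec)
        cons = SizeConstraints.for_canvas(sw.channel("BF").shape)
        seg = ReferenceSegmenter().segment(sw.channel("BF"), cons)
        img = sw.channel("GFP")
        local = GranuleParams()  # the calibrated k-sigma defaults
        naive = GranuleParams(
            smoothing_sigma=1.6, background_radius=0.0,
            threshold_mode="absolute",
            threshold_value=noise.fl_background + 0.4 * noise.haze_amplitude,
            min_area=4.0, max_area=400.0,
        )
        assert len(detect_granules(img, local, seg.fish_mask)) == 0
        assert len(detect_granules(img, naive, seg.fish_mask)) > 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_images_match_flood_fill_exactly(self, seed):
        """Absolute-threshold detection == exhaustive oracle on small images."""
        rng = np.random.default_rng(seed)
        h, w = rng.integers(8, 65, 2)
        img = rng.integers(0, 40, (h, w)).astype(float)
        # sprinkle some bright structure
        for _ in range(rng.integers(0, 6)):
            y, x = rng.integers(0, h), rng.integers(0, w)
            img[max(0, y - 2) : y + 2, max(0, x - 2) : x + 2] += rng.integers(20, 60)
        mask = np.ones((h, w), bool)
        if seed % 2:
            mask[:, : w // 2] = False
        got = detect_granules(img, RAW, mask)
        oracle = flood_fill_components(img, RAW.threshold_value, mask)
        assert len(got) == len(oracle)
        got_sorted = sorted((g.area, g.integrated_intensity) for g in got)
        ora_sorted = sorted((c["area"], c["integrated_intensity"]) for c in oracle)
        for (ga, gi), (oa, oi) in zip(got_sorted, ora_sorted):
            assert ga == oa
            assert gi == pytest.approx(oi, abs=1e-9)


def _seg_for(well_render, spec):
    sw = preprocess_well(well_render.fields, spec)
    cons = SizeConstraints.for_canvas(sw.channel("BF").shape)
    return ReferenceSegmenter().segment(sw.channel("BF"), cons), sw


class TestRegions:
    def test_granule_at_truth_tail_coordinate_labelled_tail(
        self, small_spec, lateral_well
    ):
        seg, sw = _seg_for(lateral_well, small_spec)
        params = GranuleParams()
        gs = assign_regions(
            detect_granules(sw.channel("GFP"), params, seg.fish_mask), seg
        )
        truth_by_pos = {
            (round(s.centre[0]), round(s.centre[1])): s.region
            for s in lateral_well.truth.spots
        }
        matched = 0
        for g in gs:
            key = min(
                truth_by_pos,
                key=lambda p: (p[0] - g.centroid[0]) ** 2 + (p[1] - g.centroid[1]) ** 2,
            )
            if (key[0] - g.centroid[0]) ** 2 + (key[1] - g.centroid[1]) ** 2 < 16:
                assert g.region == truth_by_pos[key]
                matched += 1
        assert matched > 0

    def test_boundary_pixel_takes_map_label(self, small_spec, lateral_well):
        seg, _ = _seg_for(lateral_well, small_spec)
        ys, xs = np.nonzero(seg.region_map == 3)
        g = Granule(centroid=(float(xs[0]), float(ys[0])), area=5,
                    integrated_intensity=10, mean_intensity=2)
        out = assign_regions(GranuleSet([g], GranuleParams()), seg)
        assert out.granules[0].region == "tail"

    def test_empty_set_stays_empty(self, small_spec, lateral_well):
        seg, _ = _seg_for(lateral_well, small_spec)
        out = assign_regions(GranuleSet([], GranuleParams()), seg)
        assert len(out) == 0


class TestRegionMetrics:
    def test_totals_and_mean(self):
        gs = GranuleSet(
            [
                Granule((0, 0), 10, 100, 10, "tail"),
                Granule((1, 1), 20, 200, 10, "tail"),
                Granule((2, 2), 30, 300, 10, "tail"),
            ],
            GranuleParams(),
        )
        m = region_metrics(gs)
        assert m["tail"]["total_granule_area"] == 60
        assert m["tail"]["mean_granule_area"] == 20
        assert m["fish"]["count"] == 3

    def test_empty_region_mean_is_missing_not_zero(self):
        m = region_metrics(GranuleSet([], GranuleParams()))
        assert m["head"]["mean_granule_area"] is None
        assert m["head"]["total_granule_area"] == 0

    def test_region_counts_sum_to_whole_fish(self, small_spec, lateral_well):
        seg, sw = _seg_for(lateral_well, small_spec)
        gs = assign_regions(
            detect_granules(sw.channel("GFP"), GranuleParams(), seg.fish_mask), seg
        )
        m = region_metrics(gs, seg)
        assert (
            m["head"]["count"] + m["trunk"]["count"] + m["tail"]["count"]
            == m["fish"]["count"]
        )


class _FakeSeg:
    """Minimal stand-in exposing the attributes QC reads."""

    def __init__(self, eye_count, tail_count, fish_area, tail_area):
        self._e, self._t = eye_count, tail_count
        self._fa, self._ta = fish_area, tail_area
        self.fish_mask = np.ones((4, 4), bool)

    @property
    def eye_count(self):
        return self._e

    @property
    def tail_count(self):
        return self._t

    @property
    def fish_area(self):
        return self._fa

    def region_area(self, name):
        return self._ta


class TestQC:
    CRIT = QCCriteria(min_fish_area=100.0, min_tail_area=10.0)

    def test_none_segmentation_is_empty_well(self):
        assert apply_qc(None, self.CRIT) == QCResult(False, "empty_well")

    def test_two_eyes_excluded_as_eye_count(self):
        assert apply_qc(_FakeSeg(2, 1, 500, 50), self.CRIT).reason == "eye_count"

    def test_cropped_tail_excluded_as_tail_count(self):
        assert apply_qc(_FakeSeg(1, 0, 500, 50), self.CRIT).reason == "tail_count"

    def test_small_fish_excluded_as_fish_area(self):
        assert apply_qc(_FakeSeg(1, 1, 50, 50), self.CRIT).reason == "fish_area"

    def test_small_tail_region_excluded_as_tail_area(self):
        assert apply_qc(_FakeSeg(1, 1, 500, 5), self.CRIT).reason == "tail_area"

    def test_check_order_reports_first_failure(self):
        # fails every check; the eye-count failure is reported
        assert apply_qc(_FakeSeg(0, 0, 0, 0), self.CRIT).reason == "eye_count"

    def test_good_lateral_fish_included(self):
        assert apply_qc(_FakeSeg(1, 1, 500, 50), self.CRIT) == QCResult(True, "ok")

    def test_params_validation(self):
        with pytest.raises(ValueError):
            GranuleParams(min_area=10, max_area=5)
        with pytest.raises(ValueError):
            GranuleParams(threshold_value=0)
        with pytest.raises(ValueError):
            QCResult(True, "eye_count")
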