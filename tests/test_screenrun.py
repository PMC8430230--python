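"""Plate orchestration, group statistics and end-to-end determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from embryoscreen.plate_io import PlateSpec, WellRecord, read_results
from embryoscreen.screenrun import (
    RunConfig,
    analyze_well,
    record_value,
    run_plate,
    summarize_groups,
)
from embryoscreen.synthplate import (
    NoiseParams,
    generate_plate,
    truth_segmentation,
)

from conftest import SMALL_LAWS


@pytest.fixture(scope="module")
def small_cfg(small_spec):
    return RunConfig(spec=small_spec, preset="hspc")


@pytest.fixture(scope="module")
def small_plate(small_spec):
    mix = {"lateral_left": 3, "lateral_right": 2, "dorsal": 1, "absent": 1, "partial": 1}
    return generate_plate(
        n_wells=8, presentation_mix=mix, spec=small_spec, seed=17, laws=SMALL_LAWS
    )


class TestRunPlate:
    def test_one_record_per_well_and_qc_matches_truth(self, small_plate, small_cfg):
        records = run_plate(small_plate, small_cfg)
        assert [r.well for r in records] == small_plate.wells()
        for r in records:
            pres = small_plate.truth[r.well].layout.presentation
            assert r.included == (pres in ("lateral_left", "lateral_right"))

    def test_excluded_wells_carry_reason_and_no_metrics(self, small_plate, small_cfg):
        records = run_plate(small_plate, small_cfg)
        for r in records:
            if not r.included:
                assert r.reason != "ok"
                assert r.fish_area is None and r.granules == {}

    def test_results_csv_deterministic(self, small_plate, small_cfg, tmp_path):
        run_plate(small_plate, small_cfg, out_csv=tmp_path / "a.csv")
        run_plate(small_plate, small_cfg, out_csv=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_well_order_invariance(self, small_plate, small_cfg):
        class Reversed:
            spec = small_plate.spec

            def wells(self):
                return small_plate.wells()[::-1]

            def well_fields(self, well):
                return small_plate.well_fields(well)

        a = run_plate(small_plate, small_cfg)
        b = run_plate(Reversed(), small_cfg)
        assert [r.well for r in a] == [r.well for r in b]
        assert [(r.included, r.headline) for r in a] == [
            (r.included, r.headline) for r in b
        ]

    def test_all_absent_plate_all_empty_well(self, small_spec, small_cfg):
        plate = generate_plate(
            n_wells=3, presentation_mix={"absent": 1.0},
            spec=small_spec, seed=2, laws=(),
        )
        records = run_plate(plate, small_cfg)
        assert all(not r.included and r.reason == "empty_well" for r in records)

    def test_disk_round_trip_matches_in_memory(self, small_spec, small_cfg, tmp_path):
        plate = generate_plate(
            n_wells=2, presentation_mix={"lateral_left": 1.0},
            spec=small_spec, seed=23, laws=SMALL_LAWS, out_dir=tmp_path / "plate",
        )
        mem = run_plate(plate, small_cfg)
        disk = run_plate(tmp_path / "plate", small_cfg)
        # the disk run covers the whole 96-well grid; wells without files
        # come back excluded(empty_well)
        by_well = {r.well: r for r in disk}
        assert [by_well[r.well].headline for r in mem] == [r.headline for r in mem]
        rest = [r for w, r in by_well.items() if w not in {r.well for r in mem}]
        assert all(r.reason == "empty_well" for r in rest)

    def test_incomplete_plate_aborts_with_report(self, small_spec, small_cfg, tmp_path):
        generate_plate(
            n_wells=1, presentation_mix={"lateral_left": 1.0},
            spec=small_spec, seed=23, laws=SMALL_LAWS, out_dir=tmp_path / "plate",
        )
        victim = next((tmp_path / "plate").glob("A01_f0_BF_z0.tif"))
        victim.unlink()
        with pytest.raises(FileNotFoundError, match="A01"):
            run_plate(tmp_path / "plate", small_cfg)


class TestOracleSegmenterSubstitution:
    def test_truth_segmentation_recovers_truth_exactly(self, small_spec):
        """With the generator's own masks plugged in, noise-free counts and
        morphometrics equal truth exactly."""
        plate = generate_plate(
            n_wells=2, presentation_mix={"lateral_left": 1.0}, spec=small_spec,
            seed=31, laws=SMALL_LAWS,
            noise=NoiseParams.noise_free(haze_amplitude=0.0),
        )
        cfg = RunConfig(spec=small_spec, preset="hspc")
        for well in plate.wells():
            tr = plate.truth[well]
            rec = analyze_well(
                plate.well_fields(well), cfg, segmentation=truth_segmentation(tr)
            )
            assert rec.included
            assert rec.fish_area == tr.fish_area
            assert rec.eye_area == tr.eye_area
            assert rec.granules[("GFP", "tail")]["count"] == tr.count("GFP", "tail")
            assert rec.granules[("GFP", "trunk")]["count"] == tr.count("GFP", "trunk")


def _recs(values_by_group, group_of):
    records, gmap = [], {}
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            well = f"A{i + 1:02d}"
            records.append(
                WellRecord(well=well, included=True, reason="ok", headline=float(v))
            )
            gmap[well] = group
            i += 1
    return records, gmap


class TestSummarize:
    def test_pooled_t_matches_closed_form(self):
        """{1..5} vs {2..6}: t from the standard pooled-variance formula."""
        records, gmap = _recs({"a": [1, 2, 3, 4, 5], "b": [2, 3, 4, 5, 6]}, None)
        out = summarize_groups(records, "headline", gmap)
        a = next(s for s in out if s.condition == "a")
        # hand-derived: means 3 and 4, pooled var 2.5, se = sqrt(2.5 * 2/5) = 1
        assert a.mean == 3.0 and a.sd == pytest.approx(math.sqrt(2.5))
        cmp = a.comparisons[0]
        assert cmp.t == pytest.approx(-1.0)
        assert cmp.p == pytest.approx(2 * stats.t.sf(1.0, df=8))

    def test_identical_groups_t_zero_p_one(self):
        records, gmap = _recs({"a": [1, 2, 3], "b": [1, 2, 3]}, None)
        out = summarize_groups(records, "headline", gmap)
        cmp = out[0].comparisons[0]
        assert cmp.t == pytest.approx(0.0) and cmp.p == pytest.approx(1.0)

    def test_single_well_group_not_computable(self):
        records, gmap = _recs({"a": [1.0], "b": [2, 3, 4]}, None)
        out = summarize_groups(records, "headline", gmap)
        assert not out[0].comparisons[0].computable

    def test_excluded_wells_never_contribute(self):
        records, gmap = _recs({"a": [1, 2, 3], "b": [4, 5, 6]}, None)
        # poison group b with an excluded well carrying a huge value
        records.append(WellRecord(well="A99", included=False, reason="eye_count"))
        gmap["A99"] = "b"
        out = summarize_groups(records, "headline", gmap)
        b = next(s for s in out if s.condition == "b")
        assert b.n == 3 and b.mean == 5.0

    def test_welch_flag_changes_df(self):
        records, gmap = _recs({"a": [1, 2, 3, 4], "b": [10, 30, 50, 70]}, None)
        student = summarize_groups(records, "headline", gmap)[0].comparisons[0]
        welch = summarize_groups(records, "headline", gmap, welch=True)[0].comparisons[0]
        assert student.t == pytest.approx(welch.t)  # same statistic here
        assert student.p != pytest.approx(welch.p)  # different df

    def test_record_value_resolves_granule_columns(self):
        rec = WellRecord(
            well="A01", included=True, reason="ok",
            granules={("GFP", "tail"): {"count": 12.0}},
            region_areas={"tail": 99.0},
        )
        assert record_value(rec, "GFP_tail_count") == 12.0
        assert record_value(rec, "tail_area") == 99.0
        assert record_value(rec, "nonexistent") is None


class TestRunConfig:
    def test_from_dict_round_trip_essentials(self):
        cfg = RunConfig.from_dict(
            {
                "plate": {"rows": 2, "cols": 3, "tile_shape": [64, 87],
                          "overlap_fraction": 0.1},
                "preset": "hspc",
                "granules": {"GFP": {"threshold_value": 4.0}},
                "qc": {"min_fish_area": 10.0, "min_tail_area": 1.0},
                "groups": {"A01": "control"},
                "seed": 5,
            }
        )
        assert cfg.spec.rows == 2 and cfg.spec.tile_shape == (64, 87)
        assert cfg.granule_params["GFP"].threshold_value == 4.0
        assert cfg.resolved_qc().min_fish_area == 10.0
        assert cfg.seed == 5

    def test_group_map_must_name_real_wells(self, small_spec):
        with pytest.raises(ValueError, match="Z99"):
            RunConfig(spec=small_spec, group_map={"Z99": "x"})

    def test_preset_channels_adopted(self):
        cfg = RunConfig(preset="haircell")
        assert [c.name for c in cfg.spec.channels] == ["BF", "YOPRO"]
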