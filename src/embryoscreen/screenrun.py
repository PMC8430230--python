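"""Whole-plate orchestration and per-group statistics.

``run_plate`` drives every well independently through preprocess →
segment → QC → quantify and emits one :class:`~.plate_io.WellRecord` per
well.  Excluded wells are exported with their QC reason and empty metric
cells; filtering happens at summary time, so nothing is silently dropped.
``summarize_groups`` then compares experimental conditions with unpaired
two-tailed Student t-tests (pooled variance, Welch optional) on any
exported metric, reporting mean ± s.d. per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import yaml
from scipy import stats

from . import plate_io
from .plate_io import (
    ChannelRole,
    FieldImage,
    PlateIndex,
    PlateSpec,
    WellRecord,
    discover_plate,
)
from .preprocess import preprocess_well
from .presets import AssayPreset, get_preset
from .quantify import (
    GranuleParams,
    QCCriteria,
    apply_qc,
    assign_regions,
    detect_granules,
    region_metrics,
)
from .segment import (
    EmbryoSegmentation,
    ReferenceSegmenter,
    Segmenter,
    SizeConstraints,
    measure_morphology,
)

__all__ = [
    "RunConfig",
    "GroupSummary",
    "Comparison",
    "PlateSource",
    "run_plate",
    "analyze_well",
    "summarize_groups",
]

log = logging.getLogger("embryoscreen")


class PlateSource(Protocol):
    """Anything that can hand over the raw tiles of a well."""

    spec: PlateSpec

    def wells(self) -> list[str]: ...

    def well_fields(self, well: str) -> list[FieldImage]: ...


@dataclass
class RunConfig:
    """Everything a plate analysis needs besides the images."""

    spec: PlateSpec = field(default_factory=PlateSpec)
    preset: str = "hspc"
    granule_params: dict[str, GranuleParams] | None = None
    qc: QCCriteria | None = None
    constraints: SizeConstraints | None = None
    group_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    refine_stitch: bool = False
    welch: bool = False
    filename_pattern: str = plate_io.DEFAULT_FILENAME_PATTERN

    def __post_init__(self) -> None:
        preset = get_preset(self.preset)
        if tuple(self.spec.channels) == PlateSpec().channels and (
            preset.channels != self.spec.channels
        ):
            # adopt the preset's channel roles unless explicitly overridden
            object.__setattr__(self, "spec",
                               _replace_channels(self.spec, preset.channels))
        if self.granule_params is None:
            self.granule_params = dict(preset.granule_params)
        for name in self.granule_params:
            self.spec.channel(name)  # must exist
        for well in self.group_map:
            if well not in self.spec.wells():
                raise ValueError(f"group map names well {well!r} not on the plate")

    @property
    def assay(self) -> AssayPreset:
        return get_preset(self.preset)

    def resolved_qc(self) -> QCCriteria:
        if self.qc is not None:
            return self.qc
        return QCCriteria.for_canvas((self.spec.tile_shape[0], self.spec.stitched_width))

    def resolved_constraints(self) -> SizeConstraints:
        if self.constraints is not None:
            return self.constraints
        return SizeConstraints.for_canvas(
            (self.spec.tile_shape[0], self.spec.stitched_width)
        )

    # -- (de)serialisation ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        plate = dict(data.get("plate", {}))
        channels = plate.pop("channels", None)
        if "tile_shape" in plate:
            plate["tile_shape"] = tuple(plate["tile_shape"])
        spec = PlateSpec(**plate) if plate or channels is None else PlateSpec(**plate)
        if channels is not None:
            spec = _replace_channels(
                spec, tuple(ChannelRole(**c) for c in channels)
            )
        gran = {
            name: GranuleParams(**params)
            for name, params in (data.get("granules") or {}).items()
        } or None
        qc = QCCriteria(**data["qc"]) if data.get("qc") else None
        cons = (
            SizeConstraints(**{k: tuple(v) for k, v in data["constraints"].items()})
            if data.get("constraints")
            else None
        )
        return cls(
            spec=spec,
            preset=data.get("preset", "hspc"),
            granule_params=gran,
            qc=qc,
            constraints=cons,
            group_map=dict(data.get("groups") or {}),
            seed=int(data.get("seed", 0)),
            refine_stitch=bool(data.get("refine_stitch", False)),
            welch=bool(data.get("welch", False)),
            filename_pattern=data.get(
                "filename_pattern", plate_io.DEFAULT_FILENAME_PATTERN
            ),
        )


def _replace_channels(spec: PlateSpec, channels: tuple[ChannelRole, ...]) -> PlateSpec:
    from dataclasses import replace

    return replace(spec, channels=channels)


class _IndexSource:
    """Adapts a PlateIndex to the PlateSource protocol."""

    def __init__(self, index: PlateIndex):
        self.index = index
        self.spec = index.spec

    def wells(self) -> list[str]:
        return self.spec.wells()

    def well_fields(self, well: str) -> list[FieldImage]:
        return list(self.index.iter_well(well))


def _excluded(well: str, reason: str) -> WellRecord:
    return WellRecord(well=well, included=False, reason=reason)


def analyze_well(
    fields: Sequence[FieldImage],
    config: RunConfig,
    segmenter: Segmenter | None = None,
    segmentation: EmbryoSegmentation | None = None,
) -> WellRecord:
    """Analyse one well's tiles into a WellRecord.

    A pre-computed ``segmentation`` (e.g. from an oracle segmenter)
    bypasses the brightfield segmenter but runs the identical QC and
    quantification path.
    """
    spec = config.spec
    well = fields[0].well if fields else "?"
    if not fields:
        return _excluded(well, "empty_well")
    stitched = preprocess_well(fields, spec, refine=config.refine_stitch)
    if segmentation is None:
        segmenter = segmenter or ReferenceSegmenter()
        segmentation = segmenter.segment(
            stitched.channel(spec.brightfield.name), config.resolved_constraints()
        )
    qc = apply_qc(segmentation, config.resolved_qc())
    if not qc.included:
        return _excluded(well, qc.reason)
    assert segmentation is not None
    morph = measure_morphology(segmentation, spec.pixel_size)
    granules: dict[tuple[str, str], dict[str, float]] = {}
    ps2 = 1.0 if spec.pixel_size is None else spec.pixel_size**2
    for ch in spec.fluorescence_channels:
        params = (config.granule_params or {}).get(ch.name)
        if params is None:
            continue
        gset = detect_granules(
            stitched.channel(ch.name), params, segmentation.fish_mask
        )
        gset.channel = ch.name
        gset = assign_regions(gset, segmentation)
        for region, metrics in region_metrics(gset, segmentation).items():
            granules[(ch.name, region)] = {
                "count": metrics["count"],
                "integrated_intensity": metrics["integrated_intensity"],
                "mean_granule_area": (
                    None
                    if metrics["mean_granule_area"] is None
                    else metrics["mean_granule_area"] * ps2
                ),
                "total_granule_area": metrics["total_granule_area"] * ps2,
            }
    record = WellRecord(
        well=well,
        included=True,
        reason="ok",
        fish_area=morph["fish_area"],
        fish_length=morph["fish_length"],
        eye_count=int(morph["eye_count"]),
        eye_area=morph["eye_area"],
        region_areas={r: morph[f"{r}_area"] for r in ("head", "trunk", "tail")},
        granules=granules,
    )
    record.headline = _headline_value(record, config.assay)
    return record


def _headline_value(record: WellRecord, preset: AssayPreset) -> float | None:
    ch, region, metric = preset.headline
    if ch:
        return record.granules.get((ch, region), {}).get(metric)
    return getattr(record, metric, None)


def run_plate(
    plate: PlateSource | PlateIndex | str | Path,
    config: RunConfig,
    out_csv: str | Path | None = None,
    segmenter: Segmenter | None = None,
) -> list[WellRecord]:
    """Analyse every well of a plate; never let one well abort the run.

    Results are emitted in well order and are independent of processing
    order.  Wells with partially missing files abort the run with a
    per-well report; wells that are empty on disk become
    excluded(empty_well) records.
    """
    if isinstance(plate, (str, Path)):
        plate = discover_plate(plate, config.spec, config.filename_pattern)
    if isinstance(plate, PlateIndex):
        if plate.missing:
            report = "; ".join(
                f"{well}: {len(keys)} missing tiles" for well, keys in plate.missing.items()
            )
            raise FileNotFoundError(f"plate incomplete: {report}")
        plate = _IndexSource(plate)

    segmenter = segmenter or ReferenceSegmenter()
    records = []
    for well in sorted(plate.wells()):
        fields = plate.well_fields(well)
        if not fields:
            rec = _excluded(well, "empty_well")
        else:
            try:
                rec = analyze_well(fields, config, segmenter=segmenter)
            except Exception:
                log.exception("well %s failed; excluding", well)
                rec = _excluded(well, "error")
        log.info(
            "well %s: %s (%s)%s",
            well,
            "included" if rec.included else "excluded",
            rec.reason,
            "" if rec.headline is None else f" headline={rec.headline:g}",
        )
        records.append(rec)
    n_inc = sum(r.included for r in records)
    log.info("plate done: %d/%d wells included", n_inc, len(records))
    if out_csv is not None:
        channels = [c.name for c in config.spec.fluorescence_channels]
        plate_io.write_results(
            records, out_csv, spec=config.spec, channels=channels,
            headline_name=config.assay.headline_column,
        )
    return records


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    other: str
    t: float
    p: float
    computable: bool = True


@dataclass
class GroupSummary:
    """Mean ± s.d. of one condition plus pairwise t-tests against the rest."""

    condition: str
    n: int
    mean: float
    sd: float
    comparisons: list[Comparison] = field(default_factory=list)


def record_value(record: WellRecord, metric: str) -> float | None:
    """Resolve a metric name against a record.

    Accepts morphometric fields (``fish_area`` ...), ``headline``, region
    areas (``tail_area``) and granule columns (``GFP_tail_count``,
    ``YOPRO_fish_integrated_intensity`` ...).
    """
    if hasattr(record, metric):
        v = getattr(record, metric)
        return None if v is None else float(v)
    for region in ("head", "trunk", "tail"):
        if metric == f"{region}_area":
            v = record.region_areas.get(region)
            return None if v is None else float(v)
    for (ch, region), metrics in record.granules.items():
        for m, v in metrics.items():
            if metric == f"{ch}_{region}_{m}":
                return None if v is None else float(v)
    return None


def summarize_groups(
    records: Sequence[WellRecord],
    metric: str,
    group_map: Mapping[str, str],
    welch: bool = False,
) -> list[GroupSummary]:
    """Unpaired two-tailed t-tests on a metric over QC-included wells.

    Student's pooled-variance t by default (``welch`` switches to Welch's
    unequal-variance form); p from the t distribution with n1+n2−2 df.
    Groups with fewer than two included wells yield not-computable
    comparisons.  Excluded wells never contribute.
    """
    values: dict[str, list[float]] = {}
    for rec in records:
        if not rec.included:
            continue
        cond = group_map.get(rec.well)
        if cond is None:
            continue
        v = record_value(rec, metric)
        if v is not None:
            values.setdefault(cond, []).append(v)
    conditions = sorted(values)
    out = []
    for cond in conditions:
        xs = np.asarray(values[cond], dtype=float)
        n = len(xs)
        summary = GroupSummary(
            condition=cond,
            n=n,
            mean=float(xs.mean()) if n else math.nan,
            sd=float(xs.std(ddof=1)) if n > 1 else math.nan,
        )
        for other in conditions:
            if other == cond:
                continue
            ys = np.asarray(values[other], dtype=float)
            if n < 2 or len(ys) < 2:
                summary.comparisons.append(
                    Comparison(other, math.nan, math.nan, computable=False)
                )
                continue
            t, p = stats.ttest_ind(xs, ys, equal_var=not welch)
            summary.comparisons.append(Comparison(other, float(t), float(p)))
        out.append(summary)
    return out
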