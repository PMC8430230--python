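"""Plate-level disk I/O: image discovery, filename conventions and results tables.

A screening run produces one grayscale TIFF per (well, field, channel,
z-slice).  A full 96-well plate imaged with four overlapping fields per
well, two channels and five z-planes therefore holds 3840 raw tiles.  This
module maps that directory onto an indexed, validated collection of
:class:`FieldImage` tiles, and writes the per-well results CSV at the other
end of the pipeline.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelRole",
    "PlateSpec",
    "FieldImage",
    "WellRecord",
    "PlateIndex",
    "FilenameParseError",
    "DuplicateKeyError",
    "DEFAULT_FILENAME_PATTERN",
    "parse_field_filename",
    "format_field_filename",
    "discover_plate",
    "read_field_image",
    "write_field_image",
    "write_results",
    "read_results",
]

DEFAULT_FILENAME_PATTERN = "{well}_f{field}_{channel}_z{z}.tif"

#: Modalities a channel may declare.
MODALITIES = ("brightfield", "fluorescence")
#: How a z-stack is collapsed to a single plane.
PROJECTIONS = ("best_slice", "max_projection")


class FilenameParseError(ValueError):
    """A filename does not match the configured naming convention."""


class DuplicateKeyError(ValueError):
    """Two files on disk map to the same (well, field, channel, z) key."""


@dataclass(frozen=True)
class ChannelRole:
    """One acquisition channel and how its z-stack is collapsed.

    Exactly one channel per run is brightfield (used for segmentation);
    every other channel is fluorescence.  Brightfield stacks default to
    best-slice selection, fluorescence stacks to maximum intensity
    projection so that labelled cells anywhere in the embryo volume are
    captured.
    """

    name: str
    modality: str = "fluorescence"
    projection: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.projection is None:
            default = "best_slice" if self.modality == "brightfield" else "max_projection"
            object.__setattr__(self, "projection", default)
        if self.projection not in PROJECTIONS:
            raise ValueError(f"unknown projection {self.projection!r}")


@dataclass(frozen=True)
class PlateSpec:
    """Geometry of a plate acquisition.

    Defaults describe a 96-well plate scanned with four overlapping fields
    along each well's long axis and five z-planes spaced 50.6 µm apart.
    ``pixel_size`` (µm/px) is optional; when unset, areas and lengths are
    reported in pixel units.
    """

    rows: int = 8
    cols: int = 12
    fields_per_well: int = 4
    z_planes: int = 5
    z_step: float = 50.6
    overlap_fraction: float = 0.15
    pixel_size: float | None = None
    tile_shape: tuple[int, int] = (512, 696)
    channels: tuple[ChannelRole, ...] = (
        ChannelRole("BF", "brightfield"),
        ChannelRole("GFP", "fluorescence"),
    )

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise ValueError("plate must have at least one well")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        n_bf = sum(c.modality == "brightfield" for c in self.channels)
        if self.channels and n_bf != 1:
            raise ValueError("exactly one brightfield channel is required")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def brightfield(self) -> ChannelRole:
        return next(c for c in self.channels if c.modality == "brightfield")

    @property
    def fluorescence_channels(self) -> tuple[ChannelRole, ...]:
        return tuple(c for c in self.channels if c.modality == "fluorescence")

    def channel(self, name: str) -> ChannelRole:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}")

    def wells(self) -> list[str]:
        """All well names in row-major order: A01, A02, ..., H12."""
        letters = string.ascii_uppercase
        return [
            f"{letters[r]}{c + 1:02d}"
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    def expected_keys(self, well: str) -> list[tuple[str, int, str, int]]:
        return [
            (well, f, ch, z)
            for f in range(self.fields_per_well)
            for ch in self.channel_names
            for z in range(self.z_planes)
        ]

    @property
    def stitched_width(self) -> int:
        """Width in px of the stitched well strip at the nominal overlap."""
        n, w = self.fields_per_well, self.tile_shape[1]
        return n * w - (n - 1) * round(self.overlap_fraction * w)

    def to_physical(self, area_px: float) -> float:
        """Convert a pixel area to µm² if a pixel size is configured."""
        if self.pixel_size is None:
            return area_px
        return area_px * self.pixel_size**2

    @property
    def area_unit(self) -> str:
        return "px2" if self.pixel_size is None else "um2"

    @property
    def length_unit(self) -> str:
        return "px" if self.pixel_size is None else "um"


@dataclass
class FieldImage:
    """One raw image tile with its plate coordinates."""

    well: str
    field_index: int
    channel: str
    z_index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("field image must be 2-D")

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.well, self.field_index, self.channel, self.z_index)


def normalize_well(well: str) -> str:
    """Canonicalise a well name to letter + zero-padded 2-digit column."""
    m = re.fullmatch(r"([A-Za-z])0*(\d+)", well)
    if m is None:
        raise ValueError(f"malformed well name {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


_FIELD_PATTERNS = {
    "well": r"(?P<well>[A-Za-z]\d+)",
    "field": r"(?P<field>\d+)",
    "channel": r"(?P<channel>[A-Za-z0-9+-]+)",
    "z": r"(?P<z>\d+)",
}


def _pattern_to_regex(pattern: str) -> re.Pattern:
    placeholders = re.findall(r"\{(\w+)\}", pattern)
    if set(placeholders) != set(_FIELD_PATTERNS):
        missing = set(_FIELD_PATTERNS) - set(placeholders)
        raise ValueError(f"filename pattern lacks placeholders: {sorted(missing)}")
    out = ""
    pos = 0
    for m in re.finditer(r"\{(\w+)\}", pattern):
        out += re.escape(pattern[pos : m.start()])
        out += _FIELD_PATTERNS[m.group(1)]
        pos = m.end()
    out += re.escape(pattern[pos:])
    return re.compile(out)


def parse_field_filename(
    name: str, pattern: str = DEFAULT_FILENAME_PATTERN
) -> tuple[str, int, str, int]:
    """Extract (well, field_index, channel, z_index) from a tile filename.

    Raises :class:`FilenameParseError` naming the offending file when the
    name does not match the convention.
    """
    rx = _pattern_to_regex(pattern)
    m = rx.fullmatch(name)
    if m is None:
        raise FilenameParseError(f"filename {name!r} does not match pattern {pattern!r}")
    return (
        normalize_well(m.group("well")),
        int(m.group("field")),
        m.group("channel"),
        int(m.group("z")),
    )


def format_field_filename(
    well: str,
    field_index: int,
    channel: str,
    z_index: int,
    pattern: str = DEFAULT_FILENAME_PATTERN,
) -> str:
    """Inverse of :func:`parse_field_filename` for valid keys."""
    return pattern.format(
        well=normalize_well(well), field=field_index, channel=channel, z=z_index
    )


@dataclass
class PlateIndex:
    """Validated map from (well, field, channel, z) keys to files on disk."""

    directory: Path
    spec: PlateSpec
    files: dict[tuple[str, int, str, int], Path]
    missing: dict[str, list[tuple[str, int, str, int]]] = field(default_factory=dict)
    empty_wells: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.files)

    def load(self, key: tuple[str, int, str, int]) -> FieldImage:
        well, f, ch, z = key
        return read_field_image(self.files[key], well, f, ch, z)

    def iter_well(self, well: str) -> Iterator[FieldImage]:
        for key in sorted(self.files):
            if key[0] == well:
                yield self.load(key)

    def wells_present(self) -> list[str]:
        return sorted({k[0] for k in self.files})


def discover_plate(
    directory: str | Path,
    spec: PlateSpec,
    pattern: str = DEFAULT_FILENAME_PATTERN,
) -> PlateIndex:
    """Index a plate directory against the expected acquisition grid.

    Every expected (well, field, channel, z) key maps to at most one file;
    a key claimed by two files raises :class:`DuplicateKeyError`.  Wells
    with some but not all tiles get their missing keys reported; wells with
    no files at all are listed as empty-on-disk.  Files not matching the
    naming convention are collected in ``unmatched`` and otherwise ignored.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"plate directory {directory} not readable")
    files: dict[tuple[str, int, str, int], Path] = {}
    unmatched: list[str] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            key = parse_field_filename(path.name, pattern)
        except FilenameParseError:
            unmatched.append(path.name)
            continue
        if key in files:
            raise DuplicateKeyError(
                f"files {files[key].name!r} and {path.name!r} both map to key {key}"
            )
        files[key] = path

    missing: dict[str, list[tuple[str, int, str, int]]] = {}
    empty: list[str] = []
    for well in spec.wells():
        expected = spec.expected_keys(well)
        present = [k for k in expected if k in files]
        if not present:
            if any(k[0] == well for k in files):
                # files exist but outside the expected grid (bad index range)
                missing[well] = [k for k in expected if k not in files]
            else:
                empty.append(well)
        elif len(present) < len(expected):
            missing[well] = [k for k in expected if k not in files]
    return PlateIndex(
        directory=directory,
        spec=spec,
        files=files,
        missing=missing,
        empty_wells=empty,
        unmatched=unmatched,
    )


def read_field_image(
    path: str | Path, well: str, field_index: int, channel: str, z_index: int
) -> FieldImage:
    try:
        pixels = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise IOError(f"unreadable image file {path}") from exc
    if pixels.ndim != 2:
        raise IOError(f"image file {path} is not a single grayscale plane")
    return FieldImage(well, field_index, channel, z_index, pixels)


def write_field_image(directory: str | Path, image: FieldImage,
                      pattern: str = DEFAULT_FILENAME_PATTERN) -> Path:
    name = format_field_filename(
        image.well, image.field_index, image.channel, image.z_index, pattern
    )
    path = Path(directory) / name
    tifffile.imwrite(path, image.pixels)
    return path


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

#: QC reasons, in the order checks are applied.
QC_REASONS = ("ok", "empty_well", "eye_count", "tail_count", "fish_area", "tail_area")

#: per-(channel, region) granule metrics exported for every fluorescence channel
GRANULE_METRICS = ("count", "integrated_intensity", "mean_granule_area", "total_granule_area")
REGIONS = ("head", "trunk", "tail")


@dataclass
class WellRecord:
    """The per-embryo exported row: QC verdict plus assay metrics.

    Excluded wells carry a reason and no metrics.  ``granules`` maps
    ``(channel, region)`` — region ``"fish"`` meaning the whole animal — to
    a metric dict with the keys in :data:`GRANULE_METRICS`.
    """

    well: str
    included: bool
    reason: str = "ok"
    fish_area: float | None = None
    fish_length: float | None = None
    eye_count: int | None = None
    eye_area: float | None = None
    region_areas: dict[str, float] = field(default_factory=dict)
    granules: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    headline: float | None = None

    def __post_init__(self) -> None:
        if self.reason not in QC_REASONS and self.reason != "error":
            raise ValueError(f"unknown QC reason {self.reason!r}")
        if self.included and self.reason != "ok":
            raise ValueError("included wells must carry reason 'ok'")


def _results_columns(channels: Sequence[str], spec: PlateSpec,
                     headline_name: str) -> list[str]:
    au, lu = spec.area_unit, spec.length_unit
    cols = [
        "well", "qc_status", "qc_reason",
        f"fish_area_{au}", f"fish_length_{lu}", "eye_count", f"eye_area_{au}",
    ]
    cols += [f"{r}_area_{au}" for r in REGIONS]
    for ch in channels:
        for region in REGIONS + ("fish",):
            for metric in GRANULE_METRICS:
                unit = f"_{au}" if "area" in metric else ""
                cols.append(f"{ch}_{region}_{metric}{unit}")
    cols.append(headline_name)
    return cols


def _fmt(value: float | int | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    v = float(value)
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return format(v, ".6g")


def write_results(
    records: Sequence[WellRecord],
    destination: str | Path,
    spec: PlateSpec | None = None,
    channels: Sequence[str] | None = None,
    headline_name: str = "headline_metric",
) -> Path:
    """Write the per-well results CSV (one row per well, header mandatory).

    The column set is fixed by the channel list and units; excluded wells
    get their reason populated and every metric cell left empty.  Values are
    canonically formatted so that read → write round-trips byte-identically.
    """
    spec = spec or PlateSpec()
    if channels is None:
        chans: list[str] = sorted({ch for r in records for (ch, _r) in r.granules})
        channels = chans or [c.name for c in spec.fluorescence_channels]
    cols = _results_columns(channels, spec, headline_name)
    au = spec.area_unit
    rows = []
    for rec in records:
        row = dict.fromkeys(cols, "")
        row["well"] = rec.well
        row["qc_status"] = "included" if rec.included else "excluded"
        row["qc_reason"] = rec.reason
        if rec.included:
            row[f"fish_area_{au}"] = _fmt(rec.fish_area)
            row[f"fish_length_{spec.length_unit}"] = _fmt(rec.fish_length)
            row["eye_count"] = _fmt(rec.eye_count)
            row[f"eye_area_{au}"] = _fmt(rec.eye_area)
            for r in REGIONS:
                row[f"{r}_area_{au}"] = _fmt(rec.region_areas.get(r))
            for ch in channels:
                for region in REGIONS + ("fish",):
                    metrics = rec.granules.get((ch, region), {})
                    for metric in GRANULE_METRICS:
                        unit = f"_{au}" if "area" in metric else ""
                        row[f"{ch}_{region}_{metric}{unit}"] = _fmt(metrics.get(metric))
            row[headline_name] = _fmt(rec.headline)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cols, dtype=str) if rows else pd.DataFrame(columns=cols)
    destination = Path(destination)
    frame.to_csv(destination, index=False, lineterminator="\n")
    return destination


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back as a string-typed DataFrame (empty cells = '')."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)
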