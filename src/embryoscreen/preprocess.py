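"""Z-stack reduction and field stitching.

Each well is acquired as four overlapping fields, each a five-plane
z-stack, per channel.  Brightfield stacks are collapsed by best-slice
selection (the sharpest plane, scored by variance of the Laplacian);
fluorescence stacks by maximum intensity projection so that labelled cells
at any depth survive.  The reduced fields are then stitched along the
well's long axis into a single multi-channel image per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .plate_io import FieldImage, PlateSpec

__all__ = [
    "StitchedWell",
    "sharpness_score",
    "select_best_slice",
    "max_project",
    "stitch_fields",
    "preprocess_well",
]


def sharpness_score(image: np.ndarray) -> float:
    """Focus score: variance of the Laplacian.

    Grows with high-spatial-frequency content and is exactly invariant
    under an additive intensity offset (the Laplacian of a constant is 0).
    A constant image scores 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot score an empty image")
    return float(np.var(ndimage.laplace(image)))


def select_best_slice(stack: Sequence[np.ndarray]) -> tuple[int, np.ndarray]:
    """Pick the sharpest z-plane; ties broken by the lowest index.

    The returned image is the unmodified slice.
    """
    if len(stack) == 0:
        raise ValueError("cannot select from an empty stack")
    scores = [sharpness_score(s) for s in stack]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return best, np.asarray(stack[best])


def max_project(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum across the stack."""
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    arrs = [np.asarray(s) for s in stack]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError("all slices must share dimensions")
    return np.maximum.reduce(arrs)


def _registration_refine(left: np.ndarray, right: np.ndarray,
                         nominal: int, radius: int) -> int:
    """Adjust one pairwise x-offset by exhaustive translation search.

    Scans offsets within ±radius of nominal, scoring the mean squared
    difference over the implied overlap strip, and returns the offset with
    the lowest error (nominal wins ties).
    """
    h, w = left.shape
    errs: dict[int, float] = {}
    for off in range(max(1, nominal - radius), min(w - 4, nominal + radius) + 1):
        ov = w - off
        a = left[:, off:].astype(np.float64)
        b = right[:, :ov].astype(np.float64)
        errs[off] = float(np.mean((a - b) ** 2))
    if not errs:
        return nominal
    best = min(errs.values())
    if nominal in errs and errs[nominal] <= best + 1e-12:
        return nominal
    return min(off for off, e in errs.items() if e <= best + 1e-12)


def stitch_fields(
    field_images: Sequence[np.ndarray],
    nominal_overlap: float,
    refine: bool = False,
    blend: str = "feather",
    search_radius: int = 10,
) -> tuple[np.ndarray, list[int]]:
    """Stitch equally sized tiles along the x axis.

    With ``refine`` off, tile *i* starts at ``i·(L − round(overlap·L))`` so
    the stitched length is ``n·L − (n−1)·round(overlap·L)``.  With
    ``refine`` on, each pairwise offset is adjusted by an exhaustive
    translation search within ±``search_radius`` px.  Pixels covered by a
    single tile always equal that tile exactly; overlap strips are blended
    by linear feathering (brightfield) or pixel-wise maximum (fluorescence,
    preserving spot peaks).
    """
    if len(field_images) == 0:
        raise ValueError("need at least one field")
    if not (0.0 <= nominal_overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    if blend not in ("feather", "max"):
        raise ValueError(f"unknown blend mode {blend!r}")
    tiles = [np.asarray(t) for t in field_images]
    shape = tiles[0].shape
    for t in tiles[1:]:
        if t.shape != shape:
            raise ValueError("tiles must all share dimensions")
    h, w = shape
    stride = w - round(nominal_overlap * w)
    offsets = [0]
    for i in range(1, len(tiles)):
        step = stride
        if refine:
            step = _registration_refine(tiles[i - 1], tiles[i], stride, search_radius)
        offsets.append(offsets[-1] + step)

    width = offsets[-1] + w
    acc = np.zeros((h, width), dtype=np.float64)
    wgt = np.zeros((h, width), dtype=np.float64)
    mx = np.full((h, width), -np.inf)
    cover = np.zeros(width, dtype=np.int32)
    for off, tile in zip(offsets, tiles):
        cover[off : off + w] += 1
    for off, tile in zip(offsets, tiles):
        ft = tile.astype(np.float64)
        if blend == "max":
            np.maximum(mx[:, off : off + w], ft, out=mx[:, off : off + w])
        else:
            # linear feather: weight ramps up through a shared strip on the
            # tile's left edge and down through one on its right edge
            ramp = np.ones(w)
            shared = cover[off : off + w] > 1
            idx = np.nonzero(shared)[0]
            left_ov = idx[idx < w // 2]
            right_ov = idx[idx >= w // 2]
            if left_ov.size:
                ramp[left_ov] = (np.arange(left_ov.size) + 1) / (left_ov.size + 1)
            if right_ov.size:
                ramp[right_ov] = (right_ov.size - np.arange(right_ov.size)) / (
                    right_ov.size + 1
                )
            acc[:, off : off + w] += ft * ramp
            wgt[:, off : off + w] += ramp
    if blend == "max":
        out = mx
    else:
        out = acc / np.maximum(wgt, 1e-12)
    # exactness outside overlaps: columns covered once come from one tile
    single = cover == 1
    for off, tile in zip(offsets, tiles):
        cols = np.nonzero(single[off : off + w])[0]
        if cols.size:
            out[:, off + cols] = tile[:, cols].astype(np.float64)
    if np.issubdtype(tiles[0].dtype, np.integer):
        info = np.iinfo(tiles[0].dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(tiles[0].dtype)
    return out, offsets


@dataclass
class StitchedWell:
    """One well after z-reduction and stitching: pixel-aligned channels."""

    well: str
    images: dict[str, np.ndarray]
    best_slices: dict[int, int] = field(default_factory=dict)  # field -> chosen z (BF)
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) > 1:
            raise ValueError("channel images must share dimensions")

    def channel(self, name: str) -> np.ndarray:
        return self.images[name]

    def save(self, directory) -> list:
        """Cache the stitched images as one TIFF per (well, channel)."""
        import tifffile
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, img in self.images.items():
            path = directory / f"{self.well}_{name}_stitched.tif"
            tifffile.imwrite(path, img)
            paths.append(path)
        return paths


def preprocess_well(
    fields: Sequence[FieldImage],
    spec: PlateSpec,
    refine: bool = False,
) -> StitchedWell:
    """Collapse z and stitch all fields of one well, per channel.

    Projection is applied per field before stitching.  The brightfield
    channel records the chosen z-index per field; its refined offsets (if
    any) are reused for the fluorescence channels so all channels stay
    pixel-aligned.
    """
    if not fields:
        raise ValueError("no fields supplied")
    well = fields[0].well
    by_cf: dict[tuple[str, int], dict[int, np.ndarray]] = {}
    for f in fields:
        if f.well != well:
            raise ValueError("fields from multiple wells supplied")
        by_cf.setdefault((f.channel, f.field_index), {})[f.z_index] = f.pixels

    images: dict[str, np.ndarray] = {}
    best: dict[int, int] = {}
    offsets: list[int] = []
    # brightfield first so its refined offsets can anchor the others
    ordered = sorted(spec.channels, key=lambda c: c.modality != "brightfield")
    bf_offsets: list[int] | None = None
    for role in ordered:
        reduced = []
        for fi in range(spec.fields_per_well):
            stack_map = by_cf.get((role.name, fi))
            if not stack_map:
                raise ValueError(f"well {well}: missing field {fi} for {role.name}")
            stack = [stack_map[z] for z in sorted(stack_map)]
            if role.projection == "best_slice":
                z, img = select_best_slice(stack)
                if role.modality == "brightfield":
                    best[fi] = z
            else:
                img = max_project(stack)
            reduced.append(img)
        if role.modality == "brightfield":
            img, offs = stitch_fields(
                reduced, spec.overlap_fraction, refine=refine, blend="feather"
            )
            bf_offsets = offs
        else:
            if bf_offsets is not None and refine:
                img, offs = _stitch_at_offsets(reduced, bf_offsets, blend="max")
            else:
                img, offs = stitch_fields(
                    reduced, spec.overlap_fraction, refine=False, blend="max"
                )
        images[role.name] = img
        offsets = offs
    return StitchedWell(well=well, images=images, best_slices=best,
                        offsets=bf_offsets or offsets)


def _stitch_at_offsets(tiles: Sequence[np.ndarray], offsets: Sequence[int],
                       blend: str = "max") -> tuple[np.ndarray, list[int]]:
    """Stitch tiles at externally supplied offsets (max blend)."""
    tiles = [np.asarray(t) for t in tiles]
    h, w = tiles[0].shape
    width = offsets[-1] + w
    mx = np.full((h, width), -np.inf)
    for off, tile in zip(offsets, tiles):
        np.maximum(mx[:, off : off + w], tile.astype(np.float64), out=mx[:, off : off + w])
    if np.issubdtype(tiles[0].dtype, np.integer):
        info = np.iinfo(tiles[0].dtype)
        mx = np.clip(np.rint(mx), info.min, info.max).astype(tiles[0].dtype)
    return mx, list(offsets)
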