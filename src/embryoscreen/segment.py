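"""Brightfield embryo segmentation: fish outline, anatomy and regions.

The reference segmenter is classical: the embryo is found as the largest
dark connected object (relative to the well background) whose area falls
inside the configured fish size constraints, after smoothing and
morphological cleanup.  Eyes and yolk sac are darker still and are
recovered as compact dark blobs inside the fish; the caudal tip of the
yolk extension and the posterior eye edge then anchor the head/trunk/tail
partition along the body axis.  The segmenter sits behind a small
contract (:class:`Segmenter`) so a learned model — or the synthetic
generator's own truth — can be dropped in unchanged.

Brightfield polarity is transmitted-light: the fish is darker than the
background.  All thresholds are relative to the image median, so the
segmentation is invariant under intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

__all__ = [
    "ANATOMY_LABELS",
    "SizeConstraints",
    "AnatomyRegion",
    "BodyAxis",
    "EmbryoSegmentation",
    "Segmenter",
    "ReferenceSegmenter",
    "segment_fish",
    "detect_eyes",
    "detect_yolk",
    "detect_tail",
    "partition_regions",
    "measure_morphology",
    "body_axis",
]

#: all legal anatomy labels; the reference segmenter populates eye,
#: yolk_sac and tail_fin — the rest are reserved for richer segmenters
ANATOMY_LABELS = (
    "eye", "heart", "tail_fin", "yolk_sac", "spine", "bladder", "otic_vesicle",
)

REGION_HEAD, REGION_TRUNK, REGION_TAIL = 1, 2, 3
REGION_NAMES = {REGION_HEAD: "head", REGION_TRUNK: "trunk", REGION_TAIL: "tail"}

#: relative-intensity thresholds (fractions of the background median)
FISH_THRESHOLD = 0.82
DARK_BLOB_MIDPOINT = 0.5  # between body level and darkest level
#: head/trunk boundary: posterior eye edge plus this fraction of body length
HEAD_OFFSET_FRACTION = 0.05
#: landmark-free fallback boundary fractions of the axis length
FALLBACK_FRACTIONS = (0.25, 0.55)
#: anatomy may poke at most this far (px) outside the fish mask (thin fin)
ANATOMY_MARGIN_PX = 5


@dataclass(frozen=True)
class SizeConstraints:
    """Minimum/maximum pixel areas per detectable object class.

    These are the only per-object tuning inputs the segmenter takes.
    Defaults are calibrated for a 512-px-tall stitched well strip;
    :meth:`for_canvas` rescales them to other canvas heights.
    """

    fish: tuple[float, float] = (40_000.0, 250_000.0)
    eye: tuple[float, float] = (700.0, 5_000.0)
    yolk: tuple[float, float] = (3_000.0, 30_000.0)
    tail: tuple[float, float] = (2_000.0, 80_000.0)

    def __post_init__(self) -> None:
        for name in ("fish", "eye", "yolk", "tail"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"constraint {name}: need 0 <= min <= max")

    @classmethod
    def for_canvas(cls, shape: tuple[int, int], **overrides) -> "SizeConstraints":
        """Rescale the 512-px defaults to a canvas of the given height."""
        f = (shape[0] / 512.0) ** 2
        base = {
            name: (lo * f, hi * f)
            for name, (lo, hi) in (
                ("fish", cls.fish), ("eye", cls.eye),
                ("yolk", cls.yolk), ("tail", cls.tail),
            )
        }
        base.update(overrides)
        return cls(**base)


@dataclass
class AnatomyRegion:
    """One labelled connected anatomical region."""

    label: str
    mask: np.ndarray
    area: float
    centroid: tuple[float, float]  # (x, y)
    tip: tuple[float, float] | None = None  # caudal-most point (yolk)


@dataclass
class BodyAxis:
    """Ordered anterior→posterior body axis with its projection frame."""

    points: np.ndarray  # (N, 2) float, columns (x, y)
    origin: np.ndarray  # projection origin (x, y)
    unit: np.ndarray  # unit vector pointing anterior→posterior

    def __post_init__(self) -> None:
        s = self.s_of(self.points)
        if np.any(np.diff(s) < 0):
            raise ValueError("axis points must be ordered anterior -> posterior")

    def s_of(self, xy: np.ndarray) -> np.ndarray:
        """Arc position of points projected onto the axis direction."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        return (xy - self.origin) @ self.unit

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def flipped(self) -> "BodyAxis":
        return BodyAxis(self.points[::-1].copy(), self.origin, -self.unit)


@dataclass
class EmbryoSegmentation:
    """Full segmentation of one well: outline, anatomy, regions, axis."""

    fish_mask: np.ndarray
    body_axis: BodyAxis
    anatomy: dict[str, list[AnatomyRegion]] = field(default_factory=dict)
    region_map: np.ndarray | None = None
    tail_count: int = 0

    @property
    def fish_area(self) -> float:
        return float(np.count_nonzero(self.fish_mask))

    @property
    def eye_count(self) -> int:
        return len(self.anatomy.get("eye", []))

    @property
    def eye_areas(self) -> list[float]:
        return [r.area for r in self.anatomy.get("eye", [])]

    def region_area(self, name: str) -> float:
        if self.region_map is None:
            return 0.0
        idx = {v: k for k, v in REGION_NAMES.items()}[name]
        return float(np.count_nonzero(self.region_map == idx))

    def region_name_at(self, x: float, y: float) -> str:
        """Region label at a pixel; 'whole_fish_only' when unpartitioned."""
        if self.region_map is None:
            return "whole_fish_only"
        iy = int(np.clip(round(y), 0, self.region_map.shape[0] - 1))
        ix = int(np.clip(round(x), 0, self.region_map.shape[1] - 1))
        return REGION_NAMES.get(int(self.region_map[iy, ix]), "whole_fish_only")


@runtime_checkable
class Segmenter(Protocol):
    """Contract every segmenter (classical, learned, or oracle) honours."""

    def segment(self, brightfield: np.ndarray,
                constraints: SizeConstraints) -> EmbryoSegmentation | None:
        ...


# ---------------------------------------------------------------------------
# Reference implementation
# ---------------------------------------------------------------------------

def segment_fish(
    brightfield: np.ndarray, constraints: SizeConstraints
) -> np.ndarray | None:
    """Find the fish outline as the largest qualifying dark object.

    Returns a single-connected-component boolean mask whose area lies
    within the fish constraints, or None when no component qualifies
    (empty well, debris only).
    """
    img = np.asarray(brightfield, dtype=np.float32)
    if img.size == 0:
        raise ValueError("empty brightfield image")
    sm = ndimage.gaussian_filter(img, 2.0)
    background = float(np.median(sm))
    if background <= 0:
        return None
    dark = sm < FISH_THRESHOLD * background
    if not dark.any():
        return None
    # closing with an all-true border so a fish cropped by the frame keeps
    # touching it (the partial-fish QC check depends on this)
    dark = ndimage.binary_dilation(dark, structure=_disc(3))
    dark = ndimage.binary_erosion(dark, structure=_disc(3), border_value=1)
    dark = ndimage.binary_fill_holes(dark)
    labels, n = ndimage.label(dark)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    lo, hi = constraints.fish
    candidates = [i + 1 for i, a in enumerate(areas) if lo <= a <= hi]
    if not candidates:
        return None
    best = max(candidates, key=lambda i: areas[i - 1])
    return labels == best


def _disc(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def body_axis(fish_mask: np.ndarray, n_bins: int = 48) -> BodyAxis:
    """Centreline polyline through per-bin centroids along the major axis.

    The returned axis is *undirected* (arbitrary sign); orientation is
    fixed afterwards from the eye position or, failing that, body width.
    """
    ys, xs = np.nonzero(fish_mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    origin = pts.mean(axis=0)
    cov = np.cov((pts - origin).T)
    evals, evecs = np.linalg.eigh(cov)
    unit = evecs[:, int(np.argmax(evals))]
    s = (pts - origin) @ unit
    order = np.argsort(s)
    edges = np.linspace(s.min(), s.max(), n_bins + 1)
    centres = []
    for i in range(n_bins):
        sel = (s >= edges[i]) & (s <= edges[i + 1] if i == n_bins - 1 else s < edges[i + 1])
        if sel.any():
            centres.append(pts[sel].mean(axis=0))
    points = np.asarray(centres)
    return BodyAxis(points=points, origin=origin, unit=unit)


def _widths_along_axis(fish_mask: np.ndarray, axis: BodyAxis,
                       n_bins: int = 16) -> np.ndarray:
    ys, xs = np.nonzero(fish_mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    s = axis.s_of(pts)
    perp = np.array([-axis.unit[1], axis.unit[0]])
    d = (pts - axis.origin) @ perp
    edges = np.linspace(s.min(), s.max() + 1e-9, n_bins + 1)
    widths = np.zeros(n_bins)
    for i in range(n_bins):
        sel = (s >= edges[i]) & (s < edges[i + 1])
        if sel.any():
            widths[i] = np.percentile(np.abs(d[sel]), 90)
    return widths


def orient_axis(
    fish_mask: np.ndarray,
    axis: BodyAxis,
    eye_centroids: Sequence[tuple[float, float]] = (),
) -> BodyAxis:
    """Point the axis anterior→posterior.

    The end nearer the eye centroid is anterior; without an eye, the wider
    body end is anterior.
    """
    if eye_centroids:
        s_eyes = float(np.mean(axis.s_of(np.asarray(eye_centroids))))
        s_pts = axis.s_of(axis.points)
        mid = 0.5 * (s_pts[0] + s_pts[-1])
        flip = s_eyes > mid
    else:
        widths = _widths_along_axis(fish_mask, axis)
        q = max(1, len(widths) // 4)
        flip = widths[:q].mean() < widths[-q:].mean()
    return axis.flipped() if flip else axis


def _dark_blobs(brightfield: np.ndarray, fish_mask: np.ndarray) -> np.ndarray:
    """Binary mask of the darkest structures (eyes, yolk) inside the fish."""
    img = np.asarray(brightfield, dtype=np.float32)
    sm = ndimage.gaussian_filter(img, 1.5)
    inside = sm[fish_mask]
    body_level = float(np.median(inside))
    dark_level = float(inside.min())
    if body_level - dark_level < 1e-9:
        return np.zeros_like(fish_mask)
    thr = dark_level + DARK_BLOB_MIDPOINT * (body_level - dark_level)
    return fish_mask & (sm < thr)


def detect_eyes(
    brightfield: np.ndarray,
    fish_mask: np.ndarray | None,
    constraints: SizeConstraints,
    axis: BodyAxis | None = None,
    min_circularity: float = 0.55,
) -> list[AnatomyRegion]:
    """Dark, high-circularity blobs in the anterior half of the fish.

    When no oriented axis is supplied yet, candidates from the whole fish
    are returned (the caller orients the axis from them and re-filters).
    """
    if fish_mask is None or not fish_mask.any():
        return []
    blobs = _dark_blobs(brightfield, fish_mask)
    labels, n = ndimage.label(blobs)
    out: list[AnatomyRegion] = []
    lo, hi = constraints.eye
    for prop in skmeasure.regionprops(labels):
        if not (lo <= prop.area <= hi):
            continue
        perim = prop.perimeter
        circ = 4 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        if circ < min_circularity:
            continue
        cy, cx = prop.centroid
        if axis is not None:
            s_pts = axis.s_of(axis.points)
            s_mid = 0.5 * (s_pts[0] + s_pts[-1])
            if float(axis.s_of([(cx, cy)])[0]) > s_mid:
                continue
        out.append(
            AnatomyRegion("eye", labels == prop.label, float(prop.area), (cx, cy))
        )
    return out


def detect_yolk(
    brightfield: np.ndarray,
    fish_mask: np.ndarray | None,
    constraints: SizeConstraints,
    axis: BodyAxis | None = None,
    eyes: Sequence[AnatomyRegion] = (),
) -> AnatomyRegion | None:
    """Largest dark compact region in the anterior body, excluding eyes.

    Exposes its caudal-most point, the trunk/tail landmark.
    """
    if fish_mask is None or not fish_mask.any():
        return None
    blobs = _dark_blobs(brightfield, fish_mask)
    for eye in eyes:
        blobs &= ~eye.mask
    blobs = ndimage.binary_closing(blobs, structure=_disc(2))
    labels, n = ndimage.label(blobs)
    if n == 0:
        return None
    lo, hi = constraints.yolk
    best = None
    for prop in skmeasure.regionprops(labels):
        if not (lo <= prop.area <= hi):
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        return None
    mask = labels == best.label
    cy, cx = best.centroid
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    if axis is not None:
        tip_idx = int(np.argmax(axis.s_of(pts)))
    else:
        tip_idx = int(np.argmax(xs))
    tip = (float(xs[tip_idx]), float(ys[tip_idx]))
    return AnatomyRegion("yolk_sac", mask, float(best.area), (cx, cy), tip=tip)


def detect_tail(
    brightfield: np.ndarray,
    fish_mask: np.ndarray | None,
    constraints: SizeConstraints,
    axis: BodyAxis | None = None,
    trunk_tail_s: float | None = None,
    border_margin: int = 2,
) -> tuple[AnatomyRegion | None, int]:
    """Posterior terminus distal to the yolk landmark, and the tail count.

    ``tail_count`` is 1 only when the terminus lies fully inside the image
    (no pixel within ``border_margin`` of the frame) and its area meets the
    tail minimum — a fish whose tail is cropped by the well edge counts 0.
    """
    if fish_mask is None or not fish_mask.any() or axis is None:
        return None, 0
    ys, xs = np.nonzero(fish_mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    s = axis.s_of(pts)
    if trunk_tail_s is None:
        s_pts = axis.s_of(axis.points)
        trunk_tail_s = s_pts[0] + FALLBACK_FRACTIONS[1] * (s_pts[-1] - s_pts[0])
    sel = s >= trunk_tail_s
    if not sel.any():
        return None, 0
    mask = np.zeros_like(fish_mask)
    mask[ys[sel], xs[sel]] = True
    area = float(mask.sum())
    region = AnatomyRegion(
        "tail_fin", mask, area,
        (float(xs[sel].mean()), float(ys[sel].mean())),
    )
    h, w = fish_mask.shape
    m = border_margin
    touches = (
        mask[:m, :].any() or mask[-m:, :].any()
        or mask[:, :m].any() or mask[:, -m:].any()
    )
    lo, _hi = constraints.tail
    count = 1 if (not touches and area >= lo) else 0
    return region, count


def partition_regions(
    fish_mask: np.ndarray,
    axis: BodyAxis,
    eye_regions: Sequence[AnatomyRegion] = (),
    yolk_tip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Assign every fish pixel to head, trunk or tail along the body axis.

    The head/trunk boundary sits at the posterior eye edge plus a fixed
    fraction of body length; the trunk/tail boundary at the yolk's caudal
    tip.  Without landmarks the boundaries fall back to fixed fractions of
    the axis length.  The three regions are disjoint and cover the mask.
    """
    ys, xs = np.nonzero(fish_mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    s = axis.s_of(pts)
    s_pts = axis.s_of(axis.points)
    s0, s1 = float(s_pts[0]), float(s_pts[-1])
    span = s1 - s0
    if eye_regions:
        eye_edge = max(
            float(axis.s_of(np.column_stack(np.nonzero(r.mask)[::-1])).max())
            for r in eye_regions
        )
        s_head = eye_edge + HEAD_OFFSET_FRACTION * span
    else:
        s_head = s0 + FALLBACK_FRACTIONS[0] * span
    if yolk_tip is not None:
        s_tail = float(axis.s_of([yolk_tip])[0])
    else:
        s_tail = s0 + FALLBACK_FRACTIONS[1] * span
    s_head = min(s_head, s_tail)  # degenerate landmark safety
    out = np.zeros(fish_mask.shape, dtype=np.uint8)
    region = np.full(s.shape, REGION_TRUNK, dtype=np.uint8)
    region[s < s_head] = REGION_HEAD
    region[s >= s_tail] = REGION_TAIL
    out[ys, xs] = region
    return out


def measure_morphology(
    seg: EmbryoSegmentation, pixel_size: float | None = None
) -> dict[str, float]:
    """Morphometrics in physical units when a pixel size is given.

    Areas are pixel counts × pixel_size²; the fish length is the arc
    length of the body axis × pixel_size.
    """
    ps = 1.0 if pixel_size is None else float(pixel_size)
    out = {
        "fish_area": seg.fish_area * ps**2,
        "fish_length": seg.body_axis.length * ps,
        "eye_count": float(seg.eye_count),
        "eye_area": float(sum(seg.eye_areas)) * ps**2,
    }
    for name in ("head", "trunk", "tail"):
        out[f"{name}_area"] = seg.region_area(name) * ps**2
    return out


def write_overlay(
    brightfield: np.ndarray,
    seg: EmbryoSegmentation,
    path,
    dpi: int = 72,
) -> None:
    """Write a QC overlay PNG: outline, regions and anatomy on brightfield.

    One image per well, for eyeballing segmentation quality in a run.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = brightfield.shape
    fig, ax = plt.subplots(figsize=(w / dpi, h / dpi), dpi=dpi)
    ax.imshow(brightfield, cmap="gray", interpolation="nearest")
    ax.contour(seg.fish_mask, levels=[0.5], colors="yellow", linewidths=0.8)
    if seg.region_map is not None:
        for idx, colour in ((REGION_HEAD, "white"), (REGION_TRUNK, "blue"),
                            (REGION_TAIL, "red")):
            ax.contour(seg.region_map == idx, levels=[0.5], colors=colour,
                       linewidths=0.5)
    palette = {"eye": "magenta", "yolk_sac": "gold", "tail_fin": "cyan"}
    for label, regions in seg.anatomy.items():
        for region in regions:
            ax.contour(region.mask, levels=[0.5],
                       colors=palette.get(label, "green"), linewidths=0.6)
    ax.plot(seg.body_axis.points[:, 0], seg.body_axis.points[:, 1],
            color="lime", linewidth=0.6)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


class ReferenceSegmenter:
    """Classical dark-object reference segmenter implementing the contract."""

    def __init__(self, min_eye_circularity: float = 0.55):
        self.min_eye_circularity = min_eye_circularity

    def segment(self, brightfield: np.ndarray,
                constraints: SizeConstraints) -> EmbryoSegmentation | None:
        mask = segment_fish(brightfield, constraints)
        if mask is None:
            return None
        axis = body_axis(mask)
        # eye candidates anywhere first: they define which end is anterior
        candidates = detect_eyes(
            brightfield, mask, constraints, axis=None,
            min_circularity=self.min_eye_circularity,
        )
        axis = orient_axis(mask, axis, [c.centroid for c in candidates])
        eyes = detect_eyes(
            brightfield, mask, constraints, axis=axis,
            min_circularity=self.min_eye_circularity,
        )
        yolk = detect_yolk(brightfield, mask, constraints, axis=axis, eyes=eyes)
        yolk_tip = yolk.tip if yolk is not None else None
        region_map = partition_regions(mask, axis, eyes, yolk_tip)
        trunk_tail_s = (
            float(axis.s_of([yolk_tip])[0]) if yolk_tip is not None else None
        )
        tail, tail_count = detect_tail(
            brightfield, mask, constraints, axis=axis, trunk_tail_s=trunk_tail_s
        )
        anatomy: dict[str, list[AnatomyRegion]] = {"eye": eyes}
        if yolk is not None:
            anatomy["yolk_sac"] = [yolk]
        if tail is not None:
            anatomy["tail_fin"] = [tail]
        return EmbryoSegmentation(
            fish_mask=mask,
            body_axis=axis,
            anatomy=anatomy,
            region_map=region_map,
            tail_count=tail_count,
        )
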