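"""Synthetic 96-well plate generator with exhaustive ground truth.

Stands in for the microscope: renders brightfield + fluorescence z-stack
tiles of model zebrafish embryos so that every stage of the analysis
pipeline can be exercised and scored against known truth at desk scale.

The rendered embryo is a tapered capsule (darker than background, as under
transmitted light) carrying the anatomy the analysis relies on: one eye
when lying on its side, two when dorsal, a yolk sac with its caudal
extension whose tip marks the trunk/tail boundary, and a thin tail-fin
margin.  Fluorescence channels carry Gaussian-profile spots in two
amplitude classes (dim ≈ 3× the local background s.d., bright ≈ 10×,
mirroring GFP-lo stem cells vs GFP-hi thrombocytes) on top of a smooth
autofluorescence haze over the head and yolk — the confounder that defeats
naive global thresholding.  Brightfield z-slices blur with distance from
the focus plane; each fluorescent spot peaks on one z-slice so that no
single slice contains all the signal and the maximum projection is
genuinely needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .plate_io import (
    DEFAULT_FILENAME_PATTERN,
    FieldImage,
    PlateSpec,
    write_field_image,
)

__all__ = [
    "PRESENTATIONS",
    "EmbryoLayout",
    "SpotTruth",
    "SpotLaw",
    "NoiseParams",
    "GroundTruth",
    "WellRender",
    "SyntheticPlate",
    "sample_layout",
    "sample_spots",
    "neuromast_spots",
    "vessel_spots",
    "render_well",
    "generate_plate",
    "DEFAULT_PRESENTATION_MIX",
    "HSPC_LAWS",
]

PRESENTATIONS = ("lateral_left", "lateral_right", "dorsal", "partial", "absent")

#: default mix: ~95% usable side-on fish, ~5% misoriented/empty per plate
DEFAULT_PRESENTATION_MIX: dict[str, float] = {
    "lateral_left": 0.475,
    "lateral_right": 0.475,
    "dorsal": 0.02,
    "partial": 0.02,
    "absent": 0.01,
}

REGION_NAMES = ("head", "trunk", "tail")


@dataclass(frozen=True)
class SpotLaw:
    """How many spots of one amplitude class to place in one region."""

    channel: str
    region: str  # head | trunk | tail | outside_fish
    amplitude_class: str  # dim | bright
    law: str  # poisson | constant
    value: float

    def draw(self, rng: np.random.Generator) -> int:
        if self.law == "poisson":
            return int(rng.poisson(self.value))
        if self.law == "constant":
            return int(self.value)
        raise ValueError(f"unknown spot count law {self.law!r}")


#: the stem-cell counting assay: dim spots in the caudal haematopoietic
#: tissue (tail), a few bright circulating cells in the trunk
HSPC_LAWS: tuple[SpotLaw, ...] = (
    SpotLaw("GFP", "tail", "dim", "poisson", 30.0),
    SpotLaw("GFP", "trunk", "bright", "poisson", 6.0),
)


@dataclass(frozen=True)
class NoiseParams:
    """Image formation parameters shared by all wells of a plate.

    Intensities are on a 16-bit scale.  Shot noise is Poisson with the
    given camera gain (ADU per photoelectron), read noise additive
    Gaussian.  ``dim_amplitude`` ≈ 3× and ``bright_amplitude`` ≈ 10× the
    fluorescence local background s.d. sqrt(fl_background·fl_gain +
    read_noise_sd²) ≈ 31 at the defaults.
    """

    bf_background: float = 30000.0
    fl_background: float = 300.0
    bf_gain: float = 4.0
    fl_gain: float = 2.0
    read_noise_sd: float = 20.0
    shot_noise: bool = True
    texture_amplitude: float = 0.02
    blur_per_plane: float = 2.5
    spot_sigma: float = 2.0
    spot_z_sigma: float = 0.7
    haze_amplitude: float = 800.0
    haze_sigma_frac: float = 0.10  # of canvas height; diffuse by construction
    dim_amplitude: float = 95.0
    bright_amplitude: float = 310.0
    amplitude_jitter: float = 0.08

    @classmethod
    def noise_free(cls, **kw) -> "NoiseParams":
        return cls(shot_noise=False, read_noise_sd=0.0, texture_amplitude=0.0, **kw)

    def spot_amplitude(self, amplitude_class: str) -> float:
        if amplitude_class == "dim":
            return self.dim_amplitude
        if amplitude_class == "bright":
            return self.bright_amplitude
        raise ValueError(f"unknown amplitude class {amplitude_class!r}")


@dataclass
class EmbryoLayout:
    """Geometric truth for one well's embryo.

    All coordinates are (x, y) in the stitched-well canvas frame.  The body
    is a tapered capsule from ``anchor`` (anterior tip) along ``angle`` for
    ``length`` px; eyes, yolk and fin are positioned in body coordinates
    (s along the axis, d perpendicular, d > 0 ventral/down).
    """

    presentation: str
    canvas_shape: tuple[int, int]  # (H, W)
    anchor: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0
    length: float = 0.0
    half_width_head: float = 0.0
    half_width_tail: float = 0.0
    eye_centres: tuple[tuple[float, float], ...] = ()
    eye_radius: float = 0.0
    yolk_centre: tuple[float, float] | None = None
    yolk_axes: tuple[float, float] = (0.0, 0.0)
    yolk_tip: tuple[float, float] | None = None
    fin_margin: float = 0.0
    fin_start_frac: float = 0.6
    z_focus: int = 2
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.presentation not in PRESENTATIONS:
            raise ValueError(f"unknown presentation {self.presentation!r}")
        n_eyes = len(self.eye_centres)
        if self.presentation in ("lateral_left", "lateral_right", "partial") and n_eyes != 1:
            raise ValueError("lateral/partial presentations carry exactly one eye")
        if self.presentation == "dorsal" and n_eyes != 2:
            raise ValueError("dorsal presentation carries exactly two eyes")
        if self.presentation == "absent" and n_eyes != 0:
            raise ValueError("absent presentation carries no anatomy")

    # -- body coordinate helpers -------------------------------------------
    @property
    def _unit(self) -> tuple[float, float]:
        return (math.cos(self.angle), math.sin(self.angle))

    def to_canvas(self, s: float, d: float) -> tuple[float, float]:
        ux, uy = self._unit
        return (self.anchor[0] + s * ux - d * uy, self.anchor[1] + s * uy + d * ux)

    def to_body(self, x: float, y: float) -> tuple[float, float]:
        ux, uy = self._unit
        dx, dy = x - self.anchor[0], y - self.anchor[1]
        return (dx * ux + dy * uy, -dx * uy + dy * ux)

    def _grid_body_coords(self) -> tuple[np.ndarray, np.ndarray]:
        if "grid" not in self._cache:
            H, W = self.canvas_shape
            ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
            ux, uy = self._unit
            dx, dy = xs - self.anchor[0], ys - self.anchor[1]
            self._cache["grid"] = (dx * ux + dy * uy, -dx * uy + dy * ux)
        return self._cache["grid"]

    def half_width(self, t: np.ndarray | float) -> np.ndarray | float:
        wh, wt = self.half_width_head, self.half_width_tail
        return wt + (wh - wt) * (1.0 - t) ** 0.9

    # -- masks --------------------------------------------------------------
    def body_mask(self) -> np.ndarray:
        if "body" not in self._cache:
            self._cache["body"] = self._compute_body_mask()
        return self._cache["body"]

    def _compute_body_mask(self) -> np.ndarray:
        if self.presentation == "absent":
            return np.zeros(self.canvas_shape, dtype=bool)
        s, d = self._grid_body_coords()
        t = np.clip(s / self.length, 0.0, 1.0)
        # distance to the clipped centreline point gives rounded end caps
        ds = s - t * self.length
        dist2 = ds * ds + d * d
        w = self.half_width(t)
        return dist2 <= w * w

    def eye_masks(self) -> list[np.ndarray]:
        H, W = self.canvas_shape
        ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
        out = []
        for (cx, cy) in self.eye_centres:
            out.append((xs - cx) ** 2 + (ys - cy) ** 2 <= self.eye_radius**2)
        return out

    def yolk_mask(self) -> np.ndarray:
        if self.yolk_centre is None:
            return np.zeros(self.canvas_shape, dtype=bool)
        s, d = self._grid_body_coords()
        sc, dc = self.to_body(*self.yolk_centre)
        a, b = self.yolk_axes
        mask = ((s - sc) / a) ** 2 + ((d - dc) / b) ** 2 <= 1.0
        if self.yolk_tip is not None:
            # tapered caudal extension of the yolk towards its tip
            s0, d0 = sc + 0.55 * a, dc * 0.8
            s1, d1 = self.to_body(*self.yolk_tip)
            seg_len = max(s1 - s0, 1.0)
            u = np.clip((s - s0) / seg_len, 0.0, 1.0)
            dd = d - (d0 + u * (d1 - d0))
            ss = s - (s0 + u * seg_len)
            w = 0.55 * b * (1 - u) + 0.12 * b * u
            mask |= (ss * ss + dd * dd) <= w * w
        return mask & self.body_mask()

    def fin_mask(self, body: np.ndarray | None = None) -> np.ndarray:
        """Thin translucent margin band around the posterior body."""
        if self.presentation == "absent" or self.fin_margin <= 0:
            return np.zeros(self.canvas_shape, dtype=bool)
        body = self.body_mask() if body is None else body
        r = max(1, int(round(self.fin_margin)))
        dilated = ndimage.binary_dilation(body, iterations=r)
        s, _ = self._grid_body_coords()
        return dilated & ~body & (s > self.fin_start_frac * self.length)

    # -- truth region partition --------------------------------------------
    def region_boundaries(self) -> tuple[float, float]:
        """(s_head_trunk, s_trunk_tail) along the body axis."""
        if self.eye_centres:
            s_eyes = [self.to_body(*c)[0] for c in self.eye_centres]
            s_head = max(s_eyes) + self.eye_radius + 0.05 * self.length
        else:
            s_head = 0.25 * self.length
        if self.yolk_tip is not None:
            s_tail = self.to_body(*self.yolk_tip)[0]
        else:
            s_tail = 0.55 * self.length
        return (s_head, s_tail)

    def region_of_s(self, s: float) -> str:
        s_head, s_tail = self.region_boundaries()
        if s < s_head:
            return "head"
        if s < s_tail:
            return "trunk"
        return "tail"

    def region_map(self, body: np.ndarray | None = None) -> np.ndarray:
        """Truth label map over the body mask: 0 outside, 1 head, 2 trunk, 3 tail."""
        body = self.body_mask() if body is None else body
        out = np.zeros(self.canvas_shape, dtype=np.uint8)
        if self.presentation == "absent":
            return out
        s, _ = self._grid_body_coords()
        s_head, s_tail = self.region_boundaries()
        out[body] = 2
        out[body & (s < s_head)] = 1
        out[body & (s >= s_tail)] = 3
        return out


@dataclass(frozen=True)
class SpotTruth:
    """One fluorescent spot placed by the generator."""

    centre: tuple[float, float]
    radius: float
    amplitude_class: str
    channel: str
    region: str
    z_index: int
    amplitude: float
    sigma: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows about one well."""

    well: str
    layout: EmbryoLayout
    spots: tuple[SpotTruth, ...] = ()
    fish_area: float = 0.0
    eye_areas: tuple[float, ...] = ()
    region_areas: dict[str, float] = field(default_factory=dict)

    @property
    def eye_area(self) -> float:
        return float(sum(self.eye_areas))

    def counts(self) -> dict[tuple[str, str], int]:
        """Tally of spots per (channel, region)."""
        out: dict[tuple[str, str], int] = {}
        for sp in self.spots:
            key = (sp.channel, sp.region)
            out[key] = out.get(key, 0) + 1
        return out

    def count(self, channel: str, region: str) -> int:
        return self.counts().get((channel, region), 0)

    def total_spot_area(self, channel: str) -> float:
        return float(
            sum(math.pi * sp.radius**2 for sp in self.spots if sp.channel == channel)
        )


# ---------------------------------------------------------------------------
# Layout sampling
# ---------------------------------------------------------------------------

def _canvas_shape(spec: PlateSpec) -> tuple[int, int]:
    return (spec.tile_shape[0], spec.stitched_width)


def sample_layout(
    presentation: str,
    spec: PlateSpec,
    rng: np.random.Generator,
) -> EmbryoLayout:
    """Draw one embryo layout; all sizes scale with the canvas geometry.

    Fish are rendered near-horizontal (angle jitter ≤ ±5°), head towards
    the first field for ``lateral_left``/``dorsal`` and mirrored for
    ``lateral_right``; ``partial`` places the tail tip beyond the imaged
    strip.
    """
    H, W = _canvas_shape(spec)
    z_focus = int(np.clip(spec.z_planes // 2 + rng.integers(-1, 2), 0, spec.z_planes - 1))
    if presentation == "absent":
        return EmbryoLayout("absent", (H, W), z_focus=z_focus)

    length = 0.69 * W * rng.normal(1.0, 0.02)
    w_head = 0.145 * H * rng.normal(1.0, 0.04)
    w_tail = 0.027 * H * rng.normal(1.0, 0.05)
    eye_r = 0.051 * H * rng.normal(1.0, 0.05)
    angle = math.radians(rng.uniform(-4.0, 4.0))
    ax = rng.uniform(0.07, 0.11) * W
    ay = H / 2 + rng.uniform(-0.04, 0.04) * H
    if presentation == "partial":
        ax = W - 0.72 * length  # tail tip ~0.28·L beyond the right edge
    flip = presentation == "lateral_right"
    if flip:
        ax = W - 1 - ax
        angle = math.pi - angle

    ux, uy = math.cos(angle), math.sin(angle)

    def to_canvas(s: float, d: float) -> tuple[float, float]:
        return (ax + s * ux - d * uy, ay + s * uy + d * ux)

    s_eye = 0.085 * length
    if presentation == "dorsal":
        d_off = 0.42 * w_head
        eyes = (to_canvas(s_eye, -d_off), to_canvas(s_eye, d_off))
    else:
        eyes = (to_canvas(s_eye, -0.025 * H),)
    return EmbryoLayout(
        presentation=presentation,
        canvas_shape=(H, W),
        anchor=(ax, ay),
        angle=angle,
        length=length,
        half_width_head=w_head,
        half_width_tail=w_tail,
        eye_radius=eye_r,
        fin_margin=max(2.0, 0.012 * H),
        z_focus=z_focus,
        eye_centres=eyes,
        yolk_centre=to_canvas(0.30 * length, 0.025 * H),
        yolk_axes=(0.16 * H, 0.07 * H),
        yolk_tip=to_canvas(0.52 * length, 0.018 * H),
    )


# ---------------------------------------------------------------------------
# Spot sampling
# ---------------------------------------------------------------------------

def _placement_mask(layout: EmbryoLayout, region: str, margin: int,
                    boundary_margin: float) -> np.ndarray:
    """Pixels where a spot of the given truth region may be centred."""
    H, W = layout.canvas_shape
    body = layout.body_mask()
    if region == "outside_fish":
        ok = ~ndimage.binary_dilation(body, iterations=margin)
        ok[:margin, :] = ok[-margin:, :] = False
        ok[:, :margin] = ok[:, -margin:] = False
        return ok
    rmap = layout.region_map(body)
    idx = 1 + REGION_NAMES.index(region)
    mask = rmap == idx
    if margin > 0:
        mask = ndimage.binary_erosion(mask, iterations=margin)
    # keep spots clear of the head/trunk and trunk/tail boundaries so that
    # small landmark-detection offsets cannot flip their region assignment
    s, _ = layout._grid_body_coords()
    s_head, s_tail = layout.region_boundaries()
    mask &= np.abs(s - s_head) > boundary_margin
    mask &= np.abs(s - s_tail) > boundary_margin
    return mask


def sample_spots(
    layout: EmbryoLayout,
    laws: Sequence[SpotLaw],
    spec: PlateSpec,
    noise: NoiseParams,
    rng: np.random.Generator,
    min_separation: float | None = None,
) -> list[SpotTruth]:
    """Place spots per region/class law with a minimum pairwise separation.

    When a region cannot hold the drawn number of spots at the required
    separation, fewer are placed; the returned list is the truth.
    """
    if layout.presentation == "absent":
        return []
    H, W = layout.canvas_shape
    sigma = noise.spot_sigma
    # spots must stay separable even at a near-zero detection threshold,
    # where a blob's footprint extends to roughly 4 smoothed sigmas
    min_sep = min_separation if min_separation is not None else max(10.0, 8.0 * sigma)
    margin = max(3, int(math.ceil(sigma)) + 2)
    placed: list[tuple[float, float]] = []
    spots: list[SpotTruth] = []
    for law in laws:
        n = law.draw(rng)
        if n <= 0:
            continue
        ok = _placement_mask(layout, law.region, margin, boundary_margin=18.0 * H / 512.0)
        cand_y, cand_x = np.nonzero(ok)
        if cand_y.size == 0:
            continue
        order = rng.permutation(cand_y.size)
        got = 0
        for i in order:
            if got >= n:
                break
            x, y = float(cand_x[i]), float(cand_y[i])
            if any((x - px) ** 2 + (y - py) ** 2 < min_sep**2 for px, py in placed):
                continue
            amp = noise.spot_amplitude(law.amplitude_class)
            amp *= 1.0 + rng.uniform(-noise.amplitude_jitter, noise.amplitude_jitter)
            spots.append(
                SpotTruth(
                    centre=(x, y),
                    radius=2.0 * sigma,
                    amplitude_class=law.amplitude_class,
                    channel=law.channel,
                    region=law.region,
                    z_index=int(rng.integers(0, spec.z_planes)),
                    amplitude=float(amp),
                    sigma=float(sigma),
                )
            )
            placed.append((x, y))
            got += 1
    return spots


def neuromast_spots(
    layout: EmbryoLayout,
    spec: PlateSpec,
    noise: NoiseParams,
    rng: np.random.Generator,
    channel: str = "YOPRO",
    n: int = 14,
    amplitude_scale: float = 1.0,
    size_scale: float = 1.0,
) -> list[SpotTruth]:
    """Bright hair-cell clusters spaced along the lateral line.

    ``amplitude_scale`` and ``size_scale`` emulate hair-cell degradation:
    dimmer, smaller neuromasts after an ototoxic treatment.
    """
    if layout.presentation == "absent":
        return []
    sigma = 3.2 * size_scale
    spots = []
    for i in range(n):
        s = (0.10 + 0.82 * i / max(n - 1, 1)) * layout.length
        d = rng.uniform(-0.3, 0.3) * layout.half_width(s / layout.length)
        x, y = layout.to_canvas(s, d)
        amp = noise.bright_amplitude * amplitude_scale * (1 + rng.uniform(-0.05, 0.05))
        spots.append(
            SpotTruth((x, y), 2.0 * sigma, "bright", channel,
                      layout.region_of_s(s), int(rng.integers(0, spec.z_planes)),
                      float(amp), float(sigma))
        )
    return spots


def vessel_spots(
    layout: EmbryoLayout,
    spec: PlateSpec,
    noise: NoiseParams,
    rng: np.random.Generator,
    channel: str = "mCherry",
    n_vessels: int = 12,
    keep_fraction: float = 1.0,
) -> list[SpotTruth]:
    """A comb of short vertical vessel-like fluorescent segments.

    Each vessel is a dense chain of overlapping bright spots rising from
    the body axis, emulating intersegmental vessels; ``keep_fraction``
    truncates the comb (fewer vessels → less total fluorescent area).
    """
    if layout.presentation == "absent":
        return []
    sigma = 1.8
    n_keep = int(round(n_vessels * keep_fraction))
    spots = []
    for i in range(n_keep):
        s = (0.30 + 0.55 * i / max(n_vessels - 1, 1)) * layout.length
        height = 0.55 * layout.half_width(s / layout.length)
        for k in range(6):
            d = -height * k / 5.0
            x, y = layout.to_canvas(s, d)
            amp = noise.bright_amplitude * (1 + rng.uniform(-0.05, 0.05))
            spots.append(
                SpotTruth((x, y), 2.0 * sigma, "bright", channel,
                          layout.region_of_s(s), int(rng.integers(0, spec.z_planes)),
                          float(amp), float(sigma))
            )
    return spots


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class WellRender:
    """Rendered tiles plus the seamless canvases they were cut from."""

    fields: list[FieldImage]
    canvases: dict[str, np.ndarray]  # channel -> (z, H, W) uint16
    truth: GroundTruth


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _apply_noise(img: np.ndarray, gain: float, noise: NoiseParams,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    read_var = noise.read_noise_sd**2
    if noise.shot_noise:
        pos = np.maximum(out, 0.0)
        if pos.min() / gain >= 50.0:
            # Gaussian approximation to Poisson shot noise, excellent at
            # these photon counts; read noise folded into the same draw
            sd = np.sqrt(pos * gain + read_var)
            return out + rng.standard_normal(out.shape, dtype=np.float32) * sd
        out = rng.poisson(pos / gain) * gain
    if read_var > 0:
        out = out + rng.standard_normal(out.shape, dtype=np.float32) * noise.read_noise_sd
    return out


def _texture_field(shape: tuple[int, int], amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency multiplicative well texture (uneven lighting)."""
    if amplitude <= 0:
        return np.ones(shape)
    H, W = shape
    coarse = rng.normal(0.0, 1.0, (6, max(6, round(6 * W / H))))
    zoomed = ndimage.zoom(coarse, (H / coarse.shape[0], W / coarse.shape[1]), order=1)
    return 1.0 + amplitude * zoomed[:H, :W]


def _cut_tiles(canvas: np.ndarray, spec: PlateSpec, well: str,
               channel: str) -> list[FieldImage]:
    H, w_tile = spec.tile_shape
    stride = w_tile - round(spec.overlap_fraction * w_tile)
    fields = []
    for f in range(spec.fields_per_well):
        x0 = f * stride
        for z in range(canvas.shape[0]):
            fields.append(
                FieldImage(well, f, channel, z, canvas[z, :, x0 : x0 + w_tile])
            )
    return fields


def render_well(
    layout: EmbryoLayout,
    spots: Sequence[SpotTruth],
    spec: PlateSpec,
    noise: NoiseParams,
    rng: np.random.Generator,
    well: str = "A01",
) -> WellRender:
    """Render one well's z-stack tiles for every configured channel.

    Brightfield shows the body darker than background with eyes and yolk
    darkest; each z-slice is blurred with kernel width proportional to
    |z − z_focus|.  Fluorescence slices carry the autofluorescence haze
    plus each spot at an amplitude that decays away from its own best
    z-slice.  Deterministic for a fixed generator state.
    """
    H, W = _canvas_shape(spec)
    for sp in spots:
        x, y = sp.centre
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"spot centre {sp.centre} outside the {H}x{W} canvas")

    body = layout.body_mask()
    eyes = layout.eye_masks()
    yolk = layout.yolk_mask()
    fin = layout.fin_mask(body)

    # ground truth from the rasterized layout
    rmap = layout.region_map(body)
    region_areas = {
        name: float(np.count_nonzero(rmap == i + 1))
        for i, name in enumerate(REGION_NAMES)
    }
    truth = GroundTruth(
        well=well,
        layout=layout,
        spots=tuple(spots),
        fish_area=float(body.sum()),
        eye_areas=tuple(float(m.sum()) for m in eyes),
        region_areas=region_areas,
    )

    texture = _texture_field((H, W), noise.texture_amplitude, rng).astype(np.float32)
    canvases: dict[str, np.ndarray] = {}

    # -- brightfield --------------------------------------------------------
    factor = np.ones((H, W), dtype=np.float32)
    factor[fin] = 0.88
    factor[body] = 0.62
    factor[yolk] = 0.30
    for m in eyes:
        factor[m & body] = 0.24
    factor = ndimage.gaussian_filter(factor, 1.0)  # anti-alias edges
    bf_sharp = (noise.bf_background * texture * factor).astype(np.float32)
    bf_stack = np.empty((spec.z_planes, H, W), dtype=np.uint16)
    blurred: dict[float, np.ndarray] = {}
    for z in range(spec.z_planes):
        sig = noise.blur_per_plane * abs(z - layout.z_focus)
        if sig not in blurred:
            blurred[sig] = (
                ndimage.gaussian_filter(bf_sharp, sig, truncate=3.0)
                if sig > 0
                else bf_sharp
            )
        bf_stack[z] = _quantize(_apply_noise(blurred[sig], noise.bf_gain, noise, rng))
    canvases[spec.brightfield.name] = bf_stack

    # -- fluorescence -------------------------------------------------------
    haze_sigma = noise.haze_sigma_frac * H
    head_mask = (rmap == 1)
    haze_src = (head_mask | yolk).astype(np.float32)
    haze = (
        noise.haze_amplitude * ndimage.gaussian_filter(haze_src, haze_sigma)
        if noise.haze_amplitude > 0 and haze_src.any()
        else np.zeros((H, W), dtype=np.float32)
    )
    for ch in spec.fluorescence_channels:
        base = (noise.fl_background * texture + haze).astype(np.float32)
        ch_spots = [sp for sp in spots if sp.channel == ch.name]
        stack = np.empty((spec.z_planes, H, W), dtype=np.uint16)
        for z in range(spec.z_planes):
            img = base.copy()
            for sp in ch_spots:
                dz = z - sp.z_index
                amp = sp.amplitude * math.exp(-(dz * dz) / (2 * noise.spot_z_sigma**2))
                if amp < 1.0:
                    continue
                _add_gaussian_spot(img, sp.centre, amp, sp.sigma)
            stack[z] = _quantize(_apply_noise(img, noise.fl_gain, noise, rng))
        canvases[ch.name] = stack

    fields: list[FieldImage] = []
    for name, stack in canvases.items():
        fields.extend(_cut_tiles(stack, spec, well, name))
    layout._cache.clear()  # the coordinate grids are large; drop them
    return WellRender(fields=fields, canvases=canvases, truth=truth)


def _add_gaussian_spot(img: np.ndarray, centre: tuple[float, float],
                       amplitude: float, sigma: float) -> None:
    H, W = img.shape
    cx, cy = centre
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2)
    )


# ---------------------------------------------------------------------------
# Oracle segmentation from ground truth
# ---------------------------------------------------------------------------

def truth_segmentation(truth: GroundTruth):
    """Build an :class:`~.segment.EmbryoSegmentation` from generator truth.

    Drop-in oracle for the segmenter contract: running the pipeline with
    this segmentation makes every downstream metric answerable against
    truth exactly, isolating quantification errors from segmentation
    errors.  Returns None for absent wells.
    """
    from .segment import AnatomyRegion, BodyAxis, EmbryoSegmentation

    lay = truth.layout
    if lay.presentation == "absent":
        return None
    body = lay.body_mask()
    ss = np.linspace(0.0, lay.length, 49)
    points = np.asarray([lay.to_canvas(s, 0.0) for s in ss])
    axis = BodyAxis(
        points=points,
        origin=np.asarray(lay.anchor, dtype=np.float64),
        unit=np.asarray(lay._unit, dtype=np.float64),
    )
    anatomy: dict[str, list] = {
        "eye": [
            AnatomyRegion("eye", m, float(m.sum()), c)
            for m, c in zip(lay.eye_masks(), lay.eye_centres)
        ]
    }
    yolk = lay.yolk_mask()
    if yolk.any():
        ys, xs = np.nonzero(yolk)
        anatomy["yolk_sac"] = [
            AnatomyRegion(
                "yolk_sac", yolk, float(yolk.sum()),
                (float(xs.mean()), float(ys.mean())), tip=lay.yolk_tip,
            )
        ]
    seg = EmbryoSegmentation(
        fish_mask=body,
        body_axis=axis,
        anatomy=anatomy,
        region_map=lay.region_map(body),
        tail_count=0 if lay.presentation == "partial" else 1,
    )
    lay._cache.clear()
    return seg


# ---------------------------------------------------------------------------
# Plate generation
# ---------------------------------------------------------------------------

def allocate_presentations(
    n_wells: int, mix: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    """Integer allocation of presentations (largest remainder), shuffled."""
    items = [(p, v) for p, v in mix.items() if v != 0]
    for p, _ in items:
        if p not in PRESENTATIONS:
            raise ValueError(f"unknown presentation {p!r}")
    values = np.array([v for _, v in items], dtype=float)
    if np.any(values < 0):
        raise ValueError("presentation mix entries must be non-negative")
    if np.all(values == np.round(values)) and int(values.sum()) == n_wells:
        counts = values.astype(int)
    else:
        total = values.sum()
        if total <= 0:
            raise ValueError("presentation mix must have positive total")
        exact = values / total * n_wells
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for i in np.argsort(-rem)[: n_wells - counts.sum()]:
            counts[i] += 1
    out: list[str] = []
    for (p, _), c in zip(items, counts):
        out.extend([p] * int(c))
    perm = rng.permutation(n_wells)
    return [out[i] for i in perm]


@dataclass
class SyntheticPlate:
    """A generated plate: eager layouts/truth, lazily rendered images.

    Rendering a well twice returns bit-identical images: every well owns a
    seed derived from the master seed, re-used on each render.
    """

    spec: PlateSpec
    noise: NoiseParams
    truth: dict[str, GroundTruth]
    _render_seeds: dict[str, np.random.SeedSequence]
    _cache: dict[str, WellRender] = field(default_factory=dict)

    def wells(self) -> list[str]:
        return sorted(self.truth)

    def render(self, well: str, cache: bool = False) -> WellRender:
        if well in self._cache:
            return self._cache[well]
        t = self.truth[well]
        rng = np.random.default_rng(self._render_seeds[well])
        out = render_well(t.layout, t.spots, self.spec, self.noise, rng, well=well)
        if cache:
            self._cache[well] = out
        return out

    def well_fields(self, well: str) -> list[FieldImage]:
        return self.render(well).fields

    def iter_wells(self) -> Iterator[tuple[str, WellRender]]:
        for well in self.wells():
            yield well, self.render(well)

    # -- truth tables --------------------------------------------------------
    def counts_table(self) -> pd.DataFrame:
        channels = [c.name for c in self.spec.fluorescence_channels]
        regions = REGION_NAMES + ("outside_fish",)
        rows = []
        for well in self.wells():
            t = self.truth[well]
            counts = t.counts()
            for ch in channels:
                for rg in regions:
                    rows.append(
                        {"well": well, "channel": ch, "region": rg,
                         "count": counts.get((ch, rg), 0)}
                    )
        return pd.DataFrame(rows)

    def layout_table(self) -> pd.DataFrame:
        rows = []
        for well in self.wells():
            t = self.truth[well]
            lay = t.layout
            row = {
                "well": well,
                "presentation": lay.presentation,
                "anchor_x": lay.anchor[0],
                "anchor_y": lay.anchor[1],
                "angle_deg": math.degrees(lay.angle),
                "length_px": lay.length,
                "eye_radius_px": lay.eye_radius,
                "z_focus": lay.z_focus,
                "fish_area_px2": t.fish_area,
                "eye_area_px2": t.eye_area,
            }
            for ch in self.spec.fluorescence_channels:
                row[f"{ch.name}_total_spot_area_px2"] = t.total_spot_area(ch.name)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path,
              pattern: str = DEFAULT_FILENAME_PATTERN) -> Path:
        """Write every tile as TIFF plus the ground-truth CSV tables."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for well in self.wells():
            for fi in self.render(well).fields:
                write_field_image(out_dir, fi, pattern)
        self.counts_table().to_csv(out_dir / "truth_counts.csv", index=False)
        self.layout_table().to_csv(out_dir / "truth_layout.csv", index=False)
        return out_dir


def generate_plate(
    n_wells: int = 96,
    presentation_mix: Mapping[str, float] | None = None,
    laws: Sequence[SpotLaw] = HSPC_LAWS,
    spec: PlateSpec | None = None,
    seed: int = 0,
    noise: NoiseParams | None = None,
    spot_sampler: Callable[..., list[SpotTruth]] | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticPlate:
    """Generate a synthetic plate of ``n_wells`` wells.

    Presentations are allocated by largest remainder from the mix (or taken
    literally when the mix is integer counts summing to ``n_wells``).  Each
    well draws layout, spots and render noise from its own seed derived
    from the master ``seed``, so plates are reproducible well-by-well.
    ``spot_sampler`` overrides the default law-driven sampler (signature
    ``(layout, spec, noise, rng) -> list[SpotTruth]``), which the
    neuromast/vessel assay generators use.
    """
    spec = spec or PlateSpec()
    noise = noise or NoiseParams()
    if n_wells < 1 or n_wells > spec.n_wells:
        raise ValueError(f"n_wells must be in [1, {spec.n_wells}]")
    mix = dict(presentation_mix or DEFAULT_PRESENTATION_MIX)
    master = np.random.SeedSequence(seed)
    alloc_rng = np.random.default_rng(master.spawn(1)[0])
    presentations = allocate_presentations(n_wells, mix, alloc_rng)
    wells = spec.wells()[:n_wells]
    truth: dict[str, GroundTruth] = {}
    render_seeds: dict[str, np.random.SeedSequence] = {}
    for well, pres in zip(wells, presentations):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(1, wells.index(well)))
        layout_ss, render_ss = child.spawn(2)
        rng = np.random.default_rng(layout_ss)
        layout = sample_layout(pres, spec, rng)
        if spot_sampler is not None:
            spots = spot_sampler(layout, spec, noise, rng)
        else:
            spots = sample_spots(layout, laws, spec, noise, rng)
        body = layout.body_mask()
        rmap = layout.region_map(body)
        truth[well] = GroundTruth(
            well=well,
            layout=layout,
            spots=tuple(spots),
            fish_area=float(body.sum()),
            eye_areas=tuple(float(m.sum()) for m in layout.eye_masks()),
            region_areas={
                name: float(np.count_nonzero(rmap == i + 1))
                for i, name in enumerate(REGION_NAMES)
            },
        )
        layout._cache.clear()
        render_seeds[well] = render_ss
    plate = SyntheticPlate(spec=spec, noise=noise, truth=truth,
                           _render_seeds=render_seeds)
    if out_dir is not None:
        plate.write(out_dir)
    return plate
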