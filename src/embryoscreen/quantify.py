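"""Fluorescent granule detection, region assignment, metrics and QC.

Detection runs a fixed operator chain — smoothing, background
subtraction, thresholding, connected components, area constraints — and
keeps a component only if its centroid lies inside the fish outline.
Background subtraction is a morphological opening (rolling-ball
equivalent) with a disc wide enough to pass the diffuse head/yolk
autofluorescence haze into the background estimate while leaving compact
granules in the foreground; with ``k_sigma_above_local_background``
thresholding this recovers dim (≈3σ) cells that a global absolute
threshold above the haze would erase.

Intensity metrics are always computed on the original, unprocessed image
so integrated intensity does not depend on the detection parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segment import EmbryoSegmentation

__all__ = [
    "GranuleParams",
    "Granule",
    "GranuleSet",
    "QCCriteria",
    "QCResult",
    "detect_granules",
    "assign_regions",
    "region_metrics",
    "apply_qc",
]

THRESHOLD_MODES = ("absolute", "k_sigma_above_local_background")

#: 8-connectivity for granule components
CONNECTIVITY = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class GranuleParams:
    """The detection operator chain parameters for one channel.

    ``background_radius`` = 0 disables background subtraction;
    ``smoothing_sigma`` = 0 disables smoothing.  In ``absolute`` mode the
    threshold is an intensity on the processed image; in k-sigma mode it
    is ``median + k × robust σ`` of the processed image (σ from the MAD).
    """

    smoothing_sigma: float = 1.6
    background_radius: float = 8.0
    threshold_mode: str = "k_sigma_above_local_background"
    threshold_value: float = 5.0
    min_area: float = 4.0
    max_area: float = 400.0

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.background_radius < 0:
            raise ValueError("background_radius must be >= 0")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_value <= 0:
            raise ValueError("threshold_value must be positive")
        if not (0 <= self.min_area <= self.max_area):
            raise ValueError("need 0 <= min_area <= max_area")


@dataclass
class Granule:
    """One detected fluorescent object."""

    centroid: tuple[float, float]  # (x, y)
    area: float
    integrated_intensity: float
    mean_intensity: float
    region: str = "whole_fish_only"


@dataclass
class GranuleSet:
    """Detected granules of one channel plus the params that found them."""

    granules: list[Granule]
    params: GranuleParams
    channel: str = ""

    def __len__(self) -> int:
        return len(self.granules)

    def __iter__(self):
        return iter(self.granules)


def _disc(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def _crop_to_mask(fluor: np.ndarray, mask: np.ndarray,
                  margin: int) -> tuple[slice, slice]:
    ys, xs = np.nonzero(mask)
    h, w = mask.shape
    y0 = max(0, ys.min() - margin)
    y1 = min(h, ys.max() + 1 + margin)
    x0 = max(0, xs.min() - margin)
    x1 = min(w, xs.max() + 1 + margin)
    return slice(y0, y1), slice(x0, x1)


def detect_granules(
    fluor: np.ndarray,
    params: GranuleParams,
    fish_mask: np.ndarray,
) -> GranuleSet:
    """Run the detection chain and keep in-fish components.

    Pipeline order: smooth → subtract background → threshold → 8-connected
    components → area filter → centroid-inside-fish filter.  Per-granule
    intensity metrics come from the original image.
    """
    fluor = np.asarray(fluor)
    fish_mask = np.asarray(fish_mask, dtype=bool)
    if fluor.shape != fish_mask.shape:
        raise ValueError("fluorescence image and fish mask dimensions differ")
    if not fish_mask.any():
        return GranuleSet([], params)

    # detection restricted to the fish neighbourhood: grown whenever a
    # thresholded component touches the window frame, so every kept
    # component is identical to what full-frame processing would yield
    margin = int(np.ceil(params.background_radius + 4 * params.smoothing_sigma)) + 16
    h, w = fluor.shape
    while True:
        win_y, win_x = _crop_to_mask(fluor, fish_mask, margin)
        img = fluor[win_y, win_x].astype(np.float64)
        mask_w = fish_mask[win_y, win_x]

        proc = img
        if params.smoothing_sigma > 0:
            proc = ndimage.gaussian_filter(
                proc.astype(np.float32), params.smoothing_sigma
            )
        if params.background_radius > 0:
            background = ndimage.grey_opening(
                proc, footprint=_disc(int(round(params.background_radius)))
            )
            proc = proc - background

        if params.threshold_mode == "absolute":
            thr = params.threshold_value
        else:
            med = float(np.median(proc))
            sigma = 1.4826 * float(np.median(np.abs(proc - med)))
            # floor at half a grey level: noise-free images keep a finite bar
            thr = med + params.threshold_value * max(sigma, 0.5)
        binary = proc > thr

        full = img.shape == fluor.shape
        frame = np.zeros_like(binary)
        if win_y.start > 0:
            frame[0, :] = True
        if win_y.stop < h:
            frame[-1, :] = True
        if win_x.start > 0:
            frame[:, 0] = True
        if win_x.stop < w:
            frame[:, -1] = True
        if full or not (binary & frame).any():
            break
        margin += max(h, w) // 4 + 32

    labels, n = ndimage.label(binary, structure=CONNECTIVITY)
    granules: list[Granule] = []
    if n:
        areas = np.bincount(labels.ravel())[1:]
        coms = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
        sums = ndimage.sum_labels(img, labels, index=np.arange(1, n + 1))
        for i in range(n):
            area = float(areas[i])
            if not (params.min_area <= area <= params.max_area):
                continue
            cy, cx = coms[i]
            iy = int(np.clip(round(cy), 0, mask_w.shape[0] - 1))
            ix = int(np.clip(round(cx), 0, mask_w.shape[1] - 1))
            if not mask_w[iy, ix]:
                continue  # spots outside the fish are disregarded
            granules.append(
                Granule(
                    centroid=(float(cx) + win_x.start, float(cy) + win_y.start),
                    area=area,
                    integrated_intensity=float(sums[i]),
                    mean_intensity=float(sums[i]) / area,
                )
            )
    return GranuleSet(granules, params)


def assign_regions(
    granules: GranuleSet, segmentation: EmbryoSegmentation
) -> GranuleSet:
    """Label each granule with the region containing its centroid.

    Boundary pixels take the label stored at that pixel in the region map
    (deterministic map lookup).
    """
    out = []
    for g in granules:
        region = segmentation.region_name_at(*g.centroid)
        out.append(replace_granule(g, region))
    return GranuleSet(out, granules.params, granules.channel)


def replace_granule(g: Granule, region: str) -> Granule:
    return Granule(g.centroid, g.area, g.integrated_intensity, g.mean_intensity, region)


def region_metrics(
    granules: GranuleSet,
    segmentation: EmbryoSegmentation | None = None,
) -> dict[str, dict[str, float | None]]:
    """Per-region counts/intensities/areas plus whole-fish totals.

    Whole-fish totals ("fish") are sums over the three regions (granules
    labelled ``whole_fish_only`` contribute to the totals only).  The mean
    granule area of an empty region is reported as missing (None), not 0.
    """
    regions = ("head", "trunk", "tail")
    out: dict[str, dict[str, float | None]] = {}
    for name in regions + ("fish",):
        if name == "fish":
            sel = list(granules)
        else:
            sel = [g for g in granules if g.region == name]
        count = len(sel)
        total_area = float(sum(g.area for g in sel))
        out[name] = {
            "count": float(count),
            "integrated_intensity": float(sum(g.integrated_intensity for g in sel)),
            "mean_granule_area": (total_area / count) if count else None,
            "total_granule_area": total_area,
        }
    return out


def write_granule_csv(granules: GranuleSet, path) -> None:
    """Debug dump: one CSV row per detected granule."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["channel", "x", "y", "area", "integrated_intensity",
             "mean_intensity", "region"]
        )
        for g in granules:
            writer.writerow(
                [granules.channel, f"{g.centroid[0]:.2f}", f"{g.centroid[1]:.2f}",
                 f"{g.area:g}", f"{g.integrated_intensity:g}",
                 f"{g.mean_intensity:g}", g.region]
            )


@dataclass(frozen=True)
class QCCriteria:
    """The on-side (lateral) orientation rule.

    An analysable well shows exactly one eye and one tail, with the fish
    and tail-region areas above minimums that reject partially imaged
    fish.  Areas are in px² on the stitched canvas.
    """

    required_eye_count: int = 1
    required_tail_count: int = 1
    min_fish_area: float = 40_000.0
    min_tail_area: float = 2_000.0

    def __post_init__(self) -> None:
        if self.min_fish_area < 0 or self.min_tail_area < 0:
            raise ValueError("QC areas must be >= 0")

    @classmethod
    def for_canvas(cls, shape: tuple[int, int], **overrides) -> "QCCriteria":
        f = (shape[0] / 512.0) ** 2
        base = {"min_fish_area": cls.min_fish_area * f,
                "min_tail_area": cls.min_tail_area * f}
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class QCResult:
    included: bool
    reason: str  # ok | empty_well | eye_count | tail_count | fish_area | tail_area

    def __post_init__(self) -> None:
        if self.included and self.reason != "ok":
            raise ValueError("included wells must have reason 'ok'")


def apply_qc(
    segmentation: EmbryoSegmentation | None, criteria: QCCriteria
) -> QCResult:
    """First failing check, in fixed order, decides the verdict."""
    if segmentation is None or not segmentation.fish_mask.any():
        return QCResult(False, "empty_well")
    if segmentation.eye_count != criteria.required_eye_count:
        return QCResult(False, "eye_count")
    if segmentation.tail_count != criteria.required_tail_count:
        return QCResult(False, "tail_count")
    if segmentation.fish_area < criteria.min_fish_area:
        return QCResult(False, "fish_area")
    if segmentation.region_area("tail") < criteria.min_tail_area:
        return QCResult(False, "tail_area")
    return QCResult(True, "ok")
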