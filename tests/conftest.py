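"""Shared fixtures: half-scale plate geometry and independent oracles.

Most unit tests run on a half-scale plate (256x348 tiles) so one well
renders in a fraction of a second; the acceptance tests use the default
full-scale geometry.  Oracles (flood fill, brute-force maxima) are plain
Python so they stay independent of the vectorised implementations they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from embryoscreen.plate_io import ChannelRole, PlateSpec
from embryoscreen.synthplate import (
    NoiseParams,
    SpotLaw,
    render_well,
    sample_layout,
    sample_spots,
)

#: spot laws scaled for the half-size canvas used by unit tests
SMALL_LAWS = (
    SpotLaw("GFP", "tail", "dim", "poisson", 12.0),
    SpotLaw("GFP", "trunk", "bright", "poisson", 3.0),
)


@pytest.fixture(scope="session")
def small_spec() -> PlateSpec:
    return PlateSpec(tile_shape=(256, 348))


@pytest.fixture(scope="session")
def noise() -> NoiseParams:
    return NoiseParams()


@pytest.fixture(scope="session")
def noise_free() -> NoiseParams:
    return NoiseParams.noise_free()


def make_well(spec, presentation="lateral_left", seed=0, noise=None, laws=SMALL_LAWS):
    """Render one well with its truth; deterministic in the seed."""
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    layout = sample_layout(presentation, spec, rng)
    spots = sample_spots(layout, laws, spec, noise, rng) if laws else []
    return render_well(layout, spots, spec, noise, rng)


@pytest.fixture(scope="session")
def lateral_well(small_spec, noise):
    return make_well(small_spec, "lateral_left", seed=3, noise=noise)


@pytest.fixture(scope="session")
def dorsal_well(small_spec, noise):
    return make_well(small_spec, "dorsal", seed=4, noise=noise)


@pytest.fixture(scope="session")
def absent_well(small_spec, noise):
    return make_well(small_spec, "absent", seed=5, noise=noise)


@pytest.fixture(scope="session")
def partial_well(small_spec, noise):
    return make_well(small_spec, "partial", seed=6, noise=noise)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def flood_fill_components(image, threshold, mask=None):
    """Exhaustive 8-connected component oracle on a thresholded image.

    Returns a list of dicts with area, integrated intensity (sum of the
    *original* image over the component) and centroid (x, y), for every
    component of ``image > threshold``.  Pure Python BFS; intended for
    small images only.
    """
    image = np.asarray(image)
    h, w = image.shape
    binary = image > threshold
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not binary[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pix = []
            while stack:
                y, x = stack.pop()
                pix.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            area = len(pix)
            total = float(sum(float(image[y, x]) for y, x in pix))
            cy = sum(y for y, _ in pix) / area
            cx = sum(x for _, x in pix) / area
            comps.append(
                {"area": area, "integrated_intensity": total, "centroid": (cx, cy)}
            )
    if mask is not None:
        kept = []
        for c in comps:
            cx, cy = c["centroid"]
            iy = int(np.clip(round(cy), 0, h - 1))
            ix = int(np.clip(round(cx), 0, w - 1))
            if mask[iy, ix]:
                kept.append(c)
        comps = kept
    return comps


@pytest.fixture(scope="session")
def flood_fill_oracle():
    return flood_fill_components
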