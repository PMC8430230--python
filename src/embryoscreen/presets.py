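"""Assay presets: channel roles, detection parameters and headline metric.

Each preset bundles the granule-detection parameters, the target region
and the single headline read-out of one screening assay.  The numbers are
calibrated on the synthetic plates bundled with this package, not taken
from any vendor configuration:

* ``hspc`` — count dim GFP-lo stem/progenitor cells in the tail (the
  caudal haematopoietic tissue), ignoring bright circulating thrombocytes
  elsewhere.
* ``dual`` — the same counting applied independently to a green and a red
  channel of one embryo (stem cells + myeloid cells).
* ``apoptosis`` — count small dying-cell foci over the whole fish.
* ``haircell`` — integrated fluorescence intensity (and granule size) of
  neuromasts over the whole fish.
* ``angiogenesis`` — total fluorescent area of the vasculature as a
  surrogate of vessel formation; no upper area bound so connected vessel
  trees survive the area filter.
* ``eyesize`` — brightfield-only morphometry; headline is the eye area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .plate_io import ChannelRole
from .quantify import GranuleParams
from .synthplate import HSPC_LAWS, SpotLaw

__all__ = ["AssayPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class AssayPreset:
    name: str
    channels: tuple[ChannelRole, ...]
    granule_params: dict[str, GranuleParams]
    #: (channel, region, metric) or ("", "", morphometric field)
    headline: tuple[str, str, str]
    #: spot laws the synthetic generator uses to emulate this assay
    generator_laws: tuple[SpotLaw, ...] = ()

    @property
    def headline_column(self) -> str:
        ch, region, metric = self.headline
        if ch:
            return f"{ch}_{region}_{metric}"
        return metric


_BF = ChannelRole("BF", "brightfield")

_STANDARD = GranuleParams(
    smoothing_sigma=1.6,
    background_radius=8.0,
    threshold_mode="k_sigma_above_local_background",
    threshold_value=5.0,
    min_area=4.0,
    max_area=400.0,
)

PRESETS: dict[str, AssayPreset] = {}


def _register(p: AssayPreset) -> AssayPreset:
    PRESETS[p.name] = p
    return p


HSPC = _register(
    AssayPreset(
        name="hspc",
        channels=(_BF, ChannelRole("GFP")),
        granule_params={"GFP": _STANDARD},
        headline=("GFP", "tail", "count"),
        generator_laws=HSPC_LAWS,
    )
)

DUAL = _register(
    AssayPreset(
        name="dual",
        channels=(_BF, ChannelRole("GFP"), ChannelRole("mCherry")),
        granule_params={"GFP": _STANDARD, "mCherry": _STANDARD},
        headline=("GFP", "tail", "count"),
        generator_laws=HSPC_LAWS
        + (
            SpotLaw("mCherry", "tail", "dim", "poisson", 20.0),
            SpotLaw("mCherry", "trunk", "bright", "poisson", 4.0),
        ),
    )
)

APOPTOSIS = _register(
    AssayPreset(
        name="apoptosis",
        channels=(_BF, ChannelRole("AO")),
        granule_params={
            "AO": GranuleParams(
                smoothing_sigma=1.0,
                background_radius=6.0,
                threshold_value=5.0,
                min_area=3.0,
                max_area=200.0,
            )
        },
        headline=("AO", "fish", "count"),
        generator_laws=(
            SpotLaw("AO", "head", "dim", "poisson", 8.0),
            SpotLaw("AO", "trunk", "dim", "poisson", 12.0),
            SpotLaw("AO", "tail", "dim", "poisson", 10.0),
        ),
    )
)

HAIRCELL = _register(
    AssayPreset(
        name="haircell",
        channels=(_BF, ChannelRole("YOPRO")),
        granule_params={
            "YOPRO": GranuleParams(
                smoothing_sigma=2.0,
                background_radius=12.0,
                threshold_value=5.0,
                min_area=8.0,
                max_area=2_000.0,
            )
        },
        headline=("YOPRO", "fish", "integrated_intensity"),
    )
)

ANGIOGENESIS = _register(
    AssayPreset(
        name="angiogenesis",
        channels=(_BF, ChannelRole("mCherry")),
        granule_params={
            "mCherry": GranuleParams(
                smoothing_sigma=1.5,
                background_radius=12.0,
                threshold_value=5.0,
                min_area=8.0,
                max_area=1e9,
            )
        },
        headline=("mCherry", "fish", "total_granule_area"),
    )
)

EYESIZE = _register(
    AssayPreset(
        name="eyesize",
        channels=(_BF,),
        granule_params={},
        headline=("", "", "eye_area"),
    )
)


def get_preset(name: str) -> AssayPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown assay preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
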