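"""Chip geometry, flow configuration, and the closed-form geometry/flow relations.

The physical system is a PMMA microfluidic cell-sorter chip: a sample stream
enters a 50 μm × 25 μm sorting channel, is narrowed by sheath buffer flows
(hydrodynamic focusing), passes an imaging/sorting segment flanked by agarose
gel electrodes, and exits through two or three outlet branches.

Units and coordinates (used by every module in this package):

* lengths in μm, times in s, speeds in mm/s, voltages in V;
* volumes carried internally in μm³ with explicit converters to fL/pL/nL/μL;
* x is the lateral axis (the sorting axis), origin on the channel centerline;
* y is the flow axis, increasing downstream (top → bottom in the camera view).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "OutletTopology",
    "ChipGeometry",
    "FlowConfig",
    "InvalidGeometryError",
    "InvalidConfigError",
    "sensing_volume",
    "focused_stream_width",
    "speed_amplification",
    "um3_to_fl",
    "um3_to_pl",
    "pl_to_nl",
    "nl_to_ul",
    "ul_to_nl",
]


class InvalidGeometryError(ValueError):
    """A chip dimension is non-positive or otherwise unphysical."""


class InvalidConfigError(ValueError):
    """A flow/optics/run configuration value violates its invariant."""


class OutletTopology(str, enum.Enum):
    two_way = "two_way"
    three_way = "three_way"

    @property
    def n_outlets(self) -> int:
        return 2 if self is OutletTopology.two_way else 3


# -- volume converters (1 μm³ = 1 fL) ---------------------------------------

def um3_to_fl(v: float) -> float:
    return float(v)


def um3_to_pl(v: float) -> float:
    return float(v) * 1e-3


def pl_to_nl(v: float) -> float:
    return float(v) * 1e-3


def nl_to_ul(v: float) -> float:
    return float(v) * 1e-3


def ul_to_nl(v: float) -> float:
    return float(v) * 1e3


@dataclass(frozen=True)
class ChipGeometry:
    """Physical dimensions of the sorting area and gel-electrode junction.

    Defaults reproduce the reference chip: a sorting channel 50 μm wide and
    25 μm high whose electrode-facing (imaged) segment is 100 μm long, with
    15 μm × 45 μm narrow junction channels connecting the flow channel to the
    agarose gel electrodes.  ``electrode_gap`` is the span the DC field
    crosses; it defaults to the channel width since the field is applied
    laterally across the flow.
    """

    sorting_width: float = 50.0
    sorting_height: float = 25.0
    sorting_length: float = 100.0
    electrode_gap: float | None = None
    junction_channel_width: float = 15.0
    junction_channel_length: float = 45.0
    outlet_topology: OutletTopology = OutletTopology.two_way

    def __post_init__(self) -> None:
        if self.electrode_gap is None:
            object.__setattr__(self, "electrode_gap", self.sorting_width)
        if isinstance(self.outlet_topology, str):
            object.__setattr__(
                self, "outlet_topology", OutletTopology(self.outlet_topology)
            )
        for name in (
            "sorting_width",
            "sorting_height",
            "sorting_length",
            "electrode_gap",
            "junction_channel_width",
            "junction_channel_length",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {value!r}")

    @property
    def n_outlets(self) -> int:
        return self.outlet_topology.n_outlets


@dataclass(frozen=True)
class FlowConfig:
    """Flow conditions in the sorting area.

    ``sorting_area_speed`` defaults to 20 mm/s, the speed at which a particle
    traverses exactly one 100 μm sensing length per frame at 200 frames/s.
    ``sheath_ratio`` is the sheath:sample stream-width ratio (1:10 focusing by
    default), which also sets the speed amplification of the sample stream.
    """

    sorting_area_speed: float = 20.0  # mm/s
    sheath_ratio: float = 10.0
    frame_rate: float = 200.0  # frames/s
    sample_inlet_width: float = 50.0  # μm

    def __post_init__(self) -> None:
        if self.sheath_ratio < 1:
            raise InvalidConfigError(
                f"sheath_ratio must be >= 1, got {self.sheath_ratio!r}"
            )
        if not self.frame_rate > 0:
            raise InvalidConfigError(
                f"frame_rate must be > 0, got {self.frame_rate!r}"
            )
        if self.sorting_area_speed < 0:
            raise InvalidConfigError(
                f"sorting_area_speed must be >= 0, got {self.sorting_area_speed!r}"
            )
        if not self.sample_inlet_width > 0:
            raise InvalidConfigError(
                f"sample_inlet_width must be > 0, got {self.sample_inlet_width!r}"
            )

    @property
    def focused_width(self) -> float:
        """Width (μm) of the hydrodynamically focused sample stream."""
        return focused_stream_width(self.sample_inlet_width, self.sheath_ratio)

    @property
    def advance_per_frame(self) -> float:
        """Distance (μm) a particle travels between consecutive frames."""
        return self.sorting_area_speed * 1e3 / self.frame_rate


def sensing_volume(geometry: ChipGeometry) -> float:
    """Volume of the imaged sorting segment in pL.

    This is the unit volume of the occupancy model: one "event" images the
    width × height × length box between the gel electrode tips.  The default
    chip gives 50 × 25 × 100 μm³ = 125 pL.
    """
    return um3_to_pl(
        geometry.sorting_width * geometry.sorting_height * geometry.sorting_length
    )


def focused_stream_width(sample_width: float, sheath_ratio: float) -> float:
    """Width (μm) of the sample stream after hydrodynamic focusing.

    A 1:``sheath_ratio`` width ratio narrows the stream from ``sample_width``
    to ``sample_width / sheath_ratio`` (50 μm → 5 μm for the default chip).
    """
    if sheath_ratio < 1:
        raise InvalidConfigError(f"sheath_ratio must be >= 1, got {sheath_ratio!r}")
    if not sample_width > 0:
        raise InvalidConfigError(f"sample_width must be > 0, got {sample_width!r}")
    return sample_width / sheath_ratio


def speed_amplification(flow: FlowConfig) -> float:
    """Factor by which the sorting-area speed exceeds the sample-inlet speed.

    Flux conservation through the narrowed stream makes this equal to the
    sheath ratio: squeezing the stream to 1/10 width speeds it up 10×.
    """
    return float(flow.sheath_ratio)
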