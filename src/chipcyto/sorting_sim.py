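"""Electrophoretic deflection between gel electrodes and outlet routing.

While a particle transits the sorting segment, a DC voltage across the agarose
gel electrodes drives a lateral electrophoretic drift

    Δx = μ · (V / gap) · (L_eff / v)

with μ the particle's electrophoretic mobility, V/gap the field, v the flow
speed, and L_eff the portion of the sorting segment over which the field acts
(the full segment minus whatever transit the decision latency consumed, capped
by the pulse duration).  Neutral particles and an off drive give Δx = 0;
reversing polarity negates Δx.

Routing is purely geometric: a two-way chip sends the particle to the opposite
outlet when its final lateral position reaches the branch line, a three-way
chip keeps it in the center outlet unless |x| reaches the branch half-width,
in which case the sign of x picks the side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip_model import ChipGeometry, FlowConfig, InvalidConfigError, OutletTopology
from .synthetic_imaging import CHARGE_CLASSES, DEFAULT_MOBILITY

__all__ = [
    "ElectrodeDrive",
    "ParticleState",
    "SortOutcome",
    "CHARGE_SIGN",
    "lateral_deflection",
    "required_shift",
    "route_two_way",
    "route_three_way",
    "efficiency_sweep",
]

CHARGE_SIGN = {"negative": -1.0, "positive": 1.0, "neutral": 0.0}
FIELD_SIGN = {"off": 0.0, "forward": 1.0, "reverse": -1.0}

#: lateral margin (μm) added to the half stream width to reach the branch line
DEFAULT_BRANCH_MARGIN = 0.5


@dataclass(frozen=True)
class ElectrodeDrive:
    """DC drive command for the gel electrodes.

    ``switch_latency`` (frames) is the delay between the recognition decision
    and the field actually switching; the default of 1 frame models a decision
    available only after the triggering frame has been processed.  For the
    continuous-DC characterization sweeps the latency is zero and
    ``pulse_frames=None`` keeps the field on for the whole transit.
    """

    voltage: float
    polarity: str = "off"
    switch_latency: float = 1.0  # frames
    pulse_frames: int | None = None

    def __post_init__(self) -> None:
        if self.voltage < 0:
            raise InvalidConfigError("voltage must be >= 0")
        if self.switch_latency < 0:
            raise InvalidConfigError("switch_latency must be >= 0")
        if self.polarity not in FIELD_SIGN:
            raise InvalidConfigError("polarity must be off/forward/reverse")


@dataclass(frozen=True)
class ParticleState:
    """Kinematic and electrokinetic state of one particle entering the segment."""

    x: float  # lateral position, μm from centerline
    y: float  # along-flow position, μm
    speed: float  # mm/s
    mobility: float = DEFAULT_MOBILITY  # magnitude, μm²/(V·s)
    charge_class: str = "neutral"

    def __post_init__(self) -> None:
        if self.charge_class not in CHARGE_CLASSES:
            raise InvalidConfigError(
                f"charge_class must be one of {CHARGE_CLASSES}"
            )


@dataclass(frozen=True)
class SortOutcome:
    particle_id: int
    intended_outlet: str
    realized_outlet: str
    deflection_um: float


def lateral_deflection(
    state: ParticleState,
    drive: ElectrodeDrive,
    geometry: ChipGeometry,
    frame_rate: float = 200.0,
) -> float:
    """Signed lateral displacement (μm) accumulated across the sorting segment.

    Sign convention: a positive value moves toward +x.  The sign is the
    product of the charge sign and the field sign, so a negative particle in a
    forward field moves toward −x and polarity reversal mirrors the motion.
    """
    if not state.speed > 0:
        raise InvalidConfigError("particle speed must be > 0")
    sign = CHARGE_SIGN[state.charge_class] * FIELD_SIGN[drive.polarity]
    if sign == 0.0 or drive.voltage == 0.0:
        return 0.0
    speed_um_s = state.speed * 1e3
    latency_distance = drive.switch_latency / frame_rate * speed_um_s
    effective_length = max(geometry.sorting_length - latency_distance, 0.0)
    if drive.pulse_frames is not None:
        pulse_distance = drive.pulse_frames / frame_rate * speed_um_s
        effective_length = min(effective_length, pulse_distance)
    field = drive.voltage / geometry.electrode_gap  # V/μm
    transit_time = effective_length / speed_um_s
    return sign * state.mobility * field * transit_time


def required_shift(flow: FlowConfig, margin: float = DEFAULT_BRANCH_MARGIN) -> float:
    """Lateral distance (μm) from the centerline to the branch line.

    Geometry-derived: half the focused stream width plus a small margin, so a
    particle anywhere in the stream must clear the stream edge to cross.
    """
    return 0.5 * flow.focused_width + margin


def route_two_way(
    state: ParticleState,
    drive: ElectrodeDrive,
    geometry: ChipGeometry,
    frame_rate: float = 200.0,
    branch_x: float = 3.0,
) -> tuple[str, float]:
    """Outlet of a two-way chip: ``'same_side'`` or ``'cross'``.

    The undisturbed stream exits through the same-side outlet; the particle
    crosses when its final lateral position reaches the branch line at
    ``branch_x`` (default 3 μm = half the 5 μm focused stream + 0.5 μm margin).
    Returns ``(outlet, deflection_um)``.
    """
    if geometry.outlet_topology is not OutletTopology.two_way:
        raise InvalidConfigError("route_two_way requires a two_way chip")
    dx = lateral_deflection(state, drive, geometry, frame_rate=frame_rate)
    final_x = state.x + dx
    outlet = "cross" if final_x >= branch_x else "same_side"
    return outlet, dx


def route_three_way(
    state: ParticleState,
    drive: ElectrodeDrive,
    geometry: ChipGeometry,
    frame_rate: float = 200.0,
    branch_half_width: float = 3.0,
) -> tuple[str, float]:
    """Outlet of a three-way chip: ``'center'``, ``'left'`` or ``'right'``.

    The undisturbed (or neutral) particle stays in the center stream; charged
    particles exit left or right by the sign of their final lateral position
    once it reaches the branch half-width.  Returns ``(outlet, deflection_um)``.
    """
    if geometry.outlet_topology is not OutletTopology.three_way:
        raise InvalidConfigError("route_three_way requires a three_way chip")
    dx = lateral_deflection(state, drive, geometry, frame_rate=frame_rate)
    final_x = state.x + dx
    if abs(final_x) < branch_half_width:
        outlet = "center"
    else:
        outlet = "right" if final_x > 0 else "left"
    return outlet, dx


def efficiency_sweep(
    sweep: str,
    values,
    *,
    geometry: ChipGeometry | None = None,
    flow: FlowConfig | None = None,
    base_voltage: float = 45.0,
    base_speed: float = 200.0,
    mobility_mean: float = DEFAULT_MOBILITY,
    mobility_cv: float = 0.05,
    n: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-way sorting efficiency as a function of voltage or flow speed.

    Every particle is commanded to cross (a negative particle with the field
    oriented to push it toward the branch).  Stochasticity comes from the
    lateral position within the focused stream and a mobility spread of
    ``mobility_cv``; the same ``n`` particle draws are reused for every sweep
    setting (common random numbers), so the monotone voltage/speed trends are
    not blurred by sampling noise.  The drive is continuous DC (no switching
    latency), matching how the voltage/flow-rate dependence is characterized.

    Returns a DataFrame with columns ``(sweep, 'efficiency')``.
    """
    if sweep not in ("voltage", "speed"):
        raise InvalidConfigError("sweep must be 'voltage' or 'speed'")
    if n < 100:
        raise InvalidConfigError("n must be >= 100")
    geometry = geometry or ChipGeometry()
    flow = flow or FlowConfig()
    rng = np.random.default_rng(seed)
    fw = flow.focused_width
    x0 = rng.uniform(-fw / 2, fw / 2, size=n)
    mob = rng.normal(mobility_mean, mobility_cv * mobility_mean, size=n)
    mob = np.clip(mob, 0.0, None)
    branch_x = required_shift(flow)

    rows = []
    for value in values:
        voltage = value if sweep == "voltage" else base_voltage
        speed = value if sweep == "speed" else base_speed
        drive = ElectrodeDrive(
            voltage=voltage, polarity="reverse", switch_latency=0.0
        )  # reverse field pushes a negative particle toward +x
        crossed = 0
        for i in range(n):
            state = ParticleState(
                x=float(x0[i]),
                y=0.0,
                speed=speed,
                mobility=float(mob[i]),
                charge_class="negative",
            )
            outlet, _ = route_two_way(
                state, drive, geometry, frame_rate=flow.frame_rate, branch_x=branch_x
            )
            crossed += outlet == "cross"
        rows.append({sweep: value, "efficiency": crossed / n})
    return pd.DataFrame(rows)
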