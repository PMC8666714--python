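"""Impeller-speed scale-up, gassing rule and process-planning arithmetic.

Scale-up between geometrically similar stirred tanks holds the power
input per volume constant, i.e. N³D⁵/V is invariant, giving
N_o = (N_i³ · (V_o/V_i) · D_i⁵/D_o⁵)^(1/3). Within one system the law
collapses to cube-root volume scaling, and each supported system also
carries a fitted volume-to-speed law N = c·V^(1/3) (V in liters, N in
rpm). The same cube-root law scales the system's operating speed window.
"""

from __future__ import annotations

import numpy as np

from .parameters import FeedSchedule, InvalidParameterError, ReactorGeometry
from . import presets

__all__ = [
    "scale_speed",
    "speed_dasbox",
    "speed_bioblock",
    "speed_for_geometry",
    "speed_bounds",
    "gassing_rate",
    "inoculum_cells",
    "feed_volume",
    "CapabilityError",
]


class CapabilityError(ValueError):
    """The geometry lacks the data needed for the requested calculation."""


def scale_speed(N_i: float, V_i: float, D_i: float, V_o: float, D_o: float) -> float:
    """Impeller speed [rpm] in the target vessel at constant power per
    volume. Valid only between impellers of the same geometry."""
    for name, v in (("N_i", N_i), ("V_i", V_i), ("D_i", D_i), ("V_o", V_o), ("D_o", D_o)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0")
    return (N_i**3 * (V_o / V_i) * D_i**5 / D_o**5) ** (1.0 / 3.0)


def _cube_root_speed(V: float, constant: float) -> float:
    if V <= 0:
        raise InvalidParameterError("volume must be > 0")
    return constant * V ** (1.0 / 3.0)


def speed_dasbox(V: float) -> float:
    """DASbox stirring speed [rpm] at working volume V [L]
    (N = 150.5·V^(1/3); 0.15 L → 79.97 rpm, the 80 rpm setpoint)."""
    return _cube_root_speed(V, 150.5)


def speed_bioblock(V: float) -> float:
    """DASGIP Bioblock stirring speed [rpm] at working volume V [L]
    (N = 76.5·V^(1/3))."""
    return _cube_root_speed(V, 76.5)


def speed_for_geometry(V: float, g: ReactorGeometry) -> float:
    """Fitted volume-to-speed law of a described system."""
    if g.speed_constant is None:
        raise CapabilityError(f"geometry '{g.name}' has no fitted speed law")
    return _cube_root_speed(V, g.speed_constant)


def speed_bounds(V: float, g: ReactorGeometry) -> tuple[float, float]:
    """Operating speed window (min, max) [rpm] at volume V, scaled from
    the system's reference-volume bounds by the cube-root volume law."""
    if V <= 0:
        raise InvalidParameterError("volume must be > 0")
    if g.reference_volume is None or g.min_speed_at_ref is None or g.max_speed_at_ref is None:
        raise CapabilityError(f"geometry '{g.name}' has no reference speed bounds")
    s = (V / g.reference_volume) ** (1.0 / 3.0)
    return g.min_speed_at_ref * s, g.max_speed_at_ref * s


def gassing_rate(V: float) -> float:
    """Headspace gassing rate [sL/h]: six reactor volumes per hour."""
    if V <= 0:
        raise InvalidParameterError("volume must be > 0")
    return 6.0 * V


def inoculum_cells(V: float, density_per_mL: float) -> float:
    """Cells required to inoculate volume V [L] at the target density
    [cells/mL] (0.15 L at 0.5 × 10⁶/mL → 75 × 10⁶ cells)."""
    if V <= 0 or density_per_mL < 0:
        raise InvalidParameterError("V must be > 0 and density >= 0")
    return V * 1000.0 * density_per_mL


def feed_volume(
    schedule: FeedSchedule, V: float, from_day: float, to_day: float
) -> float:
    """Feed medium volume [L] consumed between two process days:
    working volume × Σ(rate × overlap days), partial days pro-rated."""
    if to_day < from_day:
        raise InvalidParameterError("to_day must be >= from_day")
    if V <= 0:
        raise InvalidParameterError("V must be > 0")
    total = 0.0
    for seg in schedule.segments:
        overlap = min(seg.end_day, to_day) - max(seg.start_day, from_day)
        if overlap > 0:
            total += seg.rate * overlap
    return V * total


def plan(
    V: float,
    density_per_mL: float = 0.5e6,
    schedule: FeedSchedule | None = None,
):
    """Process plan for one run: inoculum, per-day feed volumes by
    medium, and the gassing rate. Returns a dict suitable for tabular
    display."""
    if schedule is None:
        schedule = presets.table3_schedule()
    per_day = []
    for seg in schedule.segments:
        per_day.append(
            {
                "start_day": seg.start_day,
                "end_day": seg.end_day,
                "rate_vvd": seg.rate,
                "medium": seg.medium.label if seg.medium else "none",
                "feed_volume_L": feed_volume(schedule, V, seg.start_day, seg.end_day),
            }
        )
    return {
        "inoculum_cells": inoculum_cells(V, density_per_mL),
        "gassing_rate_sL_h": gassing_rate(V),
        "per_day": per_day,
        "total_feed_L": feed_volume(
            schedule, V, schedule.segments[0].start_day, schedule.end_day
        ),
    }
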