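"""Domain types for the perfusion stirred-tank digital twin.

All quantities follow one units contract: viable cell density X in
cells/L, metabolite concentrations in mM (= mmol/L), cell-specific
rates q in mmol·cell⁻¹·day⁻¹ (so q·X lands in mM/day without any
conversion factor), osmolality in mOsm/kg, time in days, volumes in
liters, aggregate diameter in μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence


class InvalidParameterError(ValueError):
    """A model parameter or state variable violates its domain."""


@dataclass(frozen=True)
class KineticParameters:
    """Monod constants, maximal specific rates and aggregate-model
    coefficients, plus the auxiliary constants closing the osmolality
    and aggregate sub-models.

    The half-saturation constants ``K_Glc``/``K_Gln`` act as substrate
    limitation constants (c/(K+c)); ``K_Lac``/``K_Osm``/``K_Agg`` act as
    inhibition constants (K/(K+x)) on lactate, on osmolality excess above
    ``osm_ref``, and on mean aggregate *radius* respectively.

    Parameters
    ----------
    K_Glc, K_Lac, K_Gln : float
        Monod constants for glucose, lactate and glutamine [mM].
    K_Agg : float
        Critical aggregate radius [μm]; growth is halved when the mean
        aggregate radius reaches this value.
    K_Osm : float
        Osmotic inhibition constant [mOsm/kg], applied to the excess of
        culture osmolality over ``osm_ref``.
    mu_max : float
        Maximal specific growth rate [1/day].
    q_Glc_max, q_Lac_max, q_Gln_max : float
        Maximal cell-specific glucose consumption, lactate production
        and glutamine consumption rates [mmol·cell⁻¹·day⁻¹].
    agg_f : float
        Cell line-dependent aggregate formation fraction (dimensionless,
        fraction of cells recruited into aggregates at onset).
    agg_g : float
        Aggregate nucleation coefficient (dimensionless, nuclei formed
        per inoculated cell).
    k_osm : float
        Osmolality yield per mM lactate produced [mOsm·kg⁻¹·mM⁻¹];
        lumps the lactate ion itself with the pH-control base addition
        it triggers.
    osm_ref : float
        Reference osmolality [mOsm/kg] below which no osmotic
        inhibition applies.
    d_agg_init : float
        Mean aggregate diameter at aggregation onset [μm].
    t_agg : float
        Aggregation onset time [day].
    d_cell : float
        Single-cell diameter [μm].
    packing : float
        Volume packing fraction of cells within an aggregate.
    """

    K_Glc: float = 1.5
    K_Lac: float = 50.0
    K_Gln: float = 0.01
    K_Agg: float = 350.0 / 2.0
    K_Osm: float = 500.0
    mu_max: float = 1.35
    q_Glc_max: float = 1.474e-8
    q_Lac_max: float = 2.37e-8
    q_Gln_max: float = 1.856e-9
    agg_f: float = 0.95
    agg_g: float = 0.25
    # Auxiliary constants (committed output of the default calibration
    # grid; see calibrate_defaults and docs/calibration_log.md).
    k_osm: float = 2.0
    osm_ref: float = 325.0
    d_agg_init: float = 80.0
    t_agg: float = 1.0
    d_cell: float = 15.0
    packing: float = 0.74

    def __post_init__(self) -> None:
        for name in ("K_Glc", "K_Lac", "K_Gln", "K_Agg", "K_Osm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.mu_max <= 0:
            raise InvalidParameterError("mu_max must be > 0")
        for name in ("q_Glc_max", "q_Lac_max", "q_Gln_max", "k_osm"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("agg_f", "agg_g", "packing"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1]")
        if self.d_cell <= 0 or self.d_agg_init < self.d_cell:
            raise InvalidParameterError("require d_agg_init >= d_cell > 0")
        if self.t_agg < 0:
            raise InvalidParameterError("t_agg must be >= 0")

    def replace(self, **changes) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def nucleation_diameter(self, X_onset: float, X0: float) -> float:
        """Alternative aggregation-onset diameter from the formation
        fraction ``agg_f`` and nucleation coefficient ``agg_g``.

        Interprets aggregation as ``agg_f`` of the cells present at
        onset distributing over ``agg_g`` nuclei per inoculated cell,
        each a close-packed sphere of ``d_cell``-sized cells:
        d = d_cell · (agg_f·X_onset / (packing·agg_g·X0))^(1/3).
        """
        if X_onset <= 0 or X0 <= 0:
            raise InvalidParameterError("cell densities must be > 0")
        return self.d_cell * (
            self.agg_f * X_onset / (self.packing * self.agg_g * X0)
        ) ** (1.0 / 3.0)


@dataclass(frozen=True)
class MediumComposition:
    """Metabolite content and osmolality of a culture or feed medium."""

    glc: float  # mM
    gln: float  # mM
    lac: float  # mM
    osm: float  # mOsm/kg
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.glc, self.gln, self.lac) < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        if self.osm <= 0:
            raise InvalidParameterError("osmolality must be > 0")


@dataclass(frozen=True)
class FeedSegment:
    """One contiguous span of constant perfusion rate and feed medium."""

    start_day: float
    end_day: float
    rate: float  # working volumes per day [1/day]
    medium: MediumComposition | None = None

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise InvalidParameterError("segment must have end_day > start_day")
        if self.rate < 0:
            raise InvalidParameterError("feed rate must be >= 0")
        if self.rate > 0 and self.medium is None:
            raise InvalidParameterError("a fed segment needs a feed medium")


@dataclass(frozen=True)
class FeedSchedule:
    """Piecewise-constant perfusion schedule.

    Segments must be contiguous, non-overlapping and start at day 0.
    The perfusion rate is in working volumes per day (vvd), i.e. the
    dilution rate F/V.
    """

    segments: tuple[FeedSegment, ...]

    def __init__(self, segments: Sequence[FeedSegment]):
        segs = tuple(segments)
        if not segs:
            raise InvalidParameterError("schedule needs at least one segment")
        if segs[0].start_day != 0:
            raise InvalidParameterError("schedule must start at day 0")
        for a, b in zip(segs, segs[1:]):
            if b.start_day != a.end_day:
                raise InvalidParameterError(
                    "segments must be contiguous and non-overlapping"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def end_day(self) -> float:
        return self.segments[-1].end_day

    def segment_at(self, t: float) -> FeedSegment:
        """Segment in effect at time ``t`` (right-open intervals; the
        final segment is closed at its end)."""
        for seg in self.segments:
            if seg.start_day <= t < seg.end_day:
                return seg
        if t == self.end_day:
            return self.segments[-1]
        raise InvalidParameterError(f"t={t} outside schedule span")

    def rate_at(self, t: float) -> float:
        return self.segment_at(t).rate

    def boundaries(self) -> list[float]:
        return [self.segments[0].start_day] + [s.end_day for s in self.segments]


@dataclass(frozen=True)
class ProcessState:
    """Instantaneous state of the perfused culture."""

    t: float  # day
    X: float  # viable cells per liter
    glc: float  # mM
    lac: float  # mM
    gln: float  # mM
    osm: float  # mOsm/kg
    d_agg: float  # μm mean aggregate diameter
    V: float  # working volume, L

    def __post_init__(self) -> None:
        if self.X < 0:
            raise InvalidParameterError("X must be >= 0")
        if min(self.glc, self.lac, self.gln) < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        if self.V <= 0:
            raise InvalidParameterError("V must be > 0")
        if self.d_agg < 0:
            raise InvalidParameterError("d_agg must be >= 0")


@dataclass(frozen=True)
class ReactorGeometry:
    """Stirred-tank vessel description for impeller-speed scale-up.

    ``speed_constant`` is the fitted coefficient of the system's
    volume-to-speed law N = c·V^(1/3) (V in liters, N in rpm);
    ``min_speed_at_ref``/``max_speed_at_ref`` are the operating bounds
    at ``reference_volume``, scaled to other volumes by the same
    cube-root law.
    """

    name: str
    impeller_diameter: float  # m
    volume_range: tuple[float, float]  # L
    speed_constant: float | None = None  # rpm·L^(-1/3)
    reference_volume: float | None = None  # L
    min_speed_at_ref: float | None = None  # rpm
    max_speed_at_ref: float | None = None  # rpm

    def __post_init__(self) -> None:
        if self.impeller_diameter <= 0:
            raise InvalidParameterError("impeller_diameter must be > 0")
        lo, hi = self.volume_range
        if not lo < hi:
            raise InvalidParameterError("volume_range must be ascending")
        if (
            self.min_speed_at_ref is not None
            and self.max_speed_at_ref is not None
            and not self.min_speed_at_ref < self.max_speed_at_ref
        ):
            raise InvalidParameterError("min speed must be < max speed")
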