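"""Built-in parameter sets, media, feed schedule and reactor geometries.

These are the published reference conditions of the 150 mL DASbox
perfusion process: the exemplary kinetic constants, the E8-based medium
compositions, the day-by-day perfusion schedule, and the two supported
stirred-tank systems.

The DMEM/F12 basis contributes 17.5 mM glucose and 2.5 mM glutamine
(configurable); the feed media add 30 g and 45 g glucose per 10 L
(16.65 and 24.98 mM) and glutamine to 4.5 and 5.0 mM total. Osmolality
defaults are the midpoints of the quality-control ranges (315–320,
335–340 and 350–355 mOsm/kg).
"""

from __future__ import annotations

from .parameters import (
    FeedSchedule,
    FeedSegment,
    KineticParameters,
    MediumComposition,
    ProcessState,
    ReactorGeometry,
)

__all__ = [
    "table1_params",
    "e8_media",
    "table3_schedule",
    "reference_initial_state",
    "dasbox",
    "bioblock",
]

#: basal glucose of the DMEM/F12-based E8 media [mM]
BASAL_GLC = 17.5
#: basal glutamine of DMEM/F12 [mM] (feed I totals 4.5 after +2 mM)
BASAL_GLN = 2.5
#: added glucose in the feed bases [mM]: 30 g and 45 g per 10 L at 180.156 g/mol
FEED_I_ADDED_GLC = 16.65
FEED_II_ADDED_GLC = 24.98


def table1_params() -> KineticParameters:
    """Exemplary kinetic constants plus the committed calibrated
    auxiliaries (osmolality yield, reference osmolality, nucleation
    diameter)."""
    return KineticParameters()


def e8_media(basal_glc: float = BASAL_GLC) -> dict[str, MediumComposition]:
    """The three E8-based media: inoculation/suspension basis, full feed
    medium I (days 1–4) and full feed medium II (days 4–7).

    Perfusion feed is fresh medium, so feed lactate is 0 mM.
    """
    return {
        "suspension": MediumComposition(
            glc=basal_glc, gln=BASAL_GLN, lac=0.0, osm=317.5, label="E8 suspension"
        ),
        "feed_i": MediumComposition(
            glc=basal_glc + FEED_I_ADDED_GLC,
            gln=4.5,
            lac=0.0,
            osm=337.5,
            label="E8 full feed medium I",
        ),
        "feed_ii": MediumComposition(
            glc=basal_glc + FEED_II_ADDED_GLC,
            gln=5.0,
            lac=0.0,
            osm=352.5,
            label="E8 full feed medium II",
        ),
    }


def table3_schedule(basal_glc: float = BASAL_GLC) -> FeedSchedule:
    """Published perfusion schedule: 0, 1, 1.5, 3 vvd on feed medium I
    (days 0–4), then 4, 6, 7 vvd on feed medium II (days 4–7)."""
    media = e8_media(basal_glc)
    fi, fii = media["feed_i"], media["feed_ii"]
    return FeedSchedule(
        [
            FeedSegment(0, 1, 0.0, None),
            FeedSegment(1, 2, 1.0, fi),
            FeedSegment(2, 3, 1.5, fi),
            FeedSegment(3, 4, 3.0, fi),
            FeedSegment(4, 5, 4.0, fii),
            FeedSegment(5, 6, 6.0, fii),
            FeedSegment(6, 7, 7.0, fii),
        ]
    )


def reference_initial_state(
    V: float = 0.15, X0_per_mL: float = 0.5e6, basal_glc: float = BASAL_GLC
) -> ProcessState:
    """Inoculation state of the reference 150 mL process:
    0.5 × 10⁶ cells/mL in E8 suspension medium, no aggregates yet."""
    basis = e8_media(basal_glc)["suspension"]
    return ProcessState(
        t=0.0,
        X=X0_per_mL * 1e3,  # cells/mL -> cells/L
        glc=basis.glc,
        lac=basis.lac,
        gln=basis.gln,
        osm=basis.osm,
        d_agg=0.0,
        V=V,
    )


def dasbox() -> ReactorGeometry:
    """DASbox mini bioreactor: 34 mm pitched-blade impeller, 100–250 mL
    working range, fitted speed law N = 150.5·V^(1/3), operating window
    50–120 rpm at the 150 mL reference volume."""
    return ReactorGeometry(
        name="dasbox",
        impeller_diameter=0.034,
        volume_range=(0.10, 0.25),
        speed_constant=150.5,
        reference_volume=0.15,
        min_speed_at_ref=50.0,
        max_speed_at_ref=120.0,
    )


def bioblock() -> ReactorGeometry:
    """DASGIP Bioblock: 53 mm pitched-blade impeller, 300–1000 mL
    working range, fitted speed law N = 76.5·V^(1/3)."""
    return ReactorGeometry(
        name="bioblock",
        impeller_diameter=0.053,
        volume_range=(0.30, 1.00),
        speed_constant=76.5,
        reference_volume=None,
        min_speed_at_ref=None,
        max_speed_at_ref=None,
    )
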