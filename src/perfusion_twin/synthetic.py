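"""Synthetic noisy process-sampling datasets from the simulator.

Emulates the daily sampling routine of the perfused process — automated
trypan-blue cell counting and supernatant metabolite/osmolality assays —
by sampling a simulated trajectory at the requested times and applying
measurement noise: multiplicative lognormal noise on cell density
(counting error scales with the count) and additive Gaussian noise on
concentrations, clamped at zero. Identical seed and inputs give an
identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import Trajectory, simulate
from .parameters import FeedSchedule, InvalidParameterError, KineticParameters, ProcessState
from .rates import ProcessTimeSeries, SampleRecord

__all__ = ["NoiseModel", "synthesize", "sample_trajectory"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for one synthetic dataset.

    ``cv_X`` is the coefficient of variation of the multiplicative
    lognormal error on viable cell density; the ``sd_*`` fields are
    additive Gaussian standard deviations in the measurement's own unit.
    Engineering defaults reflect typical repeatability of automated
    counters and enzymatic assays.
    """

    cv_X: float = 0.05
    sd_met: float = 0.3  # mM, applied to glc/lac/gln
    sd_osm: float = 3.0  # mOsm/kg
    sd_agg: float = 10.0  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_X, self.sd_met, self.sd_osm, self.sd_agg) < 0:
            raise InvalidParameterError("noise magnitudes must be >= 0")


def sample_trajectory(
    traj: Trajectory, sampling_times, schedule: FeedSchedule
) -> list[SampleRecord]:
    """Noise-free records at the given times (must lie on the output grid)."""
    records = []
    for t in sampling_times:
        s = traj.state_at(t)
        records.append(
            SampleRecord(
                t=s.t,
                X=s.X,
                glc=s.glc,
                lac=s.lac,
                gln=s.gln,
                osm=s.osm,
                d_agg=s.d_agg,
                F=schedule.rate_at(min(t, schedule.end_day)) * traj.V,
                V=traj.V,
            )
        )
    return records


def synthesize(
    p: KineticParameters,
    schedule: FeedSchedule,
    sampling_times,
    noise: NoiseModel,
    initial: ProcessState | None = None,
    dt_out: float = 0.05,
) -> ProcessTimeSeries:
    """Simulate, sample and perturb: the synthetic counterpart of one
    sampled bioreactor run.

    The trajectory output grid is aligned to contain every sampling
    time; noise draws are deterministic per ``noise.seed``. Cell-density
    draws are strictly positive by construction of the lognormal;
    concentrations are clamped at zero.
    """
    from . import presets

    if initial is None:
        initial = presets.reference_initial_state()
    sampling_times = sorted(float(t) for t in sampling_times)
    t_end = max(sampling_times)
    if t_end <= initial.t:
        raise InvalidParameterError("sampling must extend beyond the initial time")

    traj = simulate(initial, p, schedule, t_end, dt_out=dt_out)
    clean = sample_trajectory(traj, sampling_times, schedule)

    rng = np.random.default_rng(noise.seed)
    # lognormal with unit mean and the requested CV
    sigma = np.sqrt(np.log(1.0 + noise.cv_X**2))
    records = []
    for rec in clean:
        x_fac = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)) if sigma > 0 else 1.0
        met = rng.normal(0.0, noise.sd_met, size=3) if noise.sd_met > 0 else np.zeros(3)
        osm_eps = float(rng.normal(0.0, noise.sd_osm)) if noise.sd_osm > 0 else 0.0
        agg_eps = float(rng.normal(0.0, noise.sd_agg)) if noise.sd_agg > 0 else 0.0
        records.append(
            SampleRecord(
                t=rec.t,
                X=rec.X * x_fac,
                glc=max(0.0, rec.glc + float(met[0])),
                lac=max(0.0, rec.lac + float(met[1])),
                gln=max(0.0, rec.gln + float(met[2])),
                osm=max(0.0, rec.osm + osm_eps),
                d_agg=max(0.0, rec.d_agg + agg_eps) if rec.d_agg > 0 else 0.0,
                F=rec.F,
                V=rec.V,
            )
        )
    return ProcessTimeSeries(records)
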