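import numpy as np
import pytest

from perfusion_twin import NoiseModel, PerfusionModel, synthesize
from perfusion_twin import presets


@pytest.fixture(scope="session")
def ref_model() -> PerfusionModel:
    """Reference 150 mL process with the shipped calibrated defaults."""
    return PerfusionModel()


@pytest.fixture(scope="session")
def ref_traj(ref_model):
    """Reference 7-day trajectory on the default output grid."""
    return ref_model.simulate()


@pytest.fixture(scope="session")
def fine_traj(ref_model):
    """Finely resolved reference trajectory for interval-average oracles."""
    return ref_model.simulate(dt_out=0.005)


@pytest.fixture(scope="session")
def clean_daily_series(ref_model):
    """Noise-free daily samples (days 0..7) of the reference run."""
    noise = NoiseModel(cv_X=0.0, sd_met=0.0, sd_osm=0.0, sd_agg=0.0, seed=0)
    return synthesize(
        ref_model.params, ref_model.schedule, range(8), noise, initial=ref_model.initial
    )


def interval_true_rates(fine_traj, params, t1, t2):
    """Independent oracle: the simulator's own instantaneous rates,
    averaged over [t1, t2].

    μ is averaged over time (which the log-mean estimator reproduces
    exactly for piecewise-exponential growth); the cell-specific rates
    are cell-weighted: q̄ = q_max · ∫a(t)·X dt / ∫X dt with a the
    instantaneous metabolic activity μ_eff/μ_max.
    """
    from perfusion_twin.kinetics import specific_growth_rate
    from perfusion_twin.parameters import ProcessState

    mask = (fine_traj.t >= t1 - 1e-12) & (fine_traj.t <= t2 + 1e-12)
    t = fine_traj.t[mask]
    X = fine_traj.X[mask]
    mu_inst = np.array(
        [
            specific_growth_rate(
                ProcessState(
                    t=float(tt),
                    X=float(xx),
                    glc=float(fine_traj.glc[mask][i]),
                    lac=float(fine_traj.lac[mask][i]),
                    gln=float(fine_traj.gln[mask][i]),
                    osm=float(fine_traj.osm[mask][i]),
                    d_agg=float(fine_traj.d_agg[mask][i]),
                    V=fine_traj.V,
                ),
                params,
            )
            for i, (tt, xx) in enumerate(zip(t, X))
        ]
    )
    act = mu_inst / params.mu_max
    w = np.trapezoid(act * X, t) / np.trapezoid(X, t)
    mu_bar = np.trapezoid(mu_inst, t) / (t[-1] - t[0])
    return {
        "mu": mu_bar,
        "q_glc": params.q_Glc_max * w,
        "q_lac": params.q_Lac_max * w,
        "q_gln": params.q_Gln_max * w,
    }
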