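"""Monod-kinetic growth and metabolism model of a perfused stirred tank.

The specific growth rate of the hPSC aggregate suspension is the maximal
rate scaled by multiplicative Monod factors: substrate limitation by
glucose and glutamine (c/(K+c)), and hyperbolic inhibition (K/(K+x)) by
lactate, by osmolality excess above a reference, and by the mean
aggregate radius. Metabolite mass balances combine cell-specific
consumption/production with perfusion exchange at dilution rate F/V
against the feed composition; cells are fully retained by the filter, so
the cell balance has no washout term and the working volume is constant.

Metabolism is growth-associated (a Pirt closure with zero maintenance):
each cell-specific rate is its maximum scaled by the relative growth
rate μ_eff/μ_max. Glycolytic lactate production therefore ceases when
glucose is exhausted (μ_eff contains the glucose factor), and uptake
relaxes as the culture leaves exponential growth — without which the
printed maximal rates would overdraw the feed at high density and pin
lactate far above observed levels.

Aggregates nucleate at ``t_agg`` with mean diameter ``d_agg_init`` and
thereafter grow by the cube-root law d' = μ·d/3, the geometric
consequence of aggregate volume tracking cell number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    FeedSchedule,
    InvalidParameterError,
    KineticParameters,
    MediumComposition,
    ProcessState,
)

__all__ = [
    "monod_limitation",
    "monod_inhibition",
    "specific_growth_rate",
    "rhs",
    "simulate",
    "Trajectory",
    "IntegrationError",
    "CalibrationError",
    "calibrate_defaults",
]

# state vector layout used by the integrator
_STATE = ("X", "glc", "lac", "gln", "osm", "d_agg")
# clamp tolerance: states this far below zero indicate integrator failure
_NEG_TOL = 1e-6


class IntegrationError(RuntimeError):
    """The ODE integrator failed or produced an inconsistent state."""


class CalibrationError(RuntimeError):
    """The calibration target is unreachable within the given bounds."""

    def __init__(self, message: str, best: "KineticParameters | None" = None,
                 best_value: float | None = None):
        super().__init__(message)
        self.best = best
        self.best_value = best_value


def monod_limitation(c: float, K: float) -> float:
    """Saturating Monod limitation factor c/(K+c) in [0, 1)."""
    if K <= 0:
        raise InvalidParameterError("Monod constant K must be > 0")
    if c < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return c / (K + c)


def monod_inhibition(c: float, K: float) -> float:
    """Hyperbolic inhibition factor K/(K+c) in (0, 1]."""
    if K <= 0:
        raise InvalidParameterError("inhibition constant K must be > 0")
    if c < 0:
        raise InvalidParameterError("inhibitor level must be >= 0")
    return K / (K + c)


def specific_growth_rate(state: ProcessState, p: KineticParameters) -> float:
    """Effective specific growth rate μ_eff [1/day] at the given state.

    μ_eff = μ_max · f_Glc · f_Gln · f_Lac · f_Osm · f_Agg, where the
    first two are limitation factors and the last three inhibition
    factors (lactate; osmolality excess over ``osm_ref``; aggregate
    radius d_agg/2 against the critical radius ``K_Agg``).
    """
    return p.mu_max * _growth_factors(
        state.glc, state.lac, state.gln, state.osm, state.d_agg, p
    )


def _growth_factors(glc, lac, gln, osm, d_agg, p: KineticParameters) -> float:
    return (
        monod_limitation(glc, p.K_Glc)
        * monod_limitation(gln, p.K_Gln)
        * monod_inhibition(lac, p.K_Lac)
        * monod_inhibition(max(0.0, osm - p.osm_ref), p.K_Osm)
        * monod_inhibition(d_agg / 2.0, p.K_Agg)
    )


def rhs(
    state: ProcessState,
    p: KineticParameters,
    F: float,
    feed: MediumComposition | None,
) -> dict[str, float]:
    """Time derivative of the process state under flow F [L/day].

    Returns a mapping with keys ``X, glc, lac, gln, osm, d_agg, V``.
    With F > 0 a feed composition is required; cells are retained, so
    dX/dt has no dilution term and dV/dt = 0. Cell-specific metabolic
    rates are growth-associated: q_i = q_i_max · μ_eff/μ_max.
    """
    if F < 0:
        raise InvalidParameterError("flow rate must be >= 0")
    if F > 0 and feed is None:
        raise InvalidParameterError("perfusion (F > 0) requires a feed medium")
    y = _pack(state)
    dy = _rhs_vec(state.t, y, p, F / state.V, feed, state.t)
    out = dict(zip(_STATE, dy))
    out["V"] = 0.0
    return out


def _pack(state: ProcessState) -> np.ndarray:
    return np.array(
        [state.X, state.glc, state.lac, state.gln, state.osm, state.d_agg],
        dtype=float,
    )


def _rhs_vec(
    t: float,
    y: np.ndarray,
    p: KineticParameters,
    D: float,
    feed: MediumComposition | None,
    t_agg_active_from: float,
) -> np.ndarray:
    """Vector field on the packed state. ``D`` is the dilution rate F/V.

    Concentrations are clamped at zero from below before evaluating the
    kinetic factors, which suppresses consumption of an exhausted
    substrate (the Monod factor vanishes with the substrate).
    """
    X = max(y[0], 0.0)
    glc = max(y[1], 0.0)
    lac = max(y[2], 0.0)
    gln = max(y[3], 0.0)
    osm = max(y[4], 0.0)
    d_agg = max(y[5], 0.0)

    f_glc = glc / (p.K_Glc + glc)
    f_gln = gln / (p.K_Gln + gln)
    mu = (
        p.mu_max
        * f_glc
        * f_gln
        * p.K_Lac / (p.K_Lac + lac)
        * p.K_Osm / (p.K_Osm + max(0.0, osm - p.osm_ref))
        * p.K_Agg / (p.K_Agg + d_agg / 2.0)
    )
    # growth-associated metabolic activity; vanishes with any exhausted
    # substrate, so clamped species see no further consumption
    act = mu / p.mu_max

    if feed is not None:
        glc_f, lac_f, gln_f, osm_f = feed.glc, feed.lac, feed.gln, feed.osm
    else:
        glc_f = lac_f = gln_f = osm_f = 0.0

    dX = mu * X
    dglc = -p.q_Glc_max * act * X + D * (glc_f - glc)
    dlac = p.q_Lac_max * act * X + D * (lac_f - lac)
    dgln = -p.q_Gln_max * act * X + D * (gln_f - gln)
    dosm = p.k_osm * p.q_Lac_max * act * X + D * (osm_f - osm)
    dagg = (mu / 3.0) * d_agg if t >= t_agg_active_from else 0.0
    return np.array([dX, dglc, dlac, dgln, dosm, dagg])


@dataclass(frozen=True)
class Trajectory:
    """Simulated process trajectory on a uniform output grid.

    Attributes
    ----------
    t : ndarray, day
    X : ndarray, cells/L
    glc, lac, gln : ndarray, mM
    osm : ndarray, mOsm/kg
    d_agg : ndarray, μm
    V : float, constant working volume in L
    F : ndarray, feed/waste flow rate [L/day] in effect at each point
    """

    t: np.ndarray
    X: np.ndarray
    glc: np.ndarray
    lac: np.ndarray
    gln: np.ndarray
    osm: np.ndarray
    d_agg: np.ndarray
    V: float
    F: np.ndarray

    def state_at(self, t: float, tol: float = 1e-9) -> ProcessState:
        """Exact grid-point state at time ``t`` (no interpolation)."""
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > tol:
            raise KeyError(f"t={t} is not on the output grid")
        return ProcessState(
            t=float(self.t[i]),
            X=float(self.X[i]),
            glc=float(self.glc[i]),
            lac=float(self.lac[i]),
            gln=float(self.gln[i]),
            osm=float(self.osm[i]),
            d_agg=float(self.d_agg[i]),
            V=self.V,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the canonical CSV dialect (X per mL)."""
        return pd.DataFrame(
            {
                "t_d": self.t,
                "X_cells_per_mL": self.X / 1e3,
                "glc_mM": self.glc,
                "lac_mM": self.lac,
                "gln_mM": self.gln,
                "osm_mOsm_kg": self.osm,
                "agg_diameter_um": self.d_agg,
                "feed_rate_vvd": self.F / self.V,
            }
        )

    def plot(self, ax=None):
        """Plot cell density and metabolites over process time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.t, self.X / 1e3, "k-", label="X [cells/mL]")
        ax.set_xlabel("process time [d]")
        ax.set_ylabel("viable cell density [cells/mL]")
        ax.set_yscale("log")
        ax2 = ax.twinx()
        ax2.plot(self.t, self.glc, label="glucose [mM]")
        ax2.plot(self.t, self.lac, label="lactate [mM]")
        ax2.plot(self.t, self.gln, label="glutamine [mM]")
        ax2.set_ylabel("concentration [mM]")
        ax2.legend(loc="upper left", fontsize=8)
        return ax

    @property
    def fold_expansion(self) -> float:
        return float(self.X[-1] / self.X[0])


def simulate(
    initial: ProcessState,
    p: KineticParameters,
    schedule: FeedSchedule,
    t_end: float,
    dt_out: float = 0.05,
    rtol: float = 1e-8,
    atol: float | Sequence[float] | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``[initial.t, t_end]``.

    The integration restarts at every feed-schedule boundary and at the
    aggregation onset ``t_agg`` so rate and medium switches are handled
    as exact events; aggregate nucleation sets d_agg to ``d_agg_init``
    at ``t_agg`` if no aggregates exist yet. Output lands on the uniform
    ``dt_out`` grid including both endpoints. Deterministic.
    """
    t0 = initial.t
    if t_end <= t0:
        raise InvalidParameterError("t_end must exceed initial.t")
    if not (schedule.segments[0].start_day <= t0 and schedule.end_day >= t_end):
        raise InvalidParameterError("schedule does not cover the simulated span")

    n = int(round((t_end - t0) / dt_out))
    grid = t0 + dt_out * np.arange(n + 1)
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)
    grid[-1] = t_end

    breaks = sorted(
        {t0, t_end}
        | {b for b in schedule.boundaries() if t0 < b < t_end}
        | ({p.t_agg} if t0 < p.t_agg < t_end else set())
    )

    V = initial.V
    y = _pack(initial)
    out = np.empty((len(grid), 6))
    out[0] = y

    if atol is None:
        # per-state absolute tolerances in each state's own unit
        atol = np.array([1.0, 1e-8, 1e-8, 1e-10, 1e-6, 1e-6])

    for a, b in zip(breaks, breaks[1:]):
        if a >= p.t_agg and y[5] <= 0.0:
            y[5] = p.d_agg_init  # aggregate nucleation event
            at_a = np.isclose(grid, a, rtol=0, atol=1e-12)
            out[at_a, 5] = p.d_agg_init  # nucleation is right-continuous
        seg = schedule.segment_at(a)
        D = seg.rate  # vvd == F/V
        sol = solve_ivp(
            _rhs_vec,
            (a, b),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
            args=(p, D, seg.medium, p.t_agg),
        )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in [{a}, {b}] at state {dict(zip(_STATE, y))}: "
                f"{sol.message}"
            )
        mask = (grid > a) & (grid <= b)
        if mask.any():
            vals = sol.sol(grid[mask]).T
            if vals.min() < -_NEG_TOL:
                raise IntegrationError(
                    f"state fell below clamp tolerance in [{a}, {b}]"
                )
            out[mask] = np.clip(vals, 0.0, None)
        y = np.clip(sol.y[:, -1], 0.0, None)

    # flow in effect at each grid point: the rate of the segment the
    # point opens (right-continuous, matching the sampling convention)
    F_out = np.array([schedule.rate_at(min(t, schedule.end_day)) * V for t in grid])

    return Trajectory(
        t=grid,
        X=out[:, 0],
        glc=out[:, 1],
        lac=out[:, 2],
        gln=out[:, 3],
        osm=out[:, 4],
        d_agg=out[:, 5],
        V=V,
        F=F_out,
    )


def calibrate_defaults(
    p0: KineticParameters,
    bounds: Mapping[str, tuple[float, float]],
    target_X7: float,
    initial: ProcessState | None = None,
    schedule: FeedSchedule | None = None,
    t_end: float = 7.0,
    grid_points: int | Mapping[str, int] = 9,
    tolerance: float = 0.25,
    progress: Callable[[Mapping[str, float], float], None] | None = None,
) -> KineticParameters:
    """Fix the auxiliary constants by deterministic grid search.

    Only the auxiliaries named in ``bounds`` (``k_osm``, ``osm_ref``,
    ``d_agg_init``) vary; the exemplary kinetic constants stay frozen.
    Each grid axis is sampled on ``grid_points`` equispaced values
    (inclusive of both bounds; a degenerate interval yields a single
    point). The parameter set minimising |X(t_end) − target_X7| wins;
    ties break toward the earliest point in the lexicographic grid
    order. Raises :class:`CalibrationError` when the best achievable
    endpoint misses the target by more than ``tolerance`` (relative).
    """
    from . import presets

    if not bounds:
        raise CalibrationError("empty calibration bounds")
    if initial is None:
        initial = presets.reference_initial_state()
    if schedule is None:
        schedule = presets.table3_schedule()

    names = list(bounds)
    axes = []
    for name in names:
        lo, hi = bounds[name]
        npts = grid_points[name] if isinstance(grid_points, Mapping) else grid_points
        axes.append(np.array([lo]) if lo == hi else np.linspace(lo, hi, npts))

    best: KineticParameters | None = None
    best_res = np.inf
    best_X7 = np.nan
    for combo in _lex_product(axes):
        p = p0.replace(**dict(zip(names, (float(v) for v in combo))))
        X7 = simulate(initial, p, schedule, t_end).X[-1]
        res = abs(X7 - target_X7)
        if progress is not None:
            progress(dict(zip(names, combo)), X7)
        if res < best_res:
            best, best_res, best_X7 = p, res, X7

    assert best is not None
    if best_res / target_X7 > tolerance:
        raise CalibrationError(
            f"target X(t_end)={target_X7:.3g} unreachable within bounds; "
            f"best achieved {best_X7:.3g} "
            f"(relative miss {best_res / target_X7:.1%})",
            best=best,
            best_value=best_X7,
        )
    return best


def _lex_product(axes):
    """Lexicographic Cartesian product of 1-D arrays (first axis slowest)."""
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)
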