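"""Model-versus-measurement agreement via relative prediction errors.

Each paired point contributes e_i = |x_wl − x_m| / max(x_wl) × 100,
normalised by the single series-wide maximum of the wet-lab series for
that variable (not per point), summarised as the mean error and its
sample standard deviation. The smaller the mean error, the better the
model represents the measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import Trajectory
from .rates import ProcessTimeSeries

__all__ = [
    "relative_errors",
    "mean_error",
    "sd_error",
    "evaluate_model",
    "PredictionError",
    "NormalizationError",
    "PairingError",
]


class NormalizationError(ValueError):
    """The wet-lab series has no positive maximum to normalise by."""


class PairingError(ValueError):
    """No observation could be paired with a trajectory point."""


def relative_errors(wl: Sequence[float], m: Sequence[float]) -> np.ndarray:
    """Per-point relative errors [%], normalised by max(wl)."""
    wl = np.asarray(wl, dtype=float)
    m = np.asarray(m, dtype=float)
    if wl.shape != m.shape or wl.ndim != 1 or wl.size < 1:
        raise ValueError("wl and m must be equal-length 1-D series")
    wl_max = wl.max()
    if wl_max <= 0:
        raise NormalizationError("wet-lab series maximum must be > 0")
    return np.abs(wl - m) / wl_max * 100.0


def mean_error(e: Sequence[float]) -> float:
    """Arithmetic mean of a relative-error vector [%]."""
    e = np.asarray(e, dtype=float)
    if e.size < 1:
        raise ValueError("error vector must be non-empty")
    return float(e.mean())


def sd_error(e: Sequence[float]) -> float:
    """Sample standard deviation (n−1 denominator) of the errors [%]."""
    e = np.asarray(e, dtype=float)
    if e.size < 2:
        raise ValueError("sample SD needs at least two errors")
    return float(e.std(ddof=1))


@dataclass(frozen=True)
class PredictionError:
    """Prediction-error summary for one process variable."""

    variable: str
    e_ri: np.ndarray  # per-point relative errors [%]
    e_bar: float  # mean error [%]
    sd: float | None  # sample SD [%], None for a single pair
    n: int
    unpaired_times: tuple[float, ...] = ()

    def __str__(self) -> str:
        sd = f"{self.sd:.2f}" if self.sd is not None else "n/a"
        return (
            f"{self.variable}: mean error {self.e_bar:.2f}% ± {sd}% "
            f"(n={self.n}, unpaired={len(self.unpaired_times)})"
        )


#: trajectory attribute holding each observable (X is compared per liter)
_TRAJ_FIELDS = {
    "X": "X",
    "glc": "glc",
    "lac": "lac",
    "gln": "gln",
    "osm": "osm",
    "d_agg": "d_agg",
}


def evaluate_model(
    traj: Trajectory,
    obs: ProcessTimeSeries,
    variables: Sequence[str] = ("X", "glc", "lac", "gln"),
    t_tol: float = 0.02,
) -> dict[str, PredictionError]:
    """Pair observations with trajectory grid points and compute the
    prediction-error statistics per requested variable.

    Pairing is nearest-in-time within ``t_tol`` days; observations with
    no grid point inside the tolerance are reported in
    ``unpaired_times``, never silently dropped. Observations lacking the
    variable (None) are skipped for that variable.
    """
    out: dict[str, PredictionError] = {}
    for var in variables:
        if var not in _TRAJ_FIELDS:
            raise KeyError(f"unknown variable '{var}'; choose from {list(_TRAJ_FIELDS)}")
        model_series = getattr(traj, _TRAJ_FIELDS[var])
        wl, m, unpaired = [], [], []
        for rec in obs:
            val = getattr(rec, var)
            if val is None:
                continue
            i = int(np.argmin(np.abs(traj.t - rec.t)))
            if abs(traj.t[i] - rec.t) > t_tol:
                unpaired.append(rec.t)
                continue
            wl.append(val)
            m.append(model_series[i])
        if not wl:
            raise PairingError(
                f"no observation of '{var}' pairs with the trajectory "
                f"within {t_tol} d"
            )
        e = relative_errors(wl, m)
        out[var] = PredictionError(
            variable=var,
            e_ri=e,
            e_bar=mean_error(e),
            sd=sd_error(e) if e.size >= 2 else None,
            n=int(e.size),
            unpaired_times=tuple(unpaired),
        )
    return out


def summary_frame(errors: Mapping[str, PredictionError]) -> pd.DataFrame:
    """Per-variable summary table: ``variable, n, e_bar_pct, sd_pct``."""
    return pd.DataFrame(
        [
            {
                "variable": pe.variable,
                "n": pe.n,
                "e_bar_pct": pe.e_bar,
                "sd_pct": pe.sd if pe.sd is not None else float("nan"),
            }
            for pe in errors.values()
        ]
    )
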