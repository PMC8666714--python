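"""Cell-specific rate estimation from sampled process data.

The estimators are strictly pairwise between consecutive samples. The
specific growth rate over an interval is the density change divided by
the logarithmic-mean density; substrate/waste rates follow the same
pattern, with a perfusion correction term F/V·(c̄ − c_feed) added on
intervals with medium exchange. The logarithmic mean is the correct
average of an exponentially changing quantity and makes the growth
estimator algebraically identical to ln(X₂/X₁)/Δt.

Sign convention: consumption-positive for substrates (glucose,
glutamine), production-positive for wastes (lactate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .parameters import FeedSchedule, InvalidParameterError, MediumComposition

__all__ = [
    "log_mean",
    "growth_rate_estimate",
    "substrate_rate_batch",
    "substrate_rate_perfusion",
    "waste_rate_batch",
    "waste_rate_perfusion",
    "estimate_all",
    "SampleRecord",
    "ProcessTimeSeries",
    "RateEstimates",
    "LogMeanDomainError",
    "WrongRegimeError",
    "MissingFieldError",
]

_EQUAL_REL_TOL = 1e-12


class LogMeanDomainError(ValueError):
    """A logarithmic mean was requested for a non-positive value.

    The arithmetic-mean fallback is never applied silently; callers that
    can tolerate the degenerate case must handle this error explicitly.
    """


class WrongRegimeError(ValueError):
    """A batch estimator was used on a perfused interval or vice versa."""


class MissingFieldError(ValueError):
    """A required metabolite column is absent from a sample record."""


@dataclass(frozen=True)
class SampleRecord:
    """One bioreactor sampling time point.

    ``F`` is the feed/waste flow [L/day] in effect over the interval
    this record opens (step-function convention for daily schedule
    changes). Optional fields default to None.
    """

    t: float  # day
    X: float  # cells/L
    glc: float | None = None  # mM
    lac: float | None = None  # mM
    gln: float | None = None  # mM
    osm: float | None = None  # mOsm/kg
    d_agg: float | None = None  # μm
    F: float = 0.0  # L/day
    V: float = 1.0  # L
    viability: float | None = None  # fraction

    def __post_init__(self) -> None:
        if self.F < 0:
            raise InvalidParameterError("F must be >= 0")
        if self.V <= 0:
            raise InvalidParameterError("V must be > 0")


@dataclass(frozen=True)
class ProcessTimeSeries:
    """Ordered sequence of sampling records with strictly increasing t.

    ``extra`` carries columns of the source file that are not part of
    the canonical schema, so they survive a read/write round-trip.
    """

    records: tuple[SampleRecord, ...]
    extra: "pd.DataFrame | None" = None

    def __init__(self, records: Iterable[SampleRecord], extra=None):
        recs = tuple(records)
        for a, b in zip(recs, recs[1:]):
            if b.t <= a.t:
                raise InvalidParameterError(
                    f"sample times must be strictly increasing (t={a.t} then {b.t})"
                )
        object.__setattr__(self, "records", recs)
        object.__setattr__(self, "extra", extra)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def log_mean(a: float, b: float) -> float:
    """Logarithmic mean (a−b)/(ln a − ln b) of two positive quantities.

    Returns ``a`` in the equal-value limit (relative gap ≤ 1e-12).
    Raises :class:`LogMeanDomainError` for non-positive input.
    """
    if a <= 0 or b <= 0:
        raise LogMeanDomainError(
            f"log mean requires positive values, got ({a}, {b}); "
            "no arithmetic-mean fallback is applied"
        )
    if abs(a - b) <= _EQUAL_REL_TOL * max(a, b):
        return a
    return (a - b) / (math.log(a) - math.log(b))


def _interval(x1: SampleRecord, x2: SampleRecord) -> float:
    if x2.t <= x1.t:
        raise InvalidParameterError("records must be in increasing time order")
    return x2.t - x1.t


def growth_rate_estimate(x1: SampleRecord, x2: SampleRecord) -> float:
    """Specific growth rate μ [1/day] between consecutive samples:
    ΔX/Δt divided by the log-mean density; equals ln(X₂/X₁)/Δt."""
    dt = _interval(x1, x2)
    xbar = log_mean(x2.X, x1.X)
    return (x2.X - x1.X) / dt / xbar


def _metabolite(rec: SampleRecord, name: str) -> float:
    v = getattr(rec, name, None)
    if v is None:
        raise MissingFieldError(f"sample at t={rec.t} lacks required column '{name}'")
    return v


def substrate_rate_batch(s1: SampleRecord, s2: SampleRecord, metabolite: str) -> float:
    """Cell-specific substrate consumption rate q [mmol·cell⁻¹·day⁻¹]
    over an unfed interval: −ΔS/Δt divided by the log-mean density.
    Positive when the substrate falls; a negative value signals apparent
    production and is preserved, not corrected."""
    dt = _interval(s1, s2)
    a, b = _metabolite(s1, metabolite), _metabolite(s2, metabolite)
    xbar = log_mean(s2.X, s1.X)
    return -(b - a) / dt / xbar


def substrate_rate_perfusion(
    s1: SampleRecord,
    s2: SampleRecord,
    metabolite: str,
    feed: MediumComposition,
) -> float:
    """Cell-specific substrate consumption rate over a perfused
    interval: −[ΔS/Δt + F/V·(S̄ − S_f)] / X̄, with S̄ the log-mean
    culture concentration and S_f the feed concentration."""
    if s1.F <= 0:
        raise WrongRegimeError(
            "interval has F = 0; use the batch estimator for unfed intervals"
        )
    dt = _interval(s1, s2)
    a, b = _metabolite(s1, metabolite), _metabolite(s2, metabolite)
    sbar = log_mean(b, a)
    xbar = log_mean(s2.X, s1.X)
    s_f = getattr(feed, metabolite)
    return -((b - a) / dt + (s1.F / s1.V) * (sbar - s_f)) / xbar


def waste_rate_batch(w1: SampleRecord, w2: SampleRecord, metabolite: str = "lac") -> float:
    """Cell-specific waste production rate over an unfed interval:
    ΔW/Δt divided by the log-mean density (production-positive)."""
    dt = _interval(w1, w2)
    a, b = _metabolite(w1, metabolite), _metabolite(w2, metabolite)
    xbar = log_mean(w2.X, w1.X)
    return (b - a) / dt / xbar


def waste_rate_perfusion(w1: SampleRecord, w2: SampleRecord, metabolite: str = "lac") -> float:
    """Cell-specific waste production rate over a perfused interval:
    [ΔW/Δt + F/V·W̄] / X̄ — the feed is fresh medium, so its waste
    concentration is implicitly zero."""
    if w1.F <= 0:
        raise WrongRegimeError(
            "interval has F = 0; use the batch estimator for unfed intervals"
        )
    dt = _interval(w1, w2)
    a, b = _metabolite(w1, metabolite), _metabolite(w2, metabolite)
    wbar = log_mean(b, a)
    xbar = log_mean(w2.X, w1.X)
    return ((b - a) / dt + (w1.F / w1.V) * wbar) / xbar


#: metabolites handled by estimate_all and their role
_SUBSTRATES = ("glc", "gln")
_WASTES = ("lac",)


@dataclass(frozen=True)
class RateEstimates:
    """Per-interval rate estimates as a tidy table.

    One row per consecutive-sample interval with columns
    ``t_start_d, t_end_d, regime, mu_per_d, q_glc, q_lac, q_gln,
    reason``. Intervals whose log means are undefined carry NaN for the
    affected rates and a reason code — never dropped silently.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:.4g}".format):
            return self.table.to_string(index=False)


def estimate_all(
    series: ProcessTimeSeries,
    schedule: FeedSchedule | None = None,
    metabolites: Sequence[str] = ("glc", "lac", "gln"),
) -> RateEstimates:
    """Estimate μ and cell-specific metabolite rates on every interval.

    The regime is perfusion iff F > 0 on the record opening the
    interval; perfused substrate estimates need the feed composition,
    taken from ``schedule`` at the interval start. Degenerate intervals
    (non-positive values inside a required log mean, missing feed
    composition) yield NaN rates with a reason code.
    """
    if len(series) < 2:
        raise InvalidParameterError("need at least two samples")
    rows = []
    for r1, r2 in zip(series, series.records[1:]):
        regime = "perfusion" if r1.F > 0 else "batch"
        reasons: list[str] = []
        row: dict[str, object] = {
            "t_start_d": r1.t,
            "t_end_d": r2.t,
            "regime": regime,
        }
        try:
            row["mu_per_d"] = growth_rate_estimate(r1, r2)
        except LogMeanDomainError:
            row["mu_per_d"] = float("nan")
            reasons.append("mu:log-mean domain")

        feed = None
        if regime == "perfusion" and schedule is not None:
            seg = schedule.segment_at(r1.t)
            feed = seg.medium

        for met in metabolites:
            col = f"q_{met}"
            try:
                if regime == "batch":
                    if met in _WASTES:
                        row[col] = waste_rate_batch(r1, r2, met)
                    else:
                        row[col] = substrate_rate_batch(r1, r2, met)
                elif met in _WASTES:
                    row[col] = waste_rate_perfusion(r1, r2, met)
                else:
                    if feed is None:
                        row[col] = float("nan")
                        reasons.append(f"{col}:no feed composition")
                        continue
                    row[col] = substrate_rate_perfusion(r1, r2, met, feed)
            except LogMeanDomainError:
                row[col] = float("nan")
                reasons.append(f"{col}:log-mean domain")
            except MissingFieldError:
                row[col] = float("nan")
                reasons.append(f"{col}:missing column")
        row["reason"] = ";".join(reasons)
        rows.append(row)
    return RateEstimates(pd.DataFrame(rows))
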