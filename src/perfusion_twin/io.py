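"""Readers and writers for the process-data CSV dialect and run configs.

One canonical CSV dialect (UTF-8, comma separator, dot decimal, header
mandatory) with unit-bearing column names. The cell-density column is
``X_cells_per_mL`` — the human-facing unit — and the conversion to the
internal cells/L happens exactly once, here at the boundary; a column
with any other density unit in its name is rejected rather than
rescaled, which is the only robust guard against the mL-vs-L trap in
per-cell rate arithmetic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .parameters import (
    FeedSchedule,
    FeedSegment,
    InvalidParameterError,
    KineticParameters,
    MediumComposition,
    ProcessState,
)
from .rates import ProcessTimeSeries, SampleRecord
from . import presets

__all__ = [
    "read_process_csv",
    "write_process_csv",
    "load_builtin",
    "load_config",
    "config_digest",
    "SchemaError",
    "PROCESS_COLUMNS",
]

#: canonical column order of the process-data dialect
PROCESS_COLUMNS = (
    "t_d",
    "X_cells_per_mL",
    "viability_pct",
    "glc_mM",
    "lac_mM",
    "gln_mM",
    "osm_mOsm_kg",
    "agg_diameter_um",
    "feed_rate_vvd",
    "volume_L",
)

_REQUIRED = ("t_d", "X_cells_per_mL")
_OPTIONAL_MAP = {
    "glc_mM": "glc",
    "lac_mM": "lac",
    "gln_mM": "gln",
    "osm_mOsm_kg": "osm",
    "agg_diameter_um": "d_agg",
}


class SchemaError(ValueError):
    """The file does not conform to the process-data schema.

    ``problems`` lists every offending (row, column, reason) found, not
    just the first.
    """

    def __init__(self, problems: list[tuple[Any, str, str]]):
        self.problems = problems
        lines = "\n".join(f"  row {r}, column {c}: {why}" for r, c, why in problems)
        super().__init__(f"process-data schema violations:\n{lines}")


def read_process_csv(path) -> ProcessTimeSeries:
    """Read a process-data CSV into a time series (X converted to
    cells/L at this boundary, exactly once)."""
    df = pd.read_csv(path)
    problems: list[tuple[Any, str, str]] = []

    for col in _REQUIRED:
        if col not in df.columns:
            hint = ""
            if col == "X_cells_per_mL":
                wrong = [c for c in df.columns if c.lower().startswith("x_cells")]
                if wrong:
                    hint = (
                        f" (found '{wrong[0]}'; densities must be supplied "
                        "per mL — no automatic unit rescaling is applied)"
                    )
            problems.append(("header", col, f"required column missing{hint}"))
    if problems:
        raise SchemaError(problems)

    t = df["t_d"].to_numpy()
    for i in range(1, len(t)):
        if not t[i] > t[i - 1]:
            problems.append((i, "t_d", "times must be strictly increasing"))
    for i, x in enumerate(df["X_cells_per_mL"]):
        if pd.isna(x) or x < 0:
            problems.append((i, "X_cells_per_mL", "density must be >= 0"))
    for col in _OPTIONAL_MAP:
        if col in df.columns:
            for i, v in enumerate(df[col]):
                if pd.notna(v) and v < 0:
                    problems.append((i, col, "value must be >= 0"))
    if problems:
        raise SchemaError(problems)

    records = []
    for i, row in df.iterrows():
        kwargs: dict[str, Any] = {
            "t": float(row["t_d"]),
            "X": float(row["X_cells_per_mL"]) * 1e3,  # per mL -> per L
        }
        for col, attr in _OPTIONAL_MAP.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[attr] = float(row[col])
        if "volume_L" in df.columns and pd.notna(row["volume_L"]):
            kwargs["V"] = float(row["volume_L"])
        if "feed_rate_vvd" in df.columns and pd.notna(row["feed_rate_vvd"]):
            kwargs["F"] = float(row["feed_rate_vvd"]) * kwargs.get("V", 1.0)
        if "viability_pct" in df.columns and pd.notna(row["viability_pct"]):
            kwargs["viability"] = float(row["viability_pct"]) / 100.0
        records.append(SampleRecord(**kwargs))
    unknown = [c for c in df.columns if c not in PROCESS_COLUMNS]
    extra = df[unknown].copy() if unknown else None
    return ProcessTimeSeries(records, extra=extra)


def write_process_csv(series: ProcessTimeSeries, path) -> None:
    """Write a time series in the canonical dialect (X per mL)."""
    rows = []
    for r in series:
        rows.append(
            {
                "t_d": r.t,
                "X_cells_per_mL": r.X / 1e3,
                "viability_pct": r.viability * 100.0 if r.viability is not None else None,
                "glc_mM": r.glc,
                "lac_mM": r.lac,
                "gln_mM": r.gln,
                "osm_mOsm_kg": r.osm,
                "agg_diameter_um": r.d_agg,
                "feed_rate_vvd": r.F / r.V,
                "volume_L": r.V,
            }
        )
    frame = pd.DataFrame(rows, columns=list(PROCESS_COLUMNS))
    if series.extra is not None:
        frame = pd.concat([frame, series.extra.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False)


_BUILTINS = {
    "table1_params": presets.table1_params,
    "table3_schedule": presets.table3_schedule,
    "media_e8": presets.e8_media,
    "dasbox": presets.dasbox,
    "bioblock": presets.bioblock,
}


def load_builtin(name: str):
    """Return a built-in fixture: the exemplary kinetic parameters, the
    published feed schedule, the E8 media, or a reactor geometry."""
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise KeyError(
            f"unknown builtin '{name}'; available: {sorted(_BUILTINS)}"
        ) from None


# ---------------------------------------------------------------------------
# run configuration


def _medium_from_cfg(d: Mapping[str, Any], label: str) -> MediumComposition:
    return MediumComposition(
        glc=float(d["glc_mM"]),
        gln=float(d["gln_mM"]),
        lac=float(d.get("lac_mM", 0.0)),
        osm=float(d["osm_mOsm_kg"]),
        label=label,
    )


def load_config(path) -> dict[str, Any]:
    """Load a YAML/JSON run configuration.

    Sections (all optional, defaults are the reference process):
    ``parameters`` (kinetic-constant overrides), ``media`` (named
    compositions), ``schedule`` (list of {start_day, end_day, rate_vvd,
    medium}), ``initial_state``, ``integration`` (dt_out, rtol, method),
    ``calibration`` (bounds, grid_points, target_X7_per_mL).
    Returns a dict with typed objects under ``parameters``, ``media``,
    ``schedule``, ``initial_state`` plus the raw sections.
    """
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise SchemaError([("document", "-", "config must be a mapping")])

    params = presets.table1_params().replace(**raw.get("parameters", {}))

    media = dict(presets.e8_media())
    for name, d in (raw.get("media") or {}).items():
        media[name] = _medium_from_cfg(d, name)

    if "schedule" in raw:
        segs = []
        for d in raw["schedule"]:
            medium = media[d["medium"]] if d.get("medium") else None
            segs.append(
                FeedSegment(
                    start_day=float(d["start_day"]),
                    end_day=float(d["end_day"]),
                    rate=float(d["rate_vvd"]),
                    medium=medium,
                )
            )
        schedule = FeedSchedule(segs)
    else:
        schedule = presets.table3_schedule()

    init_cfg = raw.get("initial_state", {})
    ref = presets.reference_initial_state(
        V=float(init_cfg.get("volume_L", 0.15)),
        X0_per_mL=float(init_cfg.get("X_cells_per_mL", 0.5e6)),
    )
    initial = ProcessState(
        t=float(init_cfg.get("t_d", ref.t)),
        X=float(init_cfg["X_cells_per_mL"]) * 1e3 if "X_cells_per_mL" in init_cfg else ref.X,
        glc=float(init_cfg.get("glc_mM", ref.glc)),
        lac=float(init_cfg.get("lac_mM", ref.lac)),
        gln=float(init_cfg.get("gln_mM", ref.gln)),
        osm=float(init_cfg.get("osm_mOsm_kg", ref.osm)),
        d_agg=float(init_cfg.get("agg_diameter_um", ref.d_agg)),
        V=ref.V,
    )

    return {
        "parameters": params,
        "media": media,
        "schedule": schedule,
        "initial_state": initial,
        "integration": raw.get("integration", {}),
        "calibration": raw.get("calibration", {}),
        "raw": raw,
    }


def config_digest(path) -> str:
    """Stable digest of a config file's semantic content (parsed and
    re-serialised as canonical JSON, so formatting changes do not alter
    the digest)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    canon = json.dumps(raw, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
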