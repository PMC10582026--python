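"""Reading and writing the breath-table CSV dialect, protocols and trial tables.

Canonical dialect: comma-separated, dot decimal, header
``t_s,vo2_lmin,vco2_lmin,hr_bpm,speed_ms,incline_pct`` (optional columns may
be absent).  Real-cart exports in other units/column names are adapted via a
:class:`Dialect`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError
from .types import GasSeries, GradedProtocol, Phase, Stage, TrialTable, ID_COLS

log = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "DEFAULT_DIALECT",
    "read_gas_series",
    "write_gas_series",
    "read_protocol",
    "write_protocol",
    "read_trial_table",
    "write_trial_table",
]

_CANONICAL = {
    "t": "t_s",
    "vo2": "vo2_lmin",
    "vco2": "vco2_lmin",
    "hr": "hr_bpm",
    "speed": "speed_ms",
    "incline": "incline_pct",
}


@dataclass(frozen=True)
class Dialect:
    """Column names and unit scales of a breath-table CSV.

    ``vo2_scale``/``vco2_scale`` multiply raw values into L min^-1 (use 1e-3
    for carts exporting mL min^-1); ``speed_scale`` into m s^-1.
    """

    columns: dict = field(default_factory=lambda: dict(_CANONICAL))
    vo2_scale: float = 1.0
    vco2_scale: float = 1.0
    speed_scale: float = 1.0


DEFAULT_DIALECT = Dialect()


def read_gas_series(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    phase: Phase = Phase.MIXED,
    exercise_start_s: float = 0.0,
    dt_nominal: Optional[float] = None,
) -> GasSeries:
    """Read a breath table, convert units, and validate timestamps.

    Malformed rows (non-numeric or missing required values) are dropped and
    counted at INFO level.  Samples are sorted by time; duplicated timestamps
    are a :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    cols = dialect.columns
    for key in ("t", "vo2", "vco2"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column {cols[key]!r} in {path.name}")

    required = [cols["t"], cols["vo2"], cols["vco2"]]
    for c in required:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        log.info("%s: dropped %d malformed row(s)", path.name, int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise DataError(f"{path.name}: no well-formed samples")

    df = df.sort_values(cols["t"], kind="mergesort")
    t = df[cols["t"]].to_numpy(float)
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise DataError(f"{path.name}: duplicated timestamp t={t[dup[0]]}")

    def opt(key, scale=1.0):
        c = cols.get(key)
        if c is None or c not in df.columns:
            return None
        return pd.to_numeric(df[c], errors="coerce").to_numpy(float) * scale

    if dt_nominal is None:
        dt_nominal = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return GasSeries(
        t=t,
        vo2=df[cols["vo2"]].to_numpy(float) * dialect.vo2_scale,
        vco2=df[cols["vco2"]].to_numpy(float) * dialect.vco2_scale,
        hr=opt("hr"),
        speed=opt("speed", dialect.speed_scale),
        incline=opt("incline"),
        dt_nominal=dt_nominal,
        phase=phase,
        exercise_start_s=exercise_start_s,
    )


def write_gas_series(series: GasSeries, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write in the canonical dialect (scales are applied inversely)."""
    df = series.to_frame()
    df["vo2_lmin"] = df["vo2_lmin"] / dialect.vo2_scale
    df["vco2_lmin"] = df["vco2_lmin"] / dialect.vco2_scale
    if "speed_ms" in df:
        df["speed_ms"] = df["speed_ms"] / dialect.speed_scale
    inv = {_CANONICAL[k]: v for k, v in dialect.columns.items()}
    df = df.rename(columns=inv)
    df.to_csv(path, index=False)


def read_protocol(path) -> GradedProtocol:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        stages = tuple(
            Stage(speed=float(s["speed"]), incline=float(s["incline"]),
                  duration=float(s.get("duration", 300.0)))
            for s in raw["stages"]
        )
        return GradedProtocol(
            stages=stages,
            rest_duration=float(raw.get("rest_duration", 600.0)),
            hr_stop=float(raw.get("hr_stop", 180.0)),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed protocol file {path}: {exc}") from exc


def write_protocol(protocol: GradedProtocol, path) -> None:
    raw = {
        "rest_duration": protocol.rest_duration,
        "hr_stop": protocol.hr_stop,
        "stages": [
            {"speed": s.speed, "incline": s.incline, "duration": s.duration}
            for s in protocol.stages
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_trial_table(table: TrialTable, path) -> None:
    """Tidy CSV with a ``# unit:`` sidecar header line per outcome column."""
    with open(path, "w") as fh:
        for col in table.outcomes:
            fh.write(f"# unit: {col} = {table.units[col]}\n")
        table.data.to_csv(fh, index=False)


def read_trial_table(path) -> TrialTable:
    units = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# unit:"):
            name, unit = line[len("# unit:"):].split("=", 1)
            units[name.strip()] = unit.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in df.columns if c not in ID_COLS and c not in units]
    if missing:
        raise FormatError(f"columns without unit declaration: {missing}")
    return TrialTable(data=df, units=units)
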