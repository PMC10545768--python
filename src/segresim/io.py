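"""Readers and writers for event tables, metrics, pulse logs, scenario
configs, and a minimal single-channel FCS 3.x reader.

All tabular artifacts are plain CSV with a header line; times are written in
hours to 4 decimals, fluorescence in instrument-like arbitrary units.
Writers and readers round-trip bit-exactly on the text representation.
Scenario configurations are YAML documents mirroring the dataclass fields.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .analysis import MetricSeries
from .control import ControllerConfig, EnvironmentProgram
from .simulator import EnvironmentState, KineticParams, Snapshot
from .scenarios import ScenarioPreset

__all__ = [
    "write_events",
    "read_events",
    "write_pulses",
    "read_pulses",
    "write_metrics",
    "read_metrics",
    "write_scenario",
    "read_scenario",
    "read_fcs",
]

EVENT_COLUMNS = ("time_h", "fluorescence")


def write_events(
    path: str | Path,
    snapshots: Sequence[Snapshot],
    phenotype_truth: Sequence[np.ndarray] | None = None,
) -> None:
    """Write a snapshot series as a CSV event table (one row per event)."""
    frames = {
        "time_h": np.repeat(
            [round(s.t, 4) for s in snapshots], [len(s) for s in snapshots]
        ),
        "fluorescence": np.concatenate([s.values for s in snapshots]),
    }
    if phenotype_truth is not None:
        frames["phenotype_truth"] = np.concatenate(
            [np.asarray(p, dtype=int) for p in phenotype_truth]
        )
    pd.DataFrame(frames).to_csv(path, index=False, float_format="%.6g")


def read_events(path: str | Path) -> list[Snapshot]:
    """Read an event table back into a snapshot series.

    Rows are grouped into snapshots by unique time value, preserving file
    order.  Malformed files raise ``ValueError`` naming the offending line
    (line 1 is the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty event file") from None
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: event table has no rows")
    for col in EVENT_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    nonpos = df["fluorescence"] <= 0
    if nonpos.any():
        line = int(nonpos.idxmax()) + 2
        raise ValueError(f"{path}: fluorescence must be > 0 (line {line})")
    decreasing = df["time_h"].diff().fillna(0) < 0
    if decreasing.any():
        line = int(decreasing.idxmax()) + 2
        raise ValueError(f"{path}: times must be non-decreasing (line {line})")
    snapshots = []
    for t, group in df.groupby("time_h", sort=False):
        snapshots.append(Snapshot(t=float(t), values=group["fluorescence"].to_numpy()))
    return snapshots


def write_pulses(path: str | Path, pulses: pd.DataFrame) -> None:
    """Pulse log CSV: time_h, actuator, dose_g_per_L."""
    out = pulses.copy()
    out["time_h"] = out["time_h"].round(4)
    out.to_csv(path, index=False)


def read_pulses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_h", "actuator", "dose_g_per_L"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pulse log must have columns {sorted(required)}")
    return df


def write_metrics(path: str | Path, metrics: MetricSeries) -> None:
    """Metric table CSV: time_h, H_bits, F_cells_per_min.

    F(t) is defined between consecutive snapshots, so the final row carries
    an empty flux field.
    """
    F = np.concatenate([metrics.F_total, [np.nan]])
    pd.DataFrame(
        {
            "time_h": np.round(metrics.times, 4),
            "H_bits": metrics.H,
            "F_cells_per_min": F,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_h", "H_bits", "F_cells_per_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metric table must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Scenario configuration files
# ---------------------------------------------------------------------------


def write_scenario(path: str | Path, scenario: ScenarioPreset) -> None:
    """Serialise a scenario to a YAML configuration file."""
    doc = {
        "name": scenario.name,
        "params": asdict(scenario.params),
        "environment": asdict(scenario.env0),
        "controller": asdict(scenario.controller),
        "program": asdict(scenario.program),
        "duration_h": scenario.duration_h,
        "seed": scenario.seed,
        "n_target": scenario.n_target,
        "n_events": scenario.n_events,
        "noise_cv": scenario.noise_cv,
        "background": scenario.background,
        "chemostat_I_in": scenario.chemostat_I_in,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scenario(path: str | Path) -> ScenarioPreset:
    """Load a scenario configuration file written by :func:`write_scenario`."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")
    try:
        return ScenarioPreset(
            name=doc.get("name", path.stem),
            params=KineticParams(**doc["params"]),
            env0=EnvironmentState(**doc["environment"]),
            controller=ControllerConfig(**doc["controller"]),
            program=EnvironmentProgram(**doc["program"]),
            duration_h=float(doc.get("duration_h", 60.0)),
            seed=int(doc.get("seed", 1)),
            n_target=int(doc.get("n_target", 10_000)),
            n_events=int(doc.get("n_events", 20_000)),
            noise_cv=float(doc.get("noise_cv", 0.25)),
            background=float(doc.get("background", 100.0)),
            chemostat_I_in=float(doc.get("chemostat_I_in", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid scenario config: {exc}") from exc


# ---------------------------------------------------------------------------
# Minimal FCS 3.x reader (single channel, read-only)
# ---------------------------------------------------------------------------


def _parse_fcs_text(segment: bytes) -> dict[str, str]:
    delim = segment[:1].decode("latin-1")
    parts = segment.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    kv = parts[1:]
    return {kv[i].strip(): kv[i + 1] for i in range(0, len(kv) - 1, 2)}


def read_fcs(path: str | Path, channel: str) -> Snapshot:
    """Read one channel of an FCS 3.0/3.1 file into a snapshot.

    Supports the common list-mode layouts (float ``$DATATYPE F``/``D`` and
    integer ``I`` with byte-aligned parameter widths).  Values are clamped
    to the seven-decade range [1, 1e7].  An unknown channel name raises a
    ``KeyError`` listing the channels present.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58 or raw[:3] != b"FCS":
        raise ValueError(f"{path}: not an FCS file")
    text_start = int(raw[10:18].decode("ascii").strip() or 0)
    text_end = int(raw[18:26].decode("ascii").strip() or 0)
    meta = _parse_fcs_text(raw[text_start : text_end + 1])

    n_par = int(meta["$PAR"])
    n_events = int(meta["$TOT"])
    names = [meta.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if channel not in names:
        raise KeyError(
            f"channel {channel!r} not in {path.name}; available channels: "
            f"{', '.join(names)}"
        )
    col = names.index(channel)

    data_start = int(meta.get("$BEGINDATA", raw[26:34].decode("ascii").strip() or 0))
    data_end = int(meta.get("$ENDDATA", raw[34:42].decode("ascii").strip() or 0))
    datatype = meta.get("$DATATYPE", "F").strip().upper()
    byteord = meta.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    widths = [int(meta[f"$P{i}B"]) // 8 for i in range(1, n_par + 1)]

    payload = raw[data_start : data_end + 1]
    order = "<" if little else ">"
    if datatype in ("F", "D") and len(set(widths)) == 1:
        fmt = {4: "f4", 8: "f8"}.get(widths[0])
        if fmt is None:
            raise ValueError(f"{path}: unsupported float width {widths[0] * 8} bits")
        mat = np.frombuffer(payload, dtype=order + fmt, count=n_events * n_par)
        values = mat.reshape(n_events, n_par)[:, col].astype(float)
    elif datatype == "I":
        row_w = sum(widths)
        offset = sum(widths[:col])
        w = widths[col]
        code = {1: "u1", 2: "u2", 4: "u4", 8: "u8"}.get(w)
        if code is None:
            raise ValueError(f"{path}: unsupported integer width {w * 8} bits")
        buf = np.frombuffer(payload, dtype=np.uint8, count=n_events * row_w)
        column = buf.reshape(n_events, row_w)[:, offset : offset + w].copy()
        values = column.view(order + code)[:, 0].astype(float)
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")

    return Snapshot(t=0.0, values=np.clip(values, 1.0, 1.0e7))
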