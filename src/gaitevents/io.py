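"""CSV interchange for cycles, labels, QC reports and events; flat YAML config.

The on-disk dialect is deliberately plain: one long-format CSV of sampled
channels plus one metadata CSV per dataset. Rows run on the force-rate time
grid; kinematic columns are populated only on motion-capture-rate rows (other
rows hold empty cells), so a single file carries both rates. All times are in
seconds, angles in degrees, velocities in m/s, forces in newtons and rates in
Hz.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cycles import FEATURE_CHANNELS, FeatureSequence, GaitCycle
from .events import StepEvents
from .signals import TimeSeries
from .synthetic import SyntheticDataset

__all__ = [
    "write_cycles_csv",
    "read_cycles_csv",
    "write_metadata_csv",
    "write_qc_report",
    "write_events_csv",
    "read_events_csv",
    "load_config",
    "dump_config",
]

ANGLE_COLUMNS = ("hip_angle", "knee_angle")
REQUIRED_COLUMNS = ("participant", "cycle", "time_s") + FEATURE_CHANNELS


def write_cycles_csv(cycles: list[GaitCycle], path) -> None:
    """Write cycles in the long format described in the module docstring."""
    frames = []
    for c in cycles:
        n_m = len(c.features)
        rate_m = c.features.rate
        if c.vgrf is not None:
            ratio = round(c.vgrf.rate / rate_m)
            n_rows = len(c.vgrf)
            time = np.arange(n_rows) / c.vgrf.rate
            vgrf = c.vgrf.values
        else:
            ratio = 1
            n_rows = n_m
            time = np.arange(n_m) / rate_m
            vgrf = np.full(n_rows, np.nan)
        df = pd.DataFrame({"participant": c.participant_id, "cycle": c.cycle_id, "time_s": time})
        for j, name in enumerate(FEATURE_CHANNELS):
            col = np.full(n_rows, np.nan)
            col[:: ratio][:n_m] = c.features.values[:, j]
            df[name] = col
        for name in ANGLE_COLUMNS:
            col = np.full(n_rows, np.nan)
            if name in c.angles:
                col[:: ratio][:n_m] = c.angles[name]
            df[name] = col
        df["vgrf"] = vgrf
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.8g")


def write_metadata_csv(dataset: SyntheticDataset, path) -> None:
    """Per-cycle metadata and generator ground truth."""
    rows = []
    for c, t in zip(dataset.cycles, dataset.truths):
        rows.append(
            {
                "participant": c.participant_id,
                "cycle": c.cycle_id,
                "dataset": c.dataset_id,
                "speed_mps": c.speed,
                "incline_deg": c.incline,
                "strike_pattern": c.strike_pattern,
                "foot_strike_angle_deg": c.foot_strike_angle,
                "contact_start_s": t.contact_start_time,
                "contact_end_s": t.contact_end_time,
                "cycle_duration_s": t.cycle_duration,
                "has_qc_violation": t.has_qc_violation,
                "mocap_rate_hz": dataset.config.mocap_rate,
                "force_rate_hz": dataset.config.force_rate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                         f"{col!r} at line {line}")
    return converted


def read_cycles_csv(path, metadata_path=None) -> list[GaitCycle]:
    """Read cycles written by `write_cycles_csv` (or an equivalent dialect).

    Kinematic rates are inferred from the time stamps of non-empty kinematic
    rows; the vGRF rate from the full row grid. A missing ``vgrf`` column
    yields cycles without force traces (labels unavailable) with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_vgrf = "vgrf" in df.columns
    if not has_vgrf:
        warnings.warn(f"{path}: no 'vgrf' column; cycles will load without force labels")
    numeric_cols = (
        ["time_s"]
        + list(FEATURE_CHANNELS)
        + [c for c in ANGLE_COLUMNS if c in df.columns]
        + (["vgrf"] if has_vgrf else [])
    )
    for col in numeric_cols:
        df[col] = _numeric(df, col, path)

    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path).set_index("cycle")

    cycles = []
    for (pid, cid), grp in df.groupby(["participant", "cycle"], sort=False):
        grp = grp.reset_index(drop=True)
        kin_rows = grp[grp[FEATURE_CHANNELS[0]].notna()]
        if len(kin_rows) < 2:
            raise ValueError(f"{path}: cycle {cid!r} has fewer than two kinematic samples")
        dt = np.diff(kin_rows["time_s"].to_numpy())
        rate_m = float(round(1.0 / np.median(dt)))
        feats = kin_rows[list(FEATURE_CHANNELS)].to_numpy(float)
        angles = {
            name: kin_rows[name].to_numpy(float)
            for name in ANGLE_COLUMNS
            if name in grp.columns and kin_rows[name].notna().all()
        }
        vgrf = None
        if has_vgrf and grp["vgrf"].notna().any():
            dtf = np.diff(grp["time_s"].to_numpy())
            rate_f = float(round(1.0 / np.median(dtf)))
            vgrf = TimeSeries(grp["vgrf"].to_numpy(float), rate_f, "vgrf")
        kwargs = {}
        if meta is not None and cid in meta.index:
            row = meta.loc[cid]
            kwargs = {
                "dataset_id": str(row.get("dataset", "default")),
                "speed": float(row.get("speed_mps", np.nan)),
                "incline": float(row.get("incline_deg", 0.0)),
                "foot_strike_angle": float(row.get("foot_strike_angle_deg", np.nan)),
                "strike_pattern": str(row.get("strike_pattern", "")),
            }
        cycles.append(
            GaitCycle(
                features=FeatureSequence(feats, rate_m),
                vgrf=vgrf,
                participant_id=str(pid),
                cycle_id=str(cid),
                angles=angles,
                **kwargs,
            )
        )
    return cycles


def write_qc_report(results: dict[str, object], path) -> None:
    """QC report CSV: cycle id, accepted flag, max loading rate (N/s)."""
    rows = [
        {
            "cycle": cid,
            "accepted": r.accepted,
            "max_loading_rate_n_per_s": r.max_rate,
            "note": r.note,
        }
        for cid, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events_csv(events: dict[str, StepEvents], path, truth: dict[str, StepEvents] | None = None) -> None:
    """Per-cycle events CSV, with error columns when ground truth is supplied."""
    rows = []
    for cid, ev in events.items():
        row = {
            "cycle": cid,
            "foot_strike_frame": ev.foot_strike_index,
            "toe_off_frame": ev.toe_off_index,
            "foot_strike_ms": ev.foot_strike_time_ms,
            "toe_off_ms": ev.toe_off_time_ms,
            "contact_time_ms": ev.contact_time_ms,
            "rate_hz": ev.rate,
        }
        if truth is not None and cid in truth:
            tr = truth[cid]
            row["foot_strike_error_ms"] = ev.foot_strike_time_ms - tr.foot_strike_time_ms
            row["toe_off_error_ms"] = ev.toe_off_time_ms - tr.toe_off_time_ms
            row["contact_time_error_ms"] = ev.contact_time_ms - tr.contact_time_ms
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> dict[str, StepEvents]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["cycle"])] = StepEvents(
            foot_strike_index=int(row["foot_strike_frame"]),
            toe_off_index=int(row["toe_off_frame"]),
            rate=float(row["rate_hz"]),
        )
    return out


def load_config(path) -> dict:
    """Flat key-value YAML configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
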