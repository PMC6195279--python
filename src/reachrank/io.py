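"""Readers and writers for the pipeline's file artifacts.

All artifacts are plain text: RFC-4180 CSV for tables, a JSON sidecar for
per-trial geometry and for feature-table schemas. Writers and readers
round-trip losslessly (full float repr); readers validate schemas and
name the offending column in their error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FIRST_ORDER_COLUMNS
from .kinematics import METRIC_NAMES, Trajectory
from .simulate import COVARIATE_COLUMNS

TRAJECTORY_COLUMNS = ("t", "x", "y", "z")
COHORT_COLUMNS = ("subject_id",) + COVARIATE_COLUMNS + ("treatment",)
TRIAL_METRIC_COLUMNS = ("subject_id", "trial_index") + METRIC_NAMES


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} {path}: missing required column(s) {missing}")


def write_trajectory(traj: Trajectory, directory: str | Path) -> Path:
    """Write one trial as ``<subject>_<trial>.csv`` (header ``t,x,y,z``,
    SI units) plus a geometry sidecar ``<stem>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{traj.subject_id}_t{traj.trial_index:03d}"
    csv_path = directory / f"{stem}.csv"
    pd.DataFrame(
        {"t": traj.times, "x": traj.positions[:, 0],
         "y": traj.positions[:, 1], "z": traj.positions[:, 2]}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "subject_id": traj.subject_id,
        "trial_index": traj.trial_index,
        "home": [float(v) for v in traj.home],
        "target": [float(v) for v in traj.target],
        "cue_time": float(traj.cue_time),
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_trajectory(csv_path: str | Path) -> Trajectory:
    """Read a trial CSV and its geometry sidecar back into a Trajectory."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    _require_columns(df, TRAJECTORY_COLUMNS, "trajectory file", csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"trajectory file {csv_path}: sidecar {sidecar_path} missing")
    meta = json.loads(sidecar_path.read_text())
    times = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise SchemaError(f"trajectory file {csv_path}: column 't' not strictly increasing")
    return Trajectory(
        times=times,
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        home=np.asarray(meta["home"], dtype=float),
        target=np.asarray(meta["target"], dtype=float),
        cue_time=float(meta.get("cue_time", 0.0)),
        subject_id=str(meta["subject_id"]),
        trial_index=int(meta["trial_index"]),
    )


def write_cohort(subjects: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("subject_id",) + COVARIATE_COLUMNS, "cohort file", path)
    return df


def write_trial_metrics(metrics: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trial_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRIAL_METRIC_COLUMNS, "trial-metrics file", path)
    return df


def write_feature_table(
    table: pd.DataFrame, path: str | Path, config_hash: str | None = None
) -> Path:
    """Feature-table CSV plus a JSON schema sidecar recording column
    order, provenance, and the generating config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=True, float_format="%.17g")
    schema = {
        "index": table.index.name or "subject_id",
        "columns": list(table.columns),
        "order": table.attrs.get("order", "first"),
        "provenance": table.attrs.get("provenance", {}),
        "config_hash": config_hash,
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    return path


def read_feature_table(path: str | Path, expect_first_order: bool = False) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    schema_path = path.with_suffix(".schema.json")
    if schema_path.exists():
        schema = json.loads(schema_path.read_text())
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            raise SchemaError(f"feature table {path}: missing column(s) {missing}")
        df.attrs["order"] = schema.get("order", "first")
        df.attrs["provenance"] = schema.get("provenance", {})
    if expect_first_order:
        _require_columns(df, FIRST_ORDER_COLUMNS, "feature table", path)
    return df


def write_outcomes(y: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    y.rename("outcome").to_frame().to_csv(
        path, index=True, index_label="subject_id", float_format="%.17g"
    )
    return path


def read_outcomes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if "outcome" not in df.columns:
        raise SchemaError(f"outcome file {path}: missing required column(s) ['outcome']")
    return df["outcome"]
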