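"""CSV dialects shared by the pipeline stages.

Trajectory files carry ISO-8601 timestamps at 1 Hz; internally all times
are float seconds from the study epoch.  Every artifact a pipeline stage
writes gets a sidecar ``<name>.schema.json`` listing its columns so the
next stage can reject column drift.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

STUDY_EPOCH = pd.Timestamp("2021-06-01 00:00:00")

TRAJECTORY_COLUMNS = ["calf_id", "timestamp", "x_m", "y_m"]
LABEL_COLUMNS = ["calf_id", "start", "stop", "behaviour"]


def _to_iso(seconds):
    idx = STUDY_EPOCH + pd.to_timedelta(np.asarray(seconds, dtype=float), unit="s")
    return idx.strftime("%Y-%m-%dT%H:%M:%S")


def _from_iso(values) -> pd.Series:
    stamps = pd.DatetimeIndex(pd.to_datetime(values))
    return pd.Series((stamps - STUDY_EPOCH).total_seconds(), index=None).to_numpy()


def write_trajectories(frames: list[pd.DataFrame], path: str | Path) -> None:
    """Write trajectories (columns calf_id, t, x_m, y_m) as one CSV."""
    df = pd.concat(frames, ignore_index=True)
    out = pd.DataFrame(
        {
            "calf_id": df["calf_id"],
            "timestamp": _to_iso(df["t"]),
            "x_m": df["x_m"],
            "y_m": df["y_m"],
        }
    )
    out.to_csv(path, index=False)
    write_schema(path, TRAJECTORY_COLUMNS)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    check_columns(df, TRAJECTORY_COLUMNS, str(path))
    df["t"] = _from_iso(df["timestamp"])
    return df[["calf_id", "t", "x_m", "y_m"]]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "calf_id": labels["calf_id"],
            "start": _to_iso(labels["start"]) if len(labels) else [],
            "stop": _to_iso(labels["stop"]) if len(labels) else [],
            "behaviour": labels["behaviour"],
        }
    )
    out.to_csv(path, index=False)
    write_schema(path, LABEL_COLUMNS)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    check_columns(df, LABEL_COLUMNS, str(path))
    if len(df):
        df["start"] = _from_iso(df["start"])
        df["stop"] = _from_iso(df["stop"])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
    write_schema(path, list(df.columns))


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        check_columns(df, required, str(path))
    return df


def write_schema(path: str | Path, columns: list[str]) -> None:
    Path(str(path) + ".schema.json").write_text(
        json.dumps({"columns": columns}, indent=1)
    )


def check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{name} is missing required columns {missing}")
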