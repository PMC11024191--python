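"""Kinematic measures and 3-s window feature extraction.

Three measures are computed from consecutive fixes — speed (Euclidean
displacement over elapsed time), turning angle (angle between successive
displacement vectors, arccos of the normalized dot product, in [0, pi])
and turning-angle speed (speed times the cosine of the turning angle) —
and summarised per non-overlapping 3-s window with mean, standard
deviation, sum, maximum and minimum: 15 features per window.

Windows carry the four positions [t, t+3] inclusive at 1 Hz (boundary
samples are shared between neighbouring windows) giving three speeds and
two turning angles per window.  A window is labelled play when at least
half of it overlaps a play interval; windows with missing samples are
dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import WINDOW_S
from .errors import InputError
from .preprocessing import Trajectory

#: displacements shorter than this (metres) are treated as stationary and
#: contribute a turning angle of 0
DEGENERATE_NORM_EPS = 1e-9

MEASURES = ("speed", "turning_angle", "turning_angle_speed")
STATS = ("mean", "sd", "sum", "max", "min")
FEATURE_COLUMNS = [f"{m}_{s}" for m in MEASURES for s in STATS]

LABEL_PLAY = "play"
LABEL_NON_PLAY = "non_play"


# ---------------------------------------------------------------------------
# elementary measures
# ---------------------------------------------------------------------------

def speed(p0, p1, dt: float) -> float:
    """Euclidean distance between consecutive locations over elapsed time."""
    if dt <= 0:
        raise InputError(f"dt must be > 0, got {dt}")
    return math.hypot(p1[0] - p0[0], p1[1] - p0[1]) / dt


def turning_angle(a, b) -> float:
    """Angle in [0, pi] between successive displacement vectors.

    arccos of the dot product normalized by the vector norms, clamped to
    [-1, 1]; defined as 0 when either displacement is degenerate (norm
    below DEGENERATE_NORM_EPS) so stationary behaviour yields finite
    features.
    """
    na = math.hypot(a[0], a[1])
    nb = math.hypot(b[0], b[1])
    if na < DEGENERATE_NORM_EPS or nb < DEGENERATE_NORM_EPS:
        return 0.0
    c = (a[0] * b[0] + a[1] * b[1]) / (na * nb)
    return math.acos(max(-1.0, min(1.0, c)))


def turning_angle_speed(speed_ms: float, angle_rad: float) -> float:
    """Speed times the cosine of the turning angle (signed, in m/s)."""
    if speed_ms < 0:
        raise InputError("speed must be >= 0")
    if not 0.0 <= angle_rad <= math.pi:
        raise InputError("angle must lie in [0, pi]")
    return speed_ms * math.cos(angle_rad)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class Window:
    """One 3-s analysis window: four 1 Hz positions plus a label."""

    calf_id: str
    start: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: str = "unlabelled"


def _play_overlap(start: float, stop: float, intervals: np.ndarray) -> float:
    """Total seconds of [start, stop) covered by the (merged) intervals."""
    if intervals.size == 0:
        return 0.0
    lo = np.maximum(intervals[:, 0], start)
    hi = np.minimum(intervals[:, 1], stop)
    return float(np.clip(hi - lo, 0.0, None).sum())


def _merged_play_intervals(labels: pd.DataFrame | None, calf_id: str) -> np.ndarray:
    if labels is None or labels.empty:
        return np.empty((0, 2))
    sub = labels[(labels["calf_id"] == calf_id) & (labels["behaviour"] == LABEL_PLAY)]
    if sub.empty:
        return np.empty((0, 2))
    ivals = sub[["start", "stop"]].to_numpy(float)
    ivals = ivals[np.argsort(ivals[:, 0])]
    merged = [ivals[0].copy()]
    for a, b in ivals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append(np.array([a, b]))
    return np.array(merged)


def windowize(
    traj: Trajectory,
    labels: pd.DataFrame | None = None,
    window_s: float = WINDOW_S,
) -> list[Window]:
    """Cut a cleaned trajectory into consecutive non-overlapping windows.

    Window starts lie on the absolute ``window_s`` grid; a window is kept
    only if every expected 1 Hz sample in [start, start + window_s] is
    present.  The label is play iff at least 50% of [start, start +
    window_s) overlaps a labelled play interval.
    """
    step = int(round(window_s))
    play_ivals = _merged_play_intervals(labels, traj.calf_id)
    windows: list[Window] = []
    for seg in traj.segments():
        t = traj.t[seg]
        x = traj.x[seg]
        y = traj.y[seg]
        if len(t) < step + 1:
            continue
        # index samples by integer second offset within the segment grid
        first = int(math.ceil(t[0] / step)) * step
        start = float(first)
        while start + window_s <= t[-1] + 1e-9:
            expect = np.arange(start, start + step + 1)
            idx = np.searchsorted(t, expect)
            ok = bool(idx.max() < len(t)) and np.allclose(
                t[np.clip(idx, 0, len(t) - 1)], expect, atol=1e-6
            )
            if ok:
                overlap = _play_overlap(start, start + window_s, play_ivals)
                label = LABEL_PLAY if overlap >= window_s / 2.0 else LABEL_NON_PLAY
                windows.append(
                    Window(traj.calf_id, start, t[idx], x[idx], y[idx], label)
                )
            start += step
    return windows


def extract_features(window: Window) -> pd.Series:
    """The 15 feature characteristics of one window.

    Speeds come from consecutive position pairs, turning angles from
    consecutive displacement pairs, and the turning-angle speed pairs each
    angle with the speed of its second (outgoing) displacement.  The
    standard deviation is the population (divide-by-n) form and is 0 for a
    single-element set.
    """
    dt = np.diff(window.t)
    if np.any(dt <= 0):
        raise InputError("window timestamps must be strictly increasing")
    dx = np.diff(window.x)
    dy = np.diff(window.y)
    speeds = np.hypot(dx, dy) / dt
    angles = np.array(
        [
            turning_angle((dx[i], dy[i]), (dx[i + 1], dy[i + 1]))
            for i in range(len(dx) - 1)
        ]
    )
    tas = speeds[1:] * np.cos(angles)
    values = {}
    for name, arr in (
        ("speed", speeds),
        ("turning_angle", angles),
        ("turning_angle_speed", tas),
    ):
        values[f"{name}_mean"] = float(np.mean(arr))
        values[f"{name}_sd"] = float(np.std(arr))  # population form
        values[f"{name}_sum"] = float(np.sum(arr))
        values[f"{name}_max"] = float(np.max(arr))
        values[f"{name}_min"] = float(np.min(arr))
    return pd.Series(values, index=FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# vectorized feature table (equivalent to windowize + extract_features)
# ---------------------------------------------------------------------------

def _stats_block(arr: np.ndarray, prefix: str, out: dict) -> None:
    out[f"{prefix}_mean"] = arr.mean(axis=1)
    out[f"{prefix}_sd"] = arr.std(axis=1)
    out[f"{prefix}_sum"] = arr.sum(axis=1)
    out[f"{prefix}_max"] = arr.max(axis=1)
    out[f"{prefix}_min"] = arr.min(axis=1)


def feature_table(
    traj: Trajectory,
    labels: pd.DataFrame | None = None,
    window_s: float = WINDOW_S,
) -> pd.DataFrame:
    """Vectorized windowize + extract_features for a whole trajectory.

    Returns one row per complete window with columns calf_id, window_start,
    label and the 15 feature columns.  Numerically identical (to float
    round-off) to the per-window path; the per-window functions remain the
    reference implementation.
    """
    step = int(round(window_s))
    play_ivals = _merged_play_intervals(labels, traj.calf_id)
    frames = []
    for seg in traj.segments():
        t = traj.t[seg]
        if len(t) < step + 1:
            continue
        t0 = int(math.ceil(t[0] / step)) * step
        t1 = int(math.floor(t[-1]))
        grid = np.arange(t0, t1 + 1, dtype=float)
        if len(grid) < step + 1:
            continue
        # place samples on the 1 Hz grid; NaN marks missing seconds
        gx = np.full(len(grid), np.nan)
        gy = np.full(len(grid), np.nan)
        pos = np.round(t - t0).astype(int)
        on_grid = np.abs(t - t0 - pos) < 1e-6
        inside = on_grid & (pos >= 0) & (pos < len(grid))
        gx[pos[inside]] = traj.x[seg][inside]
        gy[pos[inside]] = traj.y[seg][inside]

        n_win = (len(grid) - 1) // step
        if n_win == 0:
            continue
        # windows of step+1 samples sharing boundary samples
        take = (
            np.arange(n_win)[:, None] * step + np.arange(step + 1)[None, :]
        )
        wx = gx[take]
        wy = gy[take]
        complete = ~np.isnan(wx).any(axis=1) & ~np.isnan(wy).any(axis=1)
        if not complete.any():
            continue
        wx = wx[complete]
        wy = wy[complete]
        starts = t0 + np.flatnonzero(complete) * step

        dx = np.diff(wx, axis=1)
        dy = np.diff(wy, axis=1)
        speeds = np.hypot(dx, dy)  # dt = 1 s on the grid
        na = speeds[:, :-1]
        nb = speeds[:, 1:]
        dot = dx[:, :-1] * dx[:, 1:] + dy[:, :-1] * dy[:, 1:]
        denom = na * nb
        degenerate = (na < DEGENERATE_NORM_EPS) | (nb < DEGENERATE_NORM_EPS)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.clip(dot / np.where(denom > 0, denom, 1.0), -1.0, 1.0)
        angles = np.where(degenerate, 0.0, np.arccos(cosang))
        tas = nb * np.cos(angles)

        cols: dict = {}
        _stats_block(speeds, "speed", cols)
        _stats_block(angles, "turning_angle", cols)
        _stats_block(tas, "turning_angle_speed", cols)

        if play_ivals.size:
            lo = np.maximum(play_ivals[None, :, 0], starts[:, None])
            hi = np.minimum(play_ivals[None, :, 1], (starts + window_s)[:, None])
            overlap = np.clip(hi - lo, 0.0, None).sum(axis=1)
        else:
            overlap = np.zeros(len(starts))
        frame = pd.DataFrame(cols)
        frame.insert(0, "calf_id", traj.calf_id)
        frame.insert(1, "window_start", starts.astype(float))
        frame.insert(
            2,
            "label",
            np.where(overlap >= window_s / 2.0, LABEL_PLAY, LABEL_NON_PLAY),
        )
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["calf_id", "window_start", "label", *FEATURE_COLUMNS]
        )
    return pd.concat(frames, ignore_index=True)[
        ["calf_id", "window_start", "label", *FEATURE_COLUMNS]
    ]
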