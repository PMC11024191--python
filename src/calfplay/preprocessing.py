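"""Cleaning and smoothing of 1 Hz positional data.

The cleaning order is fixed: exclusion intervals -> pen-bounds filter ->
moving-average smoothing.  Smoothing is centered, truncated at segment
edges, and never bridges gaps longer than ``MAX_BRIDGE_GAP_S`` so that
power cuts are not interpolated across.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: gaps longer than this (seconds) split a trajectory into independent
#: segments for smoothing and windowing
MAX_BRIDGE_GAP_S = 2.0

EXCLUSION_REASONS = {"human_interaction", "first_day", "power_cut", "other"}


@dataclass
class Trajectory:
    """One calf's ordered 1 Hz positions inside a pen.

    Timestamps are seconds from the study start; they must be strictly
    increasing but may contain gaps (dropped fixes).
    """

    calf_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pen: tuple[float, float] = (6.0, 10.0)  # (width, length) in metres

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InputError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise InputError("timestamps must be strictly increasing")
        if len(self.t) and not (
            np.isfinite(self.x).all() and np.isfinite(self.y).all()
        ):
            raise InputError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"calf_id": self.calf_id, "t": self.t, "x_m": self.x, "y_m": self.y}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pen=(6.0, 10.0)) -> "Trajectory":
        if df.empty:
            return cls("", np.array([]), np.array([]), np.array([]), pen)
        (calf_id,) = df["calf_id"].unique()
        df = df.sort_values("t")
        return cls(
            str(calf_id),
            df["t"].to_numpy(float),
            df["x_m"].to_numpy(float),
            df["y_m"].to_numpy(float),
            pen,
        )

    def _take(self, mask: np.ndarray) -> "Trajectory":
        return Trajectory(self.calf_id, self.t[mask], self.x[mask], self.y[mask], self.pen)

    def segments(self, max_gap_s: float = MAX_BRIDGE_GAP_S) -> list[slice]:
        """Slices of contiguous samples (no internal gap > max_gap_s)."""
        if len(self.t) == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.t) > max_gap_s) + 1
        bounds = np.concatenate([[0], breaks, [len(self.t)]])
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class ExclusionInterval:
    """A period to drop, for one calf or for all calves (calf_id None)."""

    start: float
    stop: float
    reason: str = "other"
    calf_id: str | None = None

    def __post_init__(self):
        if self.stop <= self.start:
            raise InputError(
                f"exclusion stop ({self.stop}) must exceed start ({self.start})"
            )
        if self.reason not in EXCLUSION_REASONS:
            raise InputError(f"unknown exclusion reason {self.reason!r}")

    def applies_to(self, calf_id: str) -> bool:
        return self.calf_id is None or self.calf_id == calf_id


def remove_excluded_periods(
    traj: Trajectory, exclusions: Iterable[ExclusionInterval]
) -> Trajectory:
    """Drop every sample falling inside an applicable exclusion interval.

    Intervals are half-open [start, stop); ordering is preserved and an
    empty result is allowed.
    """
    keep = np.ones(len(traj), dtype=bool)
    for excl in exclusions:
        if excl.applies_to(traj.calf_id):
            keep &= ~((traj.t >= excl.start) & (traj.t < excl.stop))
    return traj._take(keep)


def filter_pen_bounds(
    traj: Trajectory, pen: tuple[float, float] | None = None
) -> tuple[Trajectory, int]:
    """Drop fixes outside the pen rectangle; return (trajectory, n_removed).

    The pen is axis-aligned with its origin at (0, 0): retained samples
    satisfy 0 <= x <= width and 0 <= y <= length.
    """
    width, length = pen if pen is not None else traj.pen
    inside = (traj.x >= 0) & (traj.x <= width) & (traj.y >= 0) & (traj.y <= length)
    return traj._take(inside), int((~inside).sum())


def smooth_moving_average(traj: Trajectory, window_s: float = 10.0) -> Trajectory:
    """Centered moving-average smoothing of the coordinates.

    Each coordinate is replaced by the mean of the samples whose timestamps
    lie within ``window_s / 2`` of it, truncated at segment edges.  Segments
    separated by gaps longer than ``MAX_BRIDGE_GAP_S`` are smoothed
    independently.  Timestamps are unchanged.
    """
    if window_s < 1:
        raise InputError(f"window_s must be >= 1 s, got {window_s}")
    if len(traj) == 0:
        return traj
    half = window_s / 2.0
    x_out = np.empty_like(traj.x)
    y_out = np.empty_like(traj.y)
    for seg in traj.segments():
        t = traj.t[seg]
        for src, dst in ((traj.x[seg], x_out), (traj.y[seg], y_out)):
            csum = np.concatenate([[0.0], np.cumsum(src)])
            left = np.searchsorted(t, t - half, side="left")
            right = np.searchsorted(t, t + half, side="right")
            dst[seg] = (csum[right] - csum[left]) / (right - left)
    return Trajectory(traj.calf_id, traj.t.copy(), x_out, y_out, traj.pen)


@dataclass
class RetentionReport:
    total_hours: float
    removed_hours: float
    percent_removed: float = field(init=False)
    percent_retained: float = field(init=False)

    def __post_init__(self):
        self.percent_removed = 100.0 * self.removed_hours / self.total_hours
        self.percent_retained = 100.0 - self.percent_removed


def retention_report(total_hours: float, removed_hours: float) -> RetentionReport:
    """Percent of recording hours removed by cleaning and percent retained."""
    if total_hours <= 0:
        raise InputError(f"total_hours must be > 0, got {total_hours}")
    if not 0 <= removed_hours <= total_hours:
        raise InputError("removed_hours must lie in [0, total_hours]")
    return RetentionReport(total_hours, removed_hours)


def align_labels(labels: pd.DataFrame, clock_offset_s: float) -> pd.DataFrame:
    """Shift label intervals by a constant per-recording clock offset.

    A positive offset moves labels later; durations are unchanged.  Used to
    correct timestamp desynchronisation between the video clock and the
    location system.
    """
    out = labels.copy()
    out["start"] = out["start"] + clock_offset_s
    out["stop"] = out["stop"] + clock_offset_s
    return out


def exclusions_from_frame(df: pd.DataFrame) -> list[ExclusionInterval]:
    """Build exclusion intervals from a table with columns
    calf_id (empty/NaN = all calves), start, stop, reason."""
    out = []
    for row in df.itertuples(index=False):
        calf = getattr(row, "calf_id", None)
        if calf is not None and (pd.isna(calf) or calf == ""):
            calf = None
        out.append(
            ExclusionInterval(
                start=float(row.start),
                stop=float(row.stop),
                reason=str(getattr(row, "reason", "other")),
                calf_id=None if calf is None else str(calf),
            )
        )
    return out
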