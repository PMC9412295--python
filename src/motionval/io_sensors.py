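"""Sensor time-series and rater test-log I/O.

Conventions
-----------
* Time is Unix seconds as floats; windows are half-open ``[t0, t1)``.
* Sensor CSVs carry columns ``time,x,y,z`` (header required, comma separated,
  '.' decimal). Accelerometer axes are in units of g, gyroscope axes in rad/s.
* Test-log CSVs carry columns ``subject_id,visit,task,test_id,repeat_no,
  start_time,end_time,steps,distance_m,turns`` with the trailing measure
  fields optional (blank means absent, not zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    RangeError,
    ValidationError,
)

ACCELEROMETER = "accelerometer"
GYROSCOPE = "gyroscope"
_SENSOR_KINDS = (ACCELEROMETER, GYROSCOPE)

#: tolerance used when deciding whether sample spacing is uniform
_UNIFORM_TOL_S = 1e-6


@dataclass(frozen=True)
class TriaxialRecord:
    """One sensor stream: strictly increasing timestamps plus x/y/z axes.

    ``sample_rate_hz`` is the nominal uniform rate; it is ``None`` for
    irregular streams (e.g. raw phone timestamps before resampling).
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sensor_kind: str
    sample_rate_hz: float | None = None

    def __post_init__(self) -> None:
        for name in ("timestamps", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.timestamps.size
        if any(getattr(self, a).size != n for a in ("x", "y", "z")):
            raise ValidationError("timestamps, x, y, z must have equal length")
        if n < 2:
            raise InsufficientDataError("a record needs at least 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if self.sensor_kind not in _SENSOR_KINDS:
            raise ValidationError(f"sensor_kind must be one of {_SENSOR_KINDS}")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def start_time(self) -> float:
        return float(self.timestamps[0])

    @property
    def end_time(self) -> float:
        return float(self.timestamps[-1])

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time

    def as_matrix(self) -> np.ndarray:
        """Samples as an (n, 3) array with columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])

    def slice(self, t0: float, t1: float) -> "TriaxialRecord":
        """Samples with timestamps in the half-open window [t0, t1)."""
        if t1 <= t0:
            raise RangeError("window must satisfy t1 > t0")
        m = (self.timestamps >= t0) & (self.timestamps < t1)
        if int(m.sum()) < 2:
            raise InsufficientDataError(
                f"window [{t0}, {t1}) contains fewer than 2 samples"
            )
        return TriaxialRecord(
            self.timestamps[m], self.x[m], self.y[m], self.z[m],
            self.sensor_kind, self.sample_rate_hz,
        )


@dataclass(frozen=True)
class RaterTestLog:
    """One row of a rater test log: who did what, when, and what was counted."""

    subject_id: str
    visit: int
    task: str
    test_id: str
    repeat_no: int
    start_time: float
    end_time: float
    steps: int | None = None
    distance_m: float | None = None
    turns: int | None = None

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValidationError(
                f"end_time ({self.end_time}) must exceed start_time ({self.start_time})"
            )
        if self.repeat_no < 1:
            raise ValidationError("repeat_no must be >= 1")
        for name in ("steps", "distance_m", "turns"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time


def _infer_rate(timestamps: np.ndarray) -> float | None:
    dt = np.diff(timestamps)
    if dt.size and np.all(np.abs(dt - dt[0]) <= _UNIFORM_TOL_S):
        return 1.0 / float(np.median(dt))
    return None


def read_triaxial_csv(path, sensor_kind: str) -> TriaxialRecord:
    """Read a sensor CSV with columns time,x,y,z.

    Rows are sorted by time; duplicate timestamps keep the first occurrence.
    """
    df = pd.read_csv(path)
    for col in ("time", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"sensor CSV {path} is missing required column '{col}'")
    if len(df) < 2:
        raise InsufficientDataError(f"sensor CSV {path} has fewer than 2 rows")
    df = df.sort_values("time", kind="stable")
    df = df.drop_duplicates(subset="time", keep="first")
    if len(df) < 2:
        raise InsufficientDataError(f"sensor CSV {path} has fewer than 2 distinct times")
    t = df["time"].to_numpy(dtype=float)
    return TriaxialRecord(
        t,
        df["x"].to_numpy(dtype=float),
        df["y"].to_numpy(dtype=float),
        df["z"].to_numpy(dtype=float),
        sensor_kind,
        _infer_rate(t),
    )


def write_triaxial_csv(rec: TriaxialRecord, path) -> None:
    """Write a record back to the time,x,y,z CSV layout (exact float repr)."""
    pd.DataFrame(
        {"time": rec.timestamps, "x": rec.x, "y": rec.y, "z": rec.z}
    ).to_csv(path, index=False)


def resample_uniform(
    rec: TriaxialRecord,
    target_hz: float,
    window: tuple[float, float] | None = None,
) -> TriaxialRecord:
    """Linearly interpolate each axis onto a uniform grid at ``target_hz``.

    Output instants are ``t0 + i/target_hz`` for ``i = 0 .. ceil((t1-t0)*hz)-1``
    (half-open window), so a 10 s window at 30 Hz yields exactly 300 samples.
    """
    if target_hz <= 0:
        raise RangeError("target_hz must be positive")
    t0, t1 = window if window is not None else (rec.start_time, rec.end_time)
    if t1 <= t0:
        raise RangeError("window must satisfy t1 > t0")
    eps = 1e-9
    n = int(math.ceil((t1 - t0) * target_hz - eps))
    # the half-open window needs instants up to t0 + (n-1)/hz only
    if t0 < rec.start_time - eps or t0 + (n - 1) / target_hz > rec.end_time + eps:
        raise RangeError(
            f"window [{t0}, {t1}) outside recording span "
            f"[{rec.start_time}, {rec.end_time}]"
        )
    grid = t0 + np.arange(n) / target_hz
    xyz = [np.interp(grid, rec.timestamps, a) for a in (rec.x, rec.y, rec.z)]
    return TriaxialRecord(grid, *xyz, rec.sensor_kind, float(target_hz))


_LOG_COLUMNS = (
    "subject_id", "visit", "task", "test_id", "repeat_no",
    "start_time", "end_time", "steps", "distance_m", "turns",
)
_LOG_REQUIRED = _LOG_COLUMNS[:7]


def _opt_int(v) -> int | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)


def _opt_float(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def read_test_log_csv(path) -> list[RaterTestLog]:
    """Read a rater test-log CSV; blank optional fields parse as absent."""
    df = pd.read_csv(path)
    for col in _LOG_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"test log {path} is missing required column '{col}'")
    logs: list[RaterTestLog] = []
    for i, row in df.iterrows():
        try:
            logs.append(
                RaterTestLog(
                    subject_id=str(row["subject_id"]),
                    visit=int(row["visit"]),
                    task=str(row["task"]),
                    test_id=str(row["test_id"]),
                    repeat_no=int(row["repeat_no"]),
                    start_time=float(row["start_time"]),
                    end_time=float(row["end_time"]),
                    steps=_opt_int(row.get("steps")),
                    distance_m=_opt_float(row.get("distance_m")),
                    turns=_opt_int(row.get("turns")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"test log {path}, row {i}: {exc}") from exc
    return logs


def write_test_log_csv(logs: Iterable[RaterTestLog], path) -> None:
    rows = [
        {
            "subject_id": lg.subject_id, "visit": lg.visit, "task": lg.task,
            "test_id": lg.test_id, "repeat_no": lg.repeat_no,
            "start_time": lg.start_time, "end_time": lg.end_time,
            "steps": lg.steps, "distance_m": lg.distance_m, "turns": lg.turns,
        }
        for lg in logs
    ]
    pd.DataFrame(rows, columns=list(_LOG_COLUMNS)).to_csv(path, index=False)
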