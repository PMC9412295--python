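"""Pronation/supination turn counting from gyroscope data.

The angular velocity is low-passed, projected onto the dominant rotation axis
(first principal component of the gyro samples), and integrated to a rotation
angle. Turns are alternating maxima/minima of that angle whose successive
change is at least a threshold (60 degrees by default); each adjacent
max/min pair is one turn, i.e. one palm-up <-> palm-down transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateSignalError, InsufficientDataError, ParameterError
from .io_sensors import TriaxialRecord
from .signals import ScalarSeries, lowpass, principal_axes


@dataclass(frozen=True)
class RotationConfig:
    """Tunables for angle integration and turn counting.

    ``rate_denominator`` selects what the rotation rate is divided by: the
    full task duration (a rater timing the whole test) or only the active
    span between the first and last detected extremum.
    """

    cutoff_hz: float = 20.0
    turn_threshold_deg: float = 60.0
    rate_denominator: str = "task_duration"  # or "active_span"

    def __post_init__(self) -> None:
        if self.turn_threshold_deg <= 0:
            raise ParameterError("turn_threshold_deg must be positive")
        if self.rate_denominator not in ("task_duration", "active_span"):
            raise ParameterError("rate_denominator must be task_duration or active_span")


@dataclass(frozen=True)
class TurnMeasures:
    turns: int
    rotation_rate_tps: float
    extrema_times: np.ndarray
    extrema_angles: np.ndarray


def rotation_angle(
    gyro: TriaxialRecord, cfg: RotationConfig = RotationConfig()
) -> ScalarSeries:
    """Rotation angle (radians) about the PCA axis, zero at the window start."""
    if gyro.duration_s < 2.0:
        raise InsufficientDataError("rotation angle needs >= 2 s of gyroscope data")
    filtered = lowpass(gyro, cfg.cutoff_hz)
    frame = principal_axes(filtered, "rotation", min_duration_s=2.0)
    omega = filtered.as_matrix() @ frame.axis
    angle = cumulative_trapezoid(omega, filtered.timestamps, initial=0.0)
    fs = gyro.sample_rate_hz
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(gyro.timestamps)))
    return ScalarSeries(filtered.timestamps, angle, fs)


def _alternating_extrema(
    t: np.ndarray, a: np.ndarray, threshold_rad: float
) -> tuple[list[float], list[float]]:
    """Alternating extrema of ``a`` whose successive change is >= threshold."""
    times: list[float] = []
    angles: list[float] = []
    imax = imin = 0
    direction = 0  # 0 unknown, -1 looking for min, +1 looking for max
    for i in range(1, len(a)):
        if a[i] > a[imax]:
            imax = i
        if a[i] < a[imin]:
            imin = i
        if direction >= 0 and a[imax] - a[i] >= threshold_rad:
            times.append(float(t[imax]))
            angles.append(float(a[imax]))
            direction = -1
            imin = imax + int(np.argmin(a[imax : i + 1]))
        elif direction <= 0 and a[i] - a[imin] >= threshold_rad:
            times.append(float(t[imin]))
            angles.append(float(a[imin]))
            direction = +1
            imax = imin + int(np.argmax(a[imin : i + 1]))
    return times, angles


def count_turns(
    angle: ScalarSeries, cfg: RotationConfig = RotationConfig()
) -> TurnMeasures:
    """Count turns as adjacent max/min pairs of the rotation angle.

    Only extrema separated by at least ``turn_threshold_deg`` of orientation
    change qualify; an unpaired trailing extremum does not count (pairs only).
    Zero turns is a valid result.
    """
    thr = np.deg2rad(cfg.turn_threshold_deg)
    times, angles = _alternating_extrema(angle.timestamps, angle.values, thr)
    turns = len(times) // 2
    if cfg.rate_denominator == "task_duration":
        denom = angle.duration_s
    else:
        denom = times[-1] - times[0] if len(times) >= 2 else 0.0
    rate = turns / denom if denom > 0 else 0.0
    return TurnMeasures(
        turns=turns,
        rotation_rate_tps=rate,
        extrema_times=np.asarray(times),
        extrema_angles=np.asarray(angles),
    )


def pronation_supination_measures(
    gyro: TriaxialRecord,
    window: tuple[float, float] | None = None,
    cfg: RotationConfig = RotationConfig(),
) -> TurnMeasures:
    """Turn count and rotation rate for a pronation/supination test window.

    A still device (no rotation energy at all) yields zero turns rather than
    an error.
    """
    seg = gyro if window is None else gyro.slice(*window)
    try:
        angle = rotation_angle(seg, cfg)
    except DegenerateSignalError:
        return TurnMeasures(0, 0.0, np.asarray([]), np.asarray([]))
    return count_turns(angle, cfg)
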