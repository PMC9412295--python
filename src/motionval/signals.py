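"""Shared signal primitives for the walk, gait and rotation algorithms.

Everything downstream works on either a uniformly sampled scalar series
(typically the acceleration magnitude, which is invariant to how the device
was worn) or a triaxial record. The primitives here are deliberately plain:
vector magnitude, zero-phase Butterworth low-pass, Hamming windowing, the
biased normalized autocorrelation, local-maximum peak finding, and a PCA
orientation estimate (gravity + walking direction, or axis of rotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    ParameterError,
    RangeError,
    ValidationError,
)
from .io_sensors import TriaxialRecord

_UNIFORM_TOL_S = 1e-6


@dataclass(frozen=True)
class ScalarSeries:
    """A uniformly sampled scalar signal (magnitude, angle, ...)."""

    timestamps: np.ndarray
    values: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.timestamps.size != self.values.size:
            raise ValidationError("timestamps and values must have equal length")
        if self.timestamps.size < 2:
            raise InsufficientDataError("a series needs at least 2 samples")
        dt = np.diff(self.timestamps)
        if np.any(np.abs(dt - 1.0 / self.sample_rate_hz) > _UNIFORM_TOL_S):
            raise ValidationError("series timestamps must be uniform at sample_rate_hz")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def start_time(self) -> float:
        return float(self.timestamps[0])

    @property
    def end_time(self) -> float:
        return float(self.timestamps[-1])

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time

    def slice(self, t0: float, t1: float) -> "ScalarSeries":
        """Samples in the half-open window [t0, t1)."""
        if t1 <= t0:
            raise RangeError("window must satisfy t1 > t0")
        m = (self.timestamps >= t0) & (self.timestamps < t1)
        if int(m.sum()) < 2:
            raise InsufficientDataError("window contains fewer than 2 samples")
        return ScalarSeries(self.timestamps[m], self.values[m], self.sample_rate_hz)


@dataclass(frozen=True)
class OrientationFrame:
    """Device orientation estimate.

    For gait: an orthonormal right-handed (vertical, forward, lateral) triad.
    For rotation: the dominant axis of angular velocity.
    """

    vertical: np.ndarray | None = None
    forward: np.ndarray | None = None
    lateral: np.ndarray | None = None
    axis: np.ndarray | None = None


def _record_rate(rec: TriaxialRecord) -> float:
    if rec.sample_rate_hz is not None:
        return float(rec.sample_rate_hz)
    dt = np.diff(rec.timestamps)
    if np.any(np.abs(dt - dt[0]) > _UNIFORM_TOL_S):
        raise ValidationError("record is not uniformly sampled; resample it first")
    return 1.0 / float(np.median(dt))


def magnitude(rec: TriaxialRecord) -> ScalarSeries:
    """Euclidean magnitude r = sqrt(x^2 + y^2 + z^2) per sample.

    The magnitude is invariant to any fixed device re-orientation, which is
    what makes the downstream cadence analysis wear-position agnostic.
    """
    r = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return ScalarSeries(rec.timestamps, r, _record_rate(rec))


def lowpass(obj, cutoff_hz: float):
    """Zero-phase 4th-order Butterworth low-pass (forward-backward, DC gain 1).

    Accepts a ScalarSeries or a TriaxialRecord (filtered per axis) and returns
    the same type. The cutoff must be below the Nyquist frequency.
    """
    if isinstance(obj, ScalarSeries):
        fs = obj.sample_rate_hz
    elif isinstance(obj, TriaxialRecord):
        fs = _record_rate(obj)
    else:  # pragma: no cover - defensive
        raise TypeError("lowpass expects a ScalarSeries or TriaxialRecord")
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {fs / 2}) for fs = {fs} Hz"
        )
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    if isinstance(obj, ScalarSeries):
        return ScalarSeries(obj.timestamps, sps.sosfiltfilt(sos, obj.values), fs)
    return TriaxialRecord(
        obj.timestamps,
        sps.sosfiltfilt(sos, obj.x),
        sps.sosfiltfilt(sos, obj.y),
        sps.sosfiltfilt(sos, obj.z),
        obj.sensor_kind,
        obj.sample_rate_hz,
    )


def hamming_window(values: np.ndarray) -> np.ndarray:
    """Multiply by the Hamming taper w[i] = 0.54 - 0.46 cos(2*pi*i/(N-1))."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("hamming_window needs at least 2 samples")
    return values * np.hamming(values.size)


def autocorrelation(values: np.ndarray) -> np.ndarray:
    """Biased, mean-removed autocorrelation normalized so rho[0] = 1.

    rho[k] = sum_i (v_i - vbar)(v_{i+k} - vbar) / sum_i (v_i - vbar)^2 for
    lags 0..N-1. The biased estimator keeps values in [-1, 1] and damps
    spurious long-lag peaks, so height thresholds have a scale-free meaning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise InsufficientDataError("autocorrelation needs at least 8 samples")
    v = v - v.mean()
    denom = float(np.dot(v, v))
    if denom <= 0.0:
        raise DegenerateSignalError("constant input has no autocorrelation")
    c = sps.correlate(v, v, mode="full", method="fft")[v.size - 1:]
    return c / denom


def find_peaks(
    values: np.ndarray,
    min_lag: int = 0,
    min_height: float = -np.inf,
) -> list[tuple[int, float]]:
    """Local maxima strictly greater than both neighbours, as (lag, height).

    Plateaus report their leftmost index. Results are sorted by lag and
    filtered to ``lag >= min_lag`` and ``height >= min_height``.
    """
    v = np.asarray(values, dtype=float)
    peaks: list[tuple[int, float]] = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                if i >= min_lag and v[i] >= min_height:
                    peaks.append((i, float(v[i])))
            i = j + 1
        else:
            i += 1
    return peaks


def _first_pc(second_moment: np.ndarray) -> tuple[np.ndarray, float, float]:
    w, vec = np.linalg.eigh(second_moment)
    return vec[:, -1], float(w[-1]), float(np.trace(second_moment))


def principal_axes(
    rec: TriaxialRecord,
    mode: str,
    min_duration_s: float = 3.0,
) -> OrientationFrame:
    """Estimate device orientation by principal component analysis.

    gait mode
        ``vertical`` is the normalized mean acceleration (gravity dominates
        the mean, not the variance); ``forward`` is the first principal
        component of the gravity-removed signal projected onto the horizontal
        plane; ``lateral = vertical x forward`` closes a right-handed triad.
        Forward's sign is fixed (arbitrarily but deterministically) so that
        its largest-magnitude component is positive.
    rotation mode
        ``axis`` is the first principal component of the mean-retained
        angular-velocity samples, signed so the mean projection is >= 0.
    """
    if rec.duration_s < min_duration_s:
        raise InsufficientDataError(
            f"principal_axes needs >= {min_duration_s} s of data"
        )
    M = rec.as_matrix()
    if mode == "rotation":
        axis, top, total = _first_pc(M.T @ M / len(rec))
        if total <= 1e-12 or top <= 1e-12:
            raise DegenerateSignalError("no rotation energy in gyroscope signal")
        if float(np.mean(M @ axis)) < 0:
            axis = -axis
        return OrientationFrame(axis=axis)
    if mode != "gait":
        raise ParameterError("mode must be 'gait' or 'rotation'")
    g = M.mean(axis=0)
    gn = float(np.linalg.norm(g))
    if gn <= 1e-9:
        raise DegenerateSignalError("mean acceleration is zero; no gravity direction")
    vertical = g / gn
    D = M - g
    D = D - np.outer(D @ vertical, vertical)
    fwd, top, total = _first_pc(D.T @ D / len(rec))
    if total <= 1e-18 or top <= 1e-12 * max(total, 1e-18):
        raise DegenerateSignalError("no horizontal dynamic energy for forward axis")
    fwd = fwd - vertical * float(fwd @ vertical)
    fwd = fwd / np.linalg.norm(fwd)
    if fwd[int(np.argmax(np.abs(fwd)))] < 0:
        fwd = -fwd
    lateral = np.cross(vertical, fwd)
    return OrientationFrame(vertical=vertical, forward=fwd, lateral=lateral)


def resample_series(
    series: ScalarSeries,
    target_hz: float,
    window: tuple[float, float] | None = None,
) -> ScalarSeries:
    """Linear interpolation of a scalar series onto a half-open uniform grid."""
    if target_hz <= 0:
        raise RangeError("target_hz must be positive")
    t0, t1 = window if window is not None else (series.start_time, series.end_time)
    eps = 1e-9
    if t1 <= t0:
        raise RangeError("window must satisfy t1 > t0")
    n = int(np.ceil((t1 - t0) * target_hz - eps))
    if t0 < series.start_time - eps or t0 + (n - 1) / target_hz > series.end_time + eps:
        raise RangeError("window outside series span")
    grid = t0 + np.arange(n) / target_hz
    return ScalarSeries(grid, np.interp(grid, series.timestamps, series.values), float(target_hz))
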