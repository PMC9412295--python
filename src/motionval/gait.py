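"""Gait measures from one walking segment.

Cadence is read off the autocorrelation of the low-passed acceleration
magnitude: the first qualifying peak gives the step period, and the highest
peak near twice that lag gives the stride period (a stride is two steps, so a
left/right asymmetry puts a distinct peak there; for perfectly symmetric gait
the stride period is imputed as exactly twice the step period). Steps follow
from duration / step period. Walking speed uses an amplitude-based step-length
model L = K * (vertical acceleration range per step)^(1/4), with the vertical
axis taken from the PCA orientation estimate; distance = speed * duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InsufficientDataError, NoCadenceError, UndefinedMeasureError
from .io_sensors import RaterTestLog, TriaxialRecord
from .signals import ScalarSeries, autocorrelation, find_peaks, lowpass, magnitude, principal_axes


@dataclass(frozen=True)
class GaitConfig:
    """Tunables for cadence and the step-length model.

    ``step_length_coeff_K`` is in m * g^(-1/4): step length from the fourth
    root of the per-step vertical acceleration range expressed in g.
    """

    cutoff_hz: float = 10.0
    min_cadence_lag_s: float = 0.25
    step_length_coeff_K: float = 0.41
    min_peak_height: float = 0.2
    stride_band: tuple[float, float] = (1.5, 2.5)


class CadenceResult(NamedTuple):
    step_period_s: float
    stride_period_s: float
    stride_autocorr: float
    imputed: bool


@dataclass(frozen=True)
class GaitMeasures:
    duration_s: float
    steps: int
    distance_m: float
    speed_mps: float
    stride_period_s: float
    step_period_s: float
    stride_imputed: bool = False


def cadence_periods(mag: ScalarSeries, cfg: GaitConfig = GaitConfig()) -> CadenceResult:
    """Step and stride periods from autocorrelation peaks.

    The step period is the lag of the first peak at lag >= min_cadence_lag_s
    with height >= min_peak_height. The stride period is the lag of the
    highest peak within stride_band * step period that rises above the step
    peak (a stride-distinct periodicity); absent one, it is imputed as exactly
    twice the step period.
    """
    fs = mag.sample_rate_hz
    # half-open windows: n samples at fs cover n/fs seconds
    if len(mag) / fs < 5.0 - 1e-9:
        raise InsufficientDataError("cadence needs >= 5 s of walking signal")
    filtered = lowpass(mag, cfg.cutoff_hz)
    rho = autocorrelation(filtered.values)
    min_lag = int(np.ceil(cfg.min_cadence_lag_s * fs))
    peaks = find_peaks(rho, min_lag=min_lag, min_height=cfg.min_peak_height)
    if not peaks:
        raise NoCadenceError(
            "no autocorrelation peak qualifies as a step period "
            "(signal too short or not walking)"
        )
    step_lag, step_height = peaks[0]
    step_period = step_lag / fs
    lo, hi = cfg.stride_band
    band = [p for p in peaks if lo * step_lag <= p[0] <= hi * step_lag]
    distinct = [p for p in band if p[1] > step_height]
    if distinct:
        stride_lag, stride_height = max(distinct, key=lambda p: p[1])
        return CadenceResult(step_period, stride_lag / fs, stride_height, False)
    stride_lag = 2 * step_lag
    rho_at = float(rho[stride_lag]) if stride_lag < rho.size else float("nan")
    return CadenceResult(step_period, 2.0 * step_period, rho_at, True)


def mean_step_cycle_range(values: np.ndarray, fs: float, step_period_s: float) -> float:
    """Average peak-to-peak range over consecutive step-period cycles."""
    n_cycle = max(2, int(round(step_period_s * fs)))
    n = (len(values) // n_cycle) * n_cycle
    if n == 0:
        raise InsufficientDataError("signal shorter than one step cycle")
    chunks = np.asarray(values[:n], dtype=float).reshape(-1, n_cycle)
    return float(np.mean(chunks.max(axis=1) - chunks.min(axis=1)))


def gait_measures(
    rec: TriaxialRecord,
    window: tuple[float, float],
    cfg: GaitConfig = GaitConfig(),
) -> GaitMeasures:
    """All gait measures for an accelerometer record over [t0, t1)."""
    t0, t1 = window
    duration = t1 - t0
    if duration < 5.0:
        raise InsufficientDataError("gait window must be at least 5 s")
    seg = rec.slice(t0, t1)
    mag = magnitude(seg)
    cad = cadence_periods(mag, cfg)
    steps = int(round(duration / cad.step_period_s))
    frame = principal_axes(seg, "gait")
    vert = seg.as_matrix() @ frame.vertical
    vert_f = lowpass(
        ScalarSeries(seg.timestamps, vert, mag.sample_rate_hz), cfg.cutoff_hz
    ).values
    h = mean_step_cycle_range(vert_f, mag.sample_rate_hz, cad.step_period_s)
    step_length = cfg.step_length_coeff_K * h ** 0.25
    speed = step_length / cad.step_period_s
    return GaitMeasures(
        duration_s=duration,
        steps=steps,
        distance_m=speed * duration,
        speed_mps=speed,
        stride_period_s=cad.stride_period_s,
        step_period_s=cad.step_period_s,
        stride_imputed=cad.imputed,
    )


def rater_derived_measures(log: RaterTestLog) -> tuple[float, float]:
    """Rater speed and stride period from a test log.

    Speed is rater distance over rater duration; stride period is rater
    duration over half the rater step count (a stride is two steps).
    """
    if not log.steps:
        raise UndefinedMeasureError("rater stride period needs steps > 0")
    if log.distance_m is None:
        raise UndefinedMeasureError("rater speed needs a recorded distance")
    duration = log.duration_s
    return log.distance_m / duration, duration / (log.steps / 2.0)
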