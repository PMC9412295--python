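"""Ground-truthed synthetic IMU signals for every pipeline stage.

The walking model is a two-harmonic sinusoid (a step-frequency component plus
a weaker stride-frequency component from left/right asymmetry) riding on
gravity; it is the minimal structure that gives the autocorrelation-based
algorithms distinct step and stride peaks while keeping ground truth in
closed form. The rotation model is a sinusoidal pronation/supination angle
about a fixed random axis, with optional pauses and cross-axis contamination.
The bench model is the oscillating table: a sinusoidal reference acceleration
and a device channel with bias, noise and an optional idle-mode gate that
freezes output under sustained low motion (emulating wrist-device firmware
that pauses high-frequency recording to save battery). Every generator is
deterministic given its seed and returns its own ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .errors import ParameterError
from .gait import GaitConfig, mean_step_cycle_range
from .io_sensors import ACCELEROMETER, GYROSCOPE, RaterTestLog, TriaxialRecord
from .signals import ScalarSeries

#: fixed phase offset of the stride-frequency component in the vertical axis
_STRIDE_PHASE = math.pi / 6.0


@dataclass(frozen=True)
class WalkScenario:
    """A schedule of rest/walk states with gait and sensor parameters."""

    schedule: tuple[tuple[str, float], ...] = (("rest", 10.0), ("walk", 20.0), ("rest", 10.0))
    step_freq_hz: float = 2.0
    asymmetry: float = 0.2
    dyn_amp_g: float = 0.25
    noise_sd_g: float = 0.02
    orientation: np.ndarray | None = None  # orthonormal 3x3; identity if None
    sample_rate_hz: float = 50.0
    start_time: float = 0.0
    subject_id: str = "synthetic"
    visit: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.2 <= self.step_freq_hz <= 3.0):
            raise ParameterError("step_freq_hz must lie in [1.2, 3.0]")
        if not (0.0 <= self.asymmetry <= 0.5):
            raise ParameterError("asymmetry must lie in [0, 0.5]")
        if any(d <= 0 for _, d in self.schedule):
            raise ParameterError("schedule durations must be positive")
        if any(s not in ("rest", "walk") for s, _ in self.schedule):
            raise ParameterError("schedule states must be 'rest' or 'walk'")


@dataclass(frozen=True)
class RotationScenario:
    """A pronation/supination test: n full angle oscillations in a window."""

    n_turns: int = 14
    turn_amplitude_deg: float = 170.0
    duration_s: float = 20.0
    pauses: tuple[tuple[float, float], ...] = ()
    cross_axis_amp: float = 0.0  # rad/s of orthogonal-axis contamination
    noise_sd: float = 0.01  # rad/s
    sample_rate_hz: float = 100.0
    start_time: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_turns < 0 or self.turn_amplitude_deg < 0:
            raise ParameterError("n_turns and turn_amplitude_deg must be >= 0")


@dataclass(frozen=True)
class SensorModel:
    """Additive device imperfections for the bench simulation."""

    noise_sd_g: float = 0.0
    bias_g: float = 0.0
    idle_threshold_g: float | None = None


@dataclass(frozen=True)
class TableScenario:
    """One bench configuration run: oscillate 10 s, rest, repeat."""

    amplitude_mm: float = 5.0
    frequency_hz: float = 0.5
    test_duration_s: float = 10.0
    inter_test_gap_s: float = 15.0
    repeats: int = 4
    sensor: SensorModel = field(default_factory=SensorModel)
    sample_rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.test_duration_s, self.inter_test_gap_s) <= 0 or self.repeats < 1:
            raise ParameterError("durations must be positive and repeats >= 1")


@dataclass(frozen=True)
class RotationTruth:
    n_turns: int
    rate_task_tps: float
    rate_active_tps: float
    active_time_s: float


def _body_walk_axes(tau: np.ndarray, sc: WalkScenario) -> np.ndarray:
    """Noiseless body-frame walking acceleration at relative times tau (3, n)."""
    f = sc.step_freq_hz
    a = sc.dyn_amp_g
    b = sc.asymmetry * a
    vertical = 1.0 + a * np.sin(2 * np.pi * f * tau) + b * np.sin(
        np.pi * f * tau + _STRIDE_PHASE
    )
    forward = 0.6 * a * np.sin(2 * np.pi * f * tau + np.pi / 3.0)
    lateral = b * np.sin(np.pi * f * tau)
    return np.vstack([forward, lateral, vertical])


def _truth_distance(sc: WalkScenario, duration_s: float, gait_cfg: GaitConfig) -> float:
    """Ground-truth distance via the same step-length model the gait module uses."""
    fs = sc.sample_rate_hz
    tau = np.arange(int(round(duration_s * fs))) / fs
    vertical = _body_walk_axes(tau, sc)[2]
    step_period = 1.0 / sc.step_freq_hz
    h = mean_step_cycle_range(vertical, fs, step_period)
    step_length = gait_cfg.step_length_coeff_K * h ** 0.25
    return step_length * sc.step_freq_hz * duration_s


def generate_walk(
    scenario: WalkScenario, gait_cfg: GaitConfig = GaitConfig()
) -> tuple[TriaxialRecord, list[RaterTestLog]]:
    """Simulate an accelerometer record for a rest/walk schedule.

    Returns the (rotated, noisy) record plus one ground-truth log per walk
    state carrying exact boundaries, steps = round(f_step * duration) and a
    distance defined through the shared step-length model.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs = sc.sample_rate_hz
    total = sum(d for _, d in sc.schedule)
    n = int(round(total * fs))
    tau = np.arange(n) / fs
    t = sc.start_time + tau

    body = np.zeros((3, n))
    body[2] = 1.0  # gravity only while at rest
    logs: list[RaterTestLog] = []
    t_cursor = 0.0
    test_no = 0
    for state, dur in sc.schedule:
        m = (tau >= t_cursor - 1e-12) & (tau < t_cursor + dur - 1e-12)
        if state == "walk":
            body[:, m] = _body_walk_axes(tau[m], sc)
            test_no += 1
            steps = int(round(sc.step_freq_hz * dur))
            logs.append(
                RaterTestLog(
                    subject_id=sc.subject_id,
                    visit=sc.visit,
                    task="walk",
                    test_id=f"walk-{test_no}",
                    repeat_no=test_no,
                    start_time=sc.start_time + t_cursor,
                    end_time=sc.start_time + t_cursor + dur,
                    steps=steps,
                    distance_m=_truth_distance(sc, dur, gait_cfg),
                )
            )
        t_cursor += dur

    R = np.eye(3) if sc.orientation is None else np.asarray(sc.orientation, dtype=float)
    xyz = R @ body + rng.normal(0.0, sc.noise_sd_g, size=(3, n))
    rec = TriaxialRecord(t, xyz[0], xyz[1], xyz[2], ACCELEROMETER, fs)
    return rec, logs


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_rotation(
    scenario: RotationScenario,
) -> tuple[TriaxialRecord, RotationTruth]:
    """Simulate a gyroscope record for a pronation/supination test.

    The rotation angle completes ``n_turns`` full oscillation cycles of
    amplitude ``turn_amplitude_deg`` over the active (non-paused) time, so the
    integrated angle downstream has exactly ``n_turns`` max/min extremum
    pairs. Angular velocity is exact (analytic derivative), aimed along a
    seed-fixed random axis, plus optional cross-axis sinusoid and noise.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs = sc.sample_rate_hz
    n = int(round(sc.duration_s * fs))
    tau = np.arange(n) / fs
    t = sc.start_time + tau

    active = np.ones(n, dtype=bool)
    for p0, p1 in sc.pauses:
        active &= ~((tau >= p0) & (tau < p1))
    active_time = float(active.sum()) / fs
    amp = math.radians(sc.turn_amplitude_deg)
    if sc.n_turns > 0 and active_time > 0:
        rate = np.where(active, 2.0 * np.pi * sc.n_turns / active_time, 0.0)
    else:
        rate = np.zeros(n)
    phase = np.concatenate([[0.0], np.cumsum(rate[:-1]) / fs])
    omega_axis = amp * np.cos(phase) * rate  # d/dt of amp*sin(phase)

    basis = random_rotation_matrix(rng)
    axis, perp = basis[:, 0], basis[:, 1]
    omega = np.outer(axis, omega_axis)
    if sc.cross_axis_amp > 0:
        omega += np.outer(perp, sc.cross_axis_amp * np.sin(2 * np.pi * 0.4 * tau))
    omega += rng.normal(0.0, sc.noise_sd, size=(3, n))
    rec = TriaxialRecord(t, omega[0], omega[1], omega[2], GYROSCOPE, fs)
    truth = RotationTruth(
        n_turns=sc.n_turns,
        rate_task_tps=sc.n_turns / sc.duration_s,
        rate_active_tps=sc.n_turns / active_time if active_time > 0 else 0.0,
        active_time_s=active_time,
    )
    return rec, truth


def _idle_gate(dev: np.ndarray, fs: float, threshold_g: float) -> np.ndarray:
    """Freeze output wherever a trailing 1 s window stays within threshold.

    A sample is gated when every sample of the trailing window deviates from
    the window mean by less than the threshold; gated samples repeat the last
    ungated value.
    """
    win = max(2, int(round(fs)))
    # positive origin shifts the centered filters left: window [i-win+1, i]
    org = (win - 1) // 2
    mu = uniform_filter1d(dev, size=win, origin=org, mode="nearest")
    hi = maximum_filter1d(dev, size=win, origin=org, mode="nearest")
    lo = minimum_filter1d(dev, size=win, origin=org, mode="nearest")
    dev_max = np.maximum(hi - mu, mu - lo)
    gated = dev_max < threshold_g
    gated[:win] = False  # no full trailing window yet
    idx = np.where(~gated, np.arange(dev.size), 0)
    idx = np.maximum.accumulate(idx)
    return dev[idx]


def generate_table_run(
    scenario: TableScenario,
) -> list[tuple[ScalarSeries, ScalarSeries]]:
    """Simulate one bench configuration: (reference, device) per repeat.

    The reference acceleration is (2 pi f)^2 A sin(2 pi f t) / 9860 in g over
    each test; the device adds bias and noise, and — if an idle threshold is
    set — freezes under sustained low motion. Repeats are offset in time by
    the test duration plus the stationary gap.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    fs = sc.sample_rate_hz
    n = int(round(sc.test_duration_s * fs))
    peak = (2.0 * np.pi * sc.frequency_hz) ** 2 * sc.amplitude_mm / 9860.0
    runs: list[tuple[ScalarSeries, ScalarSeries]] = []
    for r in range(sc.repeats):
        t0 = r * (sc.test_duration_s + sc.inter_test_gap_s)
        tau = np.arange(n) / fs
        ref = peak * np.sin(2.0 * np.pi * sc.frequency_hz * tau)
        dev = ref + sc.sensor.bias_g + rng.normal(0.0, sc.sensor.noise_sd_g, size=n)
        if sc.sensor.idle_threshold_g is not None:
            dev = _idle_gate(dev, fs, sc.sensor.idle_threshold_g)
        runs.append(
            (
                ScalarSeries(t0 + tau, ref, fs),
                ScalarSeries(t0 + tau, dev, fs),
            )
        )
    return runs


@dataclass(frozen=True)
class RaterModel:
    """Gaussian rater imprecision; defaults are plausible human precision."""

    sd: float = 0.0
    bias: float = 0.0


def simulate_rater(
    true_value: float,
    rater_model: RaterModel,
    rng: np.random.Generator | int,
    kind: str = "value",
) -> float:
    """Perturb a true value the way a human rater would record it.

    ``kind``: 'count' rounds to a non-negative integer, 'time' to 0.1 s,
    'value' leaves the perturbed value as is.
    """
    if rater_model.sd < 0:
        raise ParameterError("rater sd must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = true_value + rater_model.bias + (
        rng.normal(0.0, rater_model.sd) if rater_model.sd > 0 else 0.0
    )
    if kind == "count":
        return float(max(0, round(obs)))
    if kind == "time":
        return round(obs, 1)
    return float(obs)
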