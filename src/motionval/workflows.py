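"""End-to-end workflows: bench verification and rater validation.

``run_verification`` simulates a grid of oscillating-table configurations,
resamples reference and device channels to a common 30 Hz grid, computes the
per-test agreement ICC and summarizes the percentage of good-or-excellent
agreement — overall and stratified around the idle-mode threshold when one is
set. ``run_validation`` aligns algorithm output with rater test logs and
assembles the agreement report (ICC for task-based tests, error statistics
for passively detected walking bouts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    ShakeConfig,
    agreement_report,
    categorize_icc,
    timeseries_agreement_icc,
)
from .errors import MotionValError, NoCadenceError
from .gait import GaitConfig, gait_measures, rater_derived_measures
from .io_sensors import RaterTestLog, TriaxialRecord
from .rotation import RotationConfig, pronation_supination_measures
from .signals import resample_series
from .synthetic import SensorModel, TableScenario, generate_table_run
from .walk import WalkDetectionConfig, WalkingPeriod, detect_walking_periods

COMMON_RATE_HZ = 30.0


@dataclass(frozen=True)
class VerificationResult:
    rows: pd.DataFrame  # one row per configuration x repeat
    summary: dict


def run_verification(
    grid: Sequence[ShakeConfig],
    sensor: SensorModel = SensorModel(),
    repeats: int = 4,
    seed: int = 0,
    target_hz: float = COMMON_RATE_HZ,
) -> VerificationResult:
    """Simulate a bench grid and score per-test device agreement.

    Each configuration is oscillated for 10 s and repeated; both channels are
    resampled to the common grid (300 samples per 10 s test at 30 Hz) before
    the time-series ICC. The summary reports the percentage of ICC > 0.75,
    stratified by nominal peak above/below the idle threshold when the sensor
    model gates on one.
    """
    if not grid:
        raise MotionValError("verification grid must be non-empty")
    rows = []
    for i, cfg in enumerate(grid):
        scenario = TableScenario(
            amplitude_mm=cfg.amplitude_mm,
            frequency_hz=cfg.frequency_hz,
            repeats=repeats,
            sensor=sensor,
            seed=seed + i,
        )
        for rep, (ref, dev) in enumerate(generate_table_run(scenario), start=1):
            window = (ref.start_time, ref.start_time + scenario.test_duration_s)
            ref30 = resample_series(ref, target_hz, window)
            dev30 = resample_series(dev, target_hz, window)
            res = timeseries_agreement_icc(dev30, ref30)
            rows.append(
                dict(
                    amplitude_mm=cfg.amplitude_mm,
                    frequency_hz=cfg.frequency_hz,
                    nominal_peak_g=cfg.nominal_peak_g,
                    repeat=rep,
                    n=res.n_subjects,
                    icc=res.icc,
                    category=res.category,
                )
            )
    df = pd.DataFrame(rows)
    good = df["icc"] > 0.75
    summary = {
        "n_tests": int(len(df)),
        "pct_icc_gt_075": float(100.0 * good.mean()),
        "min_nominal_peak_g": float(df["nominal_peak_g"].min()),
        "max_nominal_peak_g": float(df["nominal_peak_g"].max()),
    }
    if sensor.idle_threshold_g is not None:
        above = df["nominal_peak_g"] >= sensor.idle_threshold_g
        summary["idle_threshold_g"] = sensor.idle_threshold_g
        summary["pct_icc_gt_075_above_idle"] = (
            float(100.0 * good[above].mean()) if above.any() else float("nan")
        )
        summary["pct_icc_gt_075_below_idle"] = (
            float(100.0 * good[~above].mean()) if (~above).any() else float("nan")
        )
    return VerificationResult(rows=df, summary=summary)


def match_periods_to_logs(
    periods: Sequence[WalkingPeriod], logs: Sequence[RaterTestLog]
) -> tuple[list[tuple[RaterTestLog, WalkingPeriod]], list[RaterTestLog], list[WalkingPeriod]]:
    """Greedy maximal-overlap matching of detected bouts to logged walks.

    Returns (matches, unmatched logs a.k.a. misses, unmatched bouts a.k.a.
    false positives). Ties go to the earlier bout.
    """
    free = list(periods)
    matches: list[tuple[RaterTestLog, WalkingPeriod]] = []
    misses: list[RaterTestLog] = []
    for lg in sorted(logs, key=lambda g: g.start_time):
        best = None
        best_ov = 0.0
        for p in free:
            ov = max(0.0, min(lg.end_time, p.end_time) - max(lg.start_time, p.start_time))
            if ov > best_ov:
                best, best_ov = p, ov
        if best is None:
            misses.append(lg)
        else:
            matches.append((lg, best))
            free.remove(best)
    return matches, misses, free


@dataclass(frozen=True)
class ValidationResult:
    report: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def _walk_pairs(rec, logs, gait_cfg):
    pairs, skipped = [], []
    for lg in logs:
        try:
            gm = gait_measures(rec, (lg.start_time, lg.end_time), gait_cfg)
        except MotionValError as exc:
            skipped.append(f"{lg.test_id} repeat {lg.repeat_no}: {exc}")
            continue
        group = lg.task
        pairs.append((gm.duration_s, lg.duration_s, "duration_s", group))
        if lg.steps is not None:
            pairs.append((float(gm.steps), float(lg.steps), "steps", group))
        if lg.distance_m is not None:
            pairs.append((gm.distance_m, lg.distance_m, "distance_m", group))
        if lg.steps and lg.distance_m is not None:
            speed, stride = rater_derived_measures(lg)
            pairs.append((gm.speed_mps, speed, "speed_mps", group))
            pairs.append((gm.stride_period_s, stride, "stride_period_s", group))
    return pairs, skipped


def _pronation_pairs(rec, logs, rot_cfg):
    pairs, skipped = [], []
    for lg in logs:
        if lg.turns is None:
            skipped.append(f"{lg.test_id} repeat {lg.repeat_no}: no rater turn count")
            continue
        tm = pronation_supination_measures(rec, (lg.start_time, lg.end_time), rot_cfg)
        group = lg.task
        pairs.append((float(tm.turns), float(lg.turns), "turns", group))
        pairs.append(
            (tm.rotation_rate_tps, lg.turns / lg.duration_s, "rotation_rate_tps", group)
        )
    return pairs, skipped


def _passive_pairs(rec, logs, walk_cfg, gait_cfg):
    periods = detect_walking_periods(rec, walk_cfg)
    matches, misses, false_pos = match_periods_to_logs(periods, logs)
    pairs, skipped = [], []
    for lg, p in matches:
        group = lg.task
        pairs.append((p.start_time, lg.start_time, "start_time_s", group))
        pairs.append((p.end_time, lg.end_time, "end_time_s", group))
        pairs.append((p.duration_s, lg.duration_s, "duration_s", group))
        try:
            gm = gait_measures(rec, (p.start_time, p.end_time), gait_cfg)
        except NoCadenceError as exc:
            skipped.append(f"{lg.test_id} repeat {lg.repeat_no}: {exc}")
            continue
        if lg.steps is not None:
            pairs.append((float(gm.steps), float(lg.steps), "steps", group))
            stride_rater = lg.duration_s / (lg.steps / 2.0) if lg.steps else None
            if stride_rater is not None:
                pairs.append((gm.stride_period_s, stride_rater, "stride_period_s", group))
    for lg in misses:
        skipped.append(f"{lg.test_id} repeat {lg.repeat_no}: no detected bout overlaps")
    for p in false_pos:
        skipped.append(f"false positive bout [{p.start_time:.1f}, {p.end_time:.1f}]")
    return pairs, skipped


def run_validation(
    rec: TriaxialRecord,
    logs: Sequence[RaterTestLog],
    task: str,
    walk_cfg: WalkDetectionConfig = WalkDetectionConfig(),
    gait_cfg: GaitConfig = GaitConfig(),
    rot_cfg: RotationConfig = RotationConfig(),
) -> ValidationResult:
    """Compare algorithm output against rater logs for one task.

    ``task`` is 'walk' (gait measures on logged windows, ICC mode),
    'pronation' (turn measures on logged windows, ICC mode) or 'passive'
    (detect bouts, align to logs by overlap, error-statistics mode).
    Unmatched or failing entries are reported as skipped; the run continues.
    """
    if task == "walk":
        pairs, skipped = _walk_pairs(rec, logs, gait_cfg)
        mode = "icc"
    elif task == "pronation":
        pairs, skipped = _pronation_pairs(rec, logs, rot_cfg)
        mode = "icc"
    elif task == "passive":
        pairs, skipped = _passive_pairs(rec, logs, walk_cfg, gait_cfg)
        mode = "error_stats"
    else:
        raise MotionValError("task must be 'walk', 'pronation' or 'passive'")
    if not pairs:
        return ValidationResult(
            report=pd.DataFrame(
                columns=["measure", "group", "n", "k", "statistic", "value", "category"]
            ),
            skipped=skipped,
        )
    return ValidationResult(report=agreement_report(pairs, mode), skipped=skipped)
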