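"""Agreement and precision statistics for verification and validation.

Implements ICC(A,1) — two-way, absolute agreement, single rating — from the
explicit ANOVA sums of squares, the Koo interpretation bands, MAE/RMSE/MAPE
error statistics, large-sample ICC confidence half-widths for repeat-count
planning, the nominal peak acceleration of a sinusoidally oscillating bench,
and report assembly for algorithm-vs-reference comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompleteDesignError,
    InsufficientPairsError,
    ParameterError,
    ShapeError,
    UndefinedICCError,
)
from .signals import ScalarSeries

#: acceleration due to gravity in mm/s^2 used by the bench formula
G_MM_PER_S2 = 9860.0

KOO_CATEGORIES = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int
    category: str


@dataclass(frozen=True)
class ErrorStats:
    mae: float
    rmse: float
    mape_pct: float | None  # None when any reference value is zero


@dataclass(frozen=True)
class PrecisionPlan:
    n_subjects: int
    rho: float
    k_repeats: int
    half_width: float
    feasible: bool

    @property
    def upper(self) -> float:
        return self.rho + self.half_width

    @property
    def lower(self) -> float:
        return self.rho - self.half_width


def categorize_icc(icc: float) -> str:
    """Koo interpretation bands; boundary values fall to the lower category."""
    if icc > 0.9:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc > 0.5:
        return "moderate"
    return "poor"


def icc_absolute_single(data: np.ndarray) -> ICCResult:
    """ICC(A,1): two-way ANOVA, absolute agreement, single rating.

    ``data`` is an n_subjects x k_raters matrix with no missing cells.

    icc = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ShapeError("data must be a 2-D subjects x raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise InsufficientPairsError("need at least 3 subjects and 2 raters")
    if np.any(~np.isfinite(X)):
        raise IncompleteDesignError("agreement matrix has missing cells")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    if ss_total <= 0.0:
        raise UndefinedICCError("zero total variance: ICC undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return ICCResult(
        icc=float(icc),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n_subjects=n,
        k_raters=k,
        category=categorize_icc(float(icc)),
    )


def error_stats(estimates: Sequence[float], reference: Sequence[float]) -> ErrorStats:
    """MAE, RMSE and MAPE of estimates against a reference.

    MAPE is undefined (None) when any reference value is zero — e.g. Unix
    start times, where a percentage of an epoch offset is meaningless.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(reference, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ShapeError("estimates and reference must be 1-D of equal length")
    if e.size < 1:
        raise ShapeError("need at least one pair")
    err = e - r
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = None
    if not np.any(r == 0.0):
        mape = float(100.0 * np.mean(np.abs(err) / np.abs(r)))
    return ErrorStats(mae=mae, rmse=rmse, mape_pct=mape)


def icc_ci_half_width(rho: float, n_subjects: int, k_repeats: int) -> float:
    """Large-sample 95% CI half-width of the ICC estimator.

    half_width = 1.96 * sqrt( 2 (1-rho)^2 (1 + (k-1) rho)^2 / (k (k-1) (n-1)) )
    """
    if not (0.0 < rho < 1.0):
        raise ParameterError("rho must lie in (0, 1)")
    if n_subjects < 2 or k_repeats < 2:
        raise ParameterError("need n_subjects >= 2 and k_repeats >= 2")
    n, k = n_subjects, k_repeats
    var = 2.0 * (1.0 - rho) ** 2 * (1.0 + (k - 1) * rho) ** 2 / (k * (k - 1) * (n - 1))
    return 1.96 * math.sqrt(var)


def required_repeats(rho: float, n_subjects: int, k_max: int = 12) -> PrecisionPlan:
    """Smallest repeat count k meeting both CI precision criteria.

    Criteria: rho + half_width <= 1 and rho - half_width >= 0.75. When no
    k <= k_max satisfies both, the plan is returned infeasible at k_max.
    """
    for k in range(2, k_max + 1):
        hw = icc_ci_half_width(rho, n_subjects, k)
        if rho + hw <= 1.0 and rho - hw >= 0.75:
            return PrecisionPlan(n_subjects, rho, k, hw, True)
    hw = icc_ci_half_width(rho, n_subjects, k_max)
    return PrecisionPlan(n_subjects, rho, k_max, hw, False)


def nominal_peak_acceleration(amplitude_mm: float, frequency_hz: float) -> float:
    """Peak acceleration, in g, of the displacement A*sin(2*pi*f*t).

    a = (2 pi f)^2 A / g with A in mm and g = 9860 mm/s^2.
    """
    if amplitude_mm < 0 or frequency_hz < 0:
        raise ParameterError("amplitude and frequency must be non-negative")
    return (2.0 * math.pi * frequency_hz) ** 2 * amplitude_mm / G_MM_PER_S2


@dataclass(frozen=True)
class ShakeConfig:
    """One bench configuration; the nominal peak is derived, not stored."""

    amplitude_mm: float
    frequency_hz: float

    @property
    def nominal_peak_g(self) -> float:
        return nominal_peak_acceleration(self.amplitude_mm, self.frequency_hz)


def agreement_report(
    paired_measures: Iterable[tuple[float, float, str, str]],
    mode: str,
) -> pd.DataFrame:
    """Assemble a per-measure agreement table.

    ``paired_measures`` yields (algorithm_value, reference_value, measure_name,
    grouping). In ``icc`` mode each (measure, group) cell becomes one ICC row
    treating reference and algorithm as k = 2 raters; in ``error_stats`` mode
    it becomes one row per error statistic. A degenerate cell (zero total
    variance) is reported with category 'degenerate' rather than dropped.

    Columns: measure, group, n, k, statistic, value, category.
    """
    if mode not in ("icc", "error_stats"):
        raise ParameterError("mode must be 'icc' or 'error_stats'")
    df = pd.DataFrame(
        list(paired_measures), columns=["algorithm", "reference", "measure", "group"]
    )
    rows: list[dict] = []
    for (measure, group), sub in df.groupby(["measure", "group"], sort=True):
        alg = sub["algorithm"].to_numpy(dtype=float)
        ref = sub["reference"].to_numpy(dtype=float)
        if mode == "icc":
            if len(sub) < 3:
                raise InsufficientPairsError(
                    f"measure '{measure}' has only {len(sub)} pairs; ICC needs >= 3"
                )
            try:
                res = icc_absolute_single(np.column_stack([ref, alg]))
                value, category = res.icc, res.category
            except UndefinedICCError:
                value, category = float("nan"), "degenerate"
            rows.append(
                dict(measure=measure, group=group, n=len(sub), k=2,
                     statistic="icc", value=value, category=category)
            )
        else:
            st = error_stats(alg, ref)
            for name, value in (
                ("mae", st.mae),
                ("rmse", st.rmse),
                ("mape_pct", st.mape_pct if st.mape_pct is not None else float("nan")),
            ):
                rows.append(
                    dict(measure=measure, group=group, n=len(sub), k=2,
                         statistic=name, value=value, category="")
                )
    return pd.DataFrame(
        rows, columns=["measure", "group", "n", "k", "statistic", "value", "category"]
    )


def timeseries_agreement_icc(
    device: ScalarSeries,
    reference: ScalarSeries,
    max_lag_s: float = 1.0,
) -> ICCResult:
    """ICC between a device series and a gold-standard reference series.

    Both series must share one uniform rate (e.g. the common 30 Hz grid over
    a 10 s bench test, 300 samples). The device is first aligned to the
    reference by the cross-correlation lag within +-max_lag_s, then the ICC
    treats samples as subjects and the two series as k = 2 raters.
    """
    if abs(device.sample_rate_hz - reference.sample_rate_hz) > 1e-9:
        raise ShapeError("device and reference must share a sample rate")
    d = device.values
    r = reference.values
    if d.size != r.size:
        raise ShapeError("device and reference must have equal length")
    fs = reference.sample_rate_hz
    max_lag = int(round(max_lag_s * fs))
    best_lag = 0
    if d.std() > 0 and r.std() > 0:
        best_corr = -np.inf
        # visit small shifts first so periodic signals tie-break to lag 0
        for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
            if lag >= 0:
                a, b = d[lag:], r[: r.size - lag]
            else:
                a, b = d[: d.size + lag], r[-lag:]
            if a.size < 3 or a.std() == 0 or b.std() == 0:
                continue
            c = float(np.corrcoef(a, b)[0, 1])
            if c > best_corr + 1e-12:
                best_corr, best_lag = c, lag
    if best_lag >= 0:
        a, b = d[best_lag:], r[: r.size - best_lag]
    else:
        a, b = d[: d.size + best_lag], r[-best_lag:]
    return icc_absolute_single(np.column_stack([a, b]))
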