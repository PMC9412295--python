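import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionval import (
    ScalarSeries,
    ShakeConfig,
    agreement_report,
    categorize_icc,
    error_stats,
    icc_absolute_single,
    icc_ci_half_width,
    nominal_peak_acceleration,
    required_repeats,
    timeseries_agreement_icc,
)
from motionval.errors import (
    IncompleteDesignError,
    InsufficientPairsError,
    ParameterError,
    ShapeError,
    UndefinedICCError,
)


class TestICCAbsoluteSingle:
    def test_perfect_agreement(self):
        assert icc_absolute_single([[1, 1], [2, 2], [3, 3]]).icc == pytest.approx(1.0)

    def test_constant_offset_hand_anova(self):
        # MSR = 2, MSC = 1.5, MSE = 0 -> icc = 2 / (2 + (2/3)*1.5) = 2/3
        res = icc_absolute_single([[1, 2], [2, 3], [3, 4]])
        assert res.icc == pytest.approx(2 / 3, abs=1e-12)
        assert res.ms_rows == pytest.approx(2.0)
        assert res.ms_cols == pytest.approx(1.5)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_independent_columns_near_zero(self):
        failures = 0
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(200, 2))
            if abs(icc_absolute_single(X).icc) >= 0.2:
                failures += 1
        assert failures == 0

    def test_missing_cells_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.0]])
        with pytest.raises(IncompleteDesignError):
            icc_absolute_single(X)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedICCError):
            icc_absolute_single(np.full((5, 2), 3.0))

    def test_affine_invariance_but_not_column_offsets(self, rng):
        X = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1)) * 2
        base = icc_absolute_single(X).icc
        assert icc_absolute_single(3.5 * X - 2.0).icc == pytest.approx(base, abs=1e-12)
        shifted = X.copy()
        shifted[:, 0] += 5.0
        assert icc_absolute_single(shifted).icc != pytest.approx(base, abs=1e-6)

    def test_matches_independent_oracle_on_random_matrices(self):
        """Sums-of-squares route agrees with pingouin's ICC(A,1) to 1e-9."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "scores": X.ravel(),
                }
            )
            icc_pg = pingouin.intraclass_corr(
                long, targets="targets", raters="raters", ratings="scores"
            )
            ref = float(icc_pg.loc[icc_pg["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_absolute_single(X).icc == pytest.approx(ref, abs=1e-9)


class TestCategorizeICC:
    @pytest.mark.parametrize(
        "icc,cat",
        [(0.95, "excellent"), (0.8, "good"), (0.3, "poor"), (0.6, "moderate"),
         (0.9, "good"), (0.75, "moderate"), (0.5, "poor"), (-0.2, "poor")],
    )
    def test_bands(self, icc, cat):
        assert categorize_icc(icc) == cat


class TestErrorStats:
    def test_identical_arrays_zero_errors(self):
        st_ = error_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (st_.mae, st_.rmse, st_.mape_pct) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        st_ = error_stats([2.0, 4.0], [1.0, 2.0])
        assert st_.mae == pytest.approx(1.5)
        assert st_.rmse == pytest.approx(np.sqrt(2.5))
        assert st_.mape_pct == pytest.approx(100.0)

    def test_zero_reference_makes_mape_undefined(self):
        st_ = error_stats([2.0, 4.0], [0.0, 2.0])
        assert st_.mape_pct is None
        assert st_.mae == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            error_stats([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_rmse_at_least_mae(self, errors):
        ref = np.zeros(len(errors))
        st_ = error_stats(np.asarray(errors), ref)
        assert st_.rmse >= st_.mae - 1e-12


class TestPrecisionPlanning:
    def test_half_width_closed_form(self):
        assert icc_ci_half_width(0.9, 10, 4) == pytest.approx(0.0987, abs=0.0005)

    def test_half_width_vanishes_as_rho_approaches_one(self):
        assert icc_ci_half_width(1 - 1e-9, 10, 4) < 1e-8

    def test_half_width_decreasing_in_n(self):
        widths = [icc_ci_half_width(0.9, n, 4) for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_four_repeats_at_rho_09_n_10(self):
        plan = required_repeats(0.9, 10)
        assert plan.k_repeats == 4 and plan.feasible
        assert plan.upper <= 1.0 and plan.lower >= 0.75

    def test_rho_08_is_infeasible(self):
        plan = required_repeats(0.8, 10)
        assert not plan.feasible

    def test_out_of_range_rho_rejected(self):
        with pytest.raises(ParameterError):
            icc_ci_half_width(1.0, 10, 4)


class TestNominalPeakAcceleration:
    def test_smallest_bench_configuration(self):
        assert round(nominal_peak_acceleration(5.0, 0.5), 3) == 0.005

    def test_zero_amplitude(self):
        assert nominal_peak_acceleration(0.0, 3.0) == 0.0

    def test_sixty_mm_one_hz(self):
        assert round(nominal_peak_acceleration(60.0, 1.0), 3) == 0.240

    def test_shake_config_derives_peak(self):
        cfg = ShakeConfig(5.0, 0.5)
        assert cfg.nominal_peak_g == pytest.approx(
            nominal_peak_acceleration(5.0, 0.5), abs=1e-12
        )


class TestAgreementReport:
    def test_identical_pairs_all_perfect(self):
        pairs = [(v, v, "steps", "walk") for v in (10.0, 20.0, 30.0, 40.0)]
        rep = agreement_report(pairs, "icc")
        assert float(rep["value"].iloc[0]) == pytest.approx(1.0)
        assert list(rep["category"]) == ["excellent"]

    def test_degenerate_measure_is_flagged(self):
        pairs = [(20.0, 20.0, "duration", "walk")] * 4
        rep = agreement_report(pairs, "icc")
        assert rep.loc[0, "category"] == "degenerate"

    def test_error_mode_rows(self):
        pairs = [(2.0, 1.0, "steps", "walk"), (4.0, 2.0, "steps", "walk")]
        rep = agreement_report(pairs, "error_stats")
        by_stat = rep.set_index("statistic")["value"]
        assert by_stat["mae"] == pytest.approx(1.5)
        assert by_stat["rmse"] == pytest.approx(np.sqrt(2.5))
        assert by_stat["mape_pct"] == pytest.approx(100.0)

    def test_too_few_pairs_names_measure(self):
        with pytest.raises(InsufficientPairsError, match="steps"):
            agreement_report([(1.0, 1.0, "steps", "walk")], "icc")


class TestTimeseriesAgreement:
    def _series(self, values, fs=30.0):
        t = np.arange(len(values)) / fs
        return ScalarSeries(t, values, fs)

    def test_self_agreement_is_one(self):
        t = np.arange(300) / 30
        v = 0.5 * np.sin(2 * np.pi * t)
        assert timeseries_agreement_icc(self._series(v), self._series(v)).icc == pytest.approx(1.0)

    def test_one_percent_noise_keeps_icc_above_0999(self):
        t = np.arange(300) / 30
        ref = 0.5 * np.sin(2 * np.pi * t)
        dev = ref + np.random.default_rng(2).normal(0, 0.005, 300)
        assert timeseriesicc(dev, ref) > 0.999

    def test_lag_alignment_recovers_agreement(self):
        t = np.arange(300) / 30
        ref = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        dev = 0.5 * np.sin(2 * np.pi * 1.0 * (t - 0.2))
        assert timeseriesicc(dev, ref) > 0.99

    def test_frozen_device_scores_poor(self):
        t = np.arange(300) / 30
        ref = 0.05 * np.sin(2 * np.pi * 1.0 * t)
        dev = np.full(300, 0.01)
        assert timeseriesicc(dev, ref) < 0.75


def timeseriesicc(dev_values, ref_values, fs=30.0):
    t = np.arange(len(ref_values)) / fs
    return timeseries_agreement_icc(
        ScalarSeries(t, dev_values, fs), ScalarSeries(t, ref_values, fs)
    ).icc
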