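"""Metric definitions, surrogate validation machinery and cohort aggregation."""

import numpy as np
import pytest

from preictal import (
    brier,
    brier_skill,
    cohort_report,
    forecast_ss,
    fpr_per_hour,
    ioc,
    prediction_ss,
    surrogate_bs_test,
    surrogate_ss_test,
    time_in_warning,
)
from preictal.evaluation import (
    PatientReport,
    PredictionMetrics,
    ForecastingMetrics,
    SurrogatePlacementError,
    false_alarms,
    place_surrogate_onsets,
)
from preictal.postprocess import RiskSeries, RiskState


class TestPredictionSS:
    def test_alarm_inside_occurrence_period_counts(self):
        onset = 7200.0
        # alarm 11 min before onset: lead time in (SPH, SPH+SOP] = (10, 40]
        assert prediction_ss(np.array([onset - 660.0]), [onset], 30, 10) == 1.0
        # alarm 5 min before onset falls inside the SPH: not predicted
        assert prediction_ss(np.array([onset - 300.0]), [onset], 30, 10) == 0.0
        assert prediction_ss(np.array([]), [onset], 30, 10) == 0.0
        with pytest.raises(ValueError):
            prediction_ss(np.array([1.0]), [], 30, 10)

    def test_interval_rule_equals_sop_band_membership(self):
        """Exhaustive small-case equivalence of the two SS formulations."""
        rng = np.random.default_rng(0)
        sop, sph = 30.0, 10.0
        for _ in range(200):
            alarm_times = np.sort(rng.uniform(0, 5000, rng.integers(0, 5)))
            onsets = np.sort(rng.uniform(0, 5000, rng.integers(1, 4)))
            via_rule = prediction_ss(alarm_times, onsets, sop, sph)
            hits = [
                np.any(
                    (alarm_times >= o - (sop + sph) * 60)
                    & (alarm_times < o - sph * 60)
                )
                for o in onsets
            ]
            assert via_rule == pytest.approx(np.mean(hits))

    def test_origin_shift_invariance(self):
        alarm_times = np.array([1000.0, 9000.0])
        onsets = np.array([2500.0])
        a = prediction_ss(alarm_times, onsets, 30, 10)
        b = prediction_ss(alarm_times + 1e4, onsets + 1e4, 30, 10)
        assert a == b


class TestFPR:
    def test_worked_example(self):
        # 2 false alarms in 10 interictal hours, 40-min refractory
        v = fpr_per_hour(np.array([100.0, 50000.0]), [1e6], 10.0, 2 / 3, 30, 10)
        assert v == pytest.approx(2 / (10 - 2 * 2 / 3), abs=1e-9)
        assert v == pytest.approx(0.2308, abs=1e-4)

    def test_zero_false_alarms_and_monotonicity(self):
        onset = 5000.0
        true_alarm = np.array([onset - 660.0])
        assert fpr_per_hour(true_alarm, [onset], 10.0, 2 / 3, 30, 10) == 0.0
        fa = np.array([100.0, 200000.0])
        assert fpr_per_hour(fa, [onset], 20.0, 2 / 3, 30, 10) < fpr_per_hour(
            fa, [onset], 10.0, 2 / 3, 30, 10
        )

    def test_non_positive_capacity_rejected(self):
        with pytest.raises(ValueError):
            fpr_per_hour(np.array([1.0]), [1e6], 0.5, 2 / 3, 30, 10)

    def test_false_alarm_identification(self):
        onset = 7200.0
        times = np.array([onset - 660.0, 100.0])
        assert false_alarms(times, [onset], 30, 10).tolist() == [100.0]


class TestForecastMetrics:
    def _risk(self, high_starts, n=12):
        states = np.full(n, RiskState.LOW, dtype=int)
        t = np.arange(n) * 5.0
        states[np.isin(t, high_starts)] = RiskState.HIGH
        return RiskSeries(states=states, window_start=t)

    def test_high_risk_inside_sop_band_counts(self):
        onset = 2400.0
        # SOP band: [onset-2400, onset-600) at SOP=30, SPH=10
        assert forecast_ss(np.array([1000.0]), [onset], 30, 10) == 1.0
        assert forecast_ss(np.array([onset - 300.0]), [onset], 30, 10) == 0.0  # in SPH
        assert forecast_ss(np.array([]), [onset], 30, 10) == 0.0

    def test_time_in_warning_fractions(self):
        assert time_in_warning(self._risk([0.0, 5.0, 10.0])) == 0.25
        assert time_in_warning(self._risk([])) == 0.0
        states = np.full(7, RiskState.HIGH, dtype=int)
        assert time_in_warning(RiskSeries(states, np.arange(7) * 5.0)) == 1.0

    def test_brier_values(self):
        assert brier(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0
        assert brier(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == 1.0
        assert brier(np.array([0.7, 0.3]), np.array([1.0, 0.0])) == pytest.approx(0.09)
        with pytest.raises(ValueError):
            brier(np.zeros(3), np.zeros(4))

    def test_brier_skill_fixed_points(self):
        rng = np.random.default_rng(0)
        obs = (rng.random(400) < 0.2).astype(float)
        bss, bs_ref = brier_skill(obs.copy(), obs, n_surrogates=200, seed=1)
        assert bss == 1.0 and bs_ref > 0
        # constant forecast: permutation-invariant, BS == BS_ref -> BSS == 0
        const = np.full(400, 0.4)
        bss_const, _ = brier_skill(const, obs, n_surrogates=50, seed=2)
        assert bss_const == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            brier_skill(np.zeros(10), np.zeros(10), n_surrogates=10, seed=0)

    def test_bss_null_expectation_is_zero_for_exchangeable_fp(self):
        rng = np.random.default_rng(3)
        obs = (rng.random(300) < 0.3).astype(float)
        vals = [
            brier_skill(rng.random(300), obs, n_surrogates=100, seed=s)[0]
            for s in range(40)
        ]
        assert abs(np.mean(vals)) < 0.01


class TestSurrogatePlacement:
    def test_placements_respect_validity_and_non_overlap(self):
        rng = np.random.default_rng(0)
        n = 2000
        t = np.arange(n) * 5.0
        allowed = np.ones(n, dtype=bool)
        allowed[500:700] = False  # a forbidden stretch (e.g. true preictal)
        pre_s = 1200.0
        w = int(pre_s / 5.0)
        for _ in range(20):
            onsets = place_surrogate_onsets(rng, t, allowed, 3, pre_s)
            assert np.all(np.diff(onsets) >= pre_s)
            for o in onsets:
                i = int(round(o / 5.0))
                assert allowed[i - w : i].all()

    def test_placement_error_when_no_room(self):
        rng = np.random.default_rng(0)
        t = np.arange(50) * 5.0
        with pytest.raises(SurrogatePlacementError):
            place_surrogate_onsets(rng, t, np.zeros(50, dtype=bool), 1, 600.0)


class TestSurrogateSSTest:
    def test_empty_alarm_series_never_validates(self):
        t = np.arange(3000) * 5.0
        ok, surr_mean = surrogate_ss_test(
            np.array([]), [10000.0], t, np.ones(3000, dtype=bool), 30, 10,
            mode="prediction", seed=0,
        )
        assert not ok and surr_mean == 0.0

    def test_perfectly_placed_alarm_validates(self):
        t = np.arange(6000) * 5.0  # 30000 s
        onset = 25000.0
        alarm = np.array([onset - 900.0])
        allowed = np.ones(6000, dtype=bool)
        allowed[(t >= onset - 2400) & (t < onset)] = False
        ok, surr_mean = surrogate_ss_test(
            alarm, [onset], t, allowed, 30, 10, mode="prediction", seed=1
        )
        assert ok and surr_mean < 0.5

    def test_forecasting_mode_uses_sop_band(self):
        t = np.arange(6000) * 5.0
        onset = 25000.0
        high = np.array([onset - 1500.0])
        allowed = np.ones(6000, dtype=bool)
        ok, _ = surrogate_ss_test(
            high, [onset], t, allowed, 30, 10, mode="forecasting", seed=2
        )
        assert ok
        with pytest.raises(ValueError):
            surrogate_ss_test(high, [onset], t, allowed, 30, 10, mode="other")


class TestSurrogateBSTest:
    def test_perfect_forecast_validates(self):
        rng = np.random.default_rng(1)
        obs = (rng.random(500) < 0.2).astype(float)
        assert surrogate_bs_test(obs.copy(), obs, n=100, seed=0)

    def test_constant_forecast_never_validates(self):
        obs = np.array([0.0, 1.0] * 100)
        assert not surrogate_bs_test(np.full(200, 0.5), obs, n=50, seed=0)


class TestCohort:
    def _patient(self, ss, validated=False):
        return PatientReport(
            patient_id=f"p{ss}",
            backend="logreg",
            prediction=PredictionMetrics(ss, 0.1, validated, 0.0),
            forecasting=ForecastingMetrics(ss, 0.1, 0.2, 0.0, 0.2, validated, 0.0, validated),
            hyperparameters={"sop_minutes": 30},
            n_test_seizures=1,
            seed=0,
        )

    def test_ioc_fractions(self):
        assert ioc([True] * 5 + [False] * 35) == 0.125
        assert ioc([True, True]) == 1.0
        assert ioc([False]) == 0.0
        with pytest.raises(ValueError):
            ioc([])

    def test_single_patient_and_two_patient_sd(self):
        r = cohort_report([self._patient(0.4)])
        assert r.means["prediction.ss"] == 0.4 and r.sds["prediction.ss"] == 0.0
        r2 = cohort_report([self._patient(0.2), self._patient(0.4, validated=True)])
        assert r2.means["prediction.ss"] == pytest.approx(0.3)
        assert r2.sds["prediction.ss"] == pytest.approx(0.1414, abs=1e-4)  # n-1 sd
        assert r2.ioc_prediction_ss == 0.5
        assert "IoC" in r2.to_markdown()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_report([])
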