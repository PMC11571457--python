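import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wprime_kinetics.cp_estimation import (
    detect_get_vslope,
    fit_cp_linear,
    predict_tt_power,
    predicted_hrmax,
    rolling_peak_mean,
    vo2max_criteria,
)
from wprime_kinetics.datamodel import (
    CPFit,
    PhysioTimeSeries,
    TimeTrialResult,
    ValidationError,
)


def _trials(cp, w_prime, durations):
    return [TimeTrialResult(duration=d, mean_power=w_prime / d + cp)
            for d in durations]


class TestFitCpLinear:
    def test_noiseless_model_inversion(self):
        fit = fit_cp_linear(_trials(274.0, 14800.0, [180, 420, 720]))
        assert fit.cp == pytest.approx(274.0, abs=1e-9)
        assert fit.w_prime == pytest.approx(14800.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        fit = fit_cp_linear(_trials(250.0, 20000.0, [180, 720]))
        assert fit.cp == pytest.approx(250.0)
        assert fit.w_prime == pytest.approx(20000.0)
        assert fit.r_squared == 1.0
        assert fit.n_points == 2

    def test_matches_normal_equations_oracle(self):
        durations = np.array([180.0, 420.0, 720.0])
        powers = np.array([360.0, 305.0, 300.0])
        # independent oracle: closed-form simple-regression normal equations
        x = 1.0 / durations
        n = len(x)
        slope = (n * (x * powers).sum() - x.sum() * powers.sum()) / \
                (n * (x * x).sum() - x.sum() ** 2)
        intercept = (powers.sum() - slope * x.sum()) / n
        fit = fit_cp_linear([TimeTrialResult(duration=d, mean_power=p)
                             for d, p in zip(durations, powers)])
        assert fit.cp == pytest.approx(intercept, rel=1e-9)
        assert fit.w_prime == pytest.approx(slope, rel=1e-9)

    def test_order_invariance(self):
        trials = _trials(260.0, 18000.0, [180, 420, 720])
        a = fit_cp_linear(trials)
        b = fit_cp_linear(trials[::-1])
        assert a.cp == pytest.approx(b.cp, rel=1e-12)
        assert a.w_prime == pytest.approx(b.w_prime, rel=1e-12)

    def test_duplicate_durations_singular(self):
        with pytest.raises(ValidationError):
            fit_cp_linear([TimeTrialResult(duration=300, mean_power=300),
                           TimeTrialResult(duration=300, mean_power=310)])

    def test_negative_wprime_warns_but_returns(self):
        # power increasing with duration implies a negative slope
        trials = [TimeTrialResult(duration=180, mean_power=250),
                  TimeTrialResult(duration=720, mean_power=300)]
        with pytest.warns(UserWarning):
            fit = fit_cp_linear(trials)
        assert fit.w_prime < 0

    @settings(deadline=None, derandomize=True)
    @given(cp=st.floats(100, 450), w_prime=st.floats(5_000, 40_000),
           durations=st.lists(st.integers(60, 1800), min_size=2, max_size=6,
                              unique=True))
    def test_property_noiseless_recovery_any_parameters(self, cp, w_prime, durations):
        fit = fit_cp_linear(_trials(cp, w_prime, durations))
        assert fit.cp == pytest.approx(cp, rel=1e-9, abs=1e-6)
        assert fit.w_prime == pytest.approx(w_prime, rel=1e-9)


class TestPredictTtPower:
    def test_direct_evaluation(self):
        fit = CPFit(cp=274.0, w_prime=14800.0, r_squared=1.0, see_cp=0.0, n_points=3)
        assert predict_tt_power(fit, 180) == pytest.approx(356.22, abs=0.01)

    def test_asymptote_is_cp(self):
        fit = CPFit(cp=274.0, w_prime=14800.0, r_squared=1.0, see_cp=0.0, n_points=3)
        assert predict_tt_power(fit, 1e9) == pytest.approx(274.0, abs=1e-4)

    def test_round_trip_fit_on_predictions(self):
        fit = CPFit(cp=310.0, w_prime=12000.0, r_squared=1.0, see_cp=0.0, n_points=3)
        trials = [TimeTrialResult(duration=d, mean_power=predict_tt_power(fit, d))
                  for d in (180, 420, 720)]
        refit = fit_cp_linear(trials)
        assert refit.cp == pytest.approx(fit.cp, rel=1e-12)
        assert refit.w_prime == pytest.approx(fit.w_prime, rel=1e-12)

    def test_strictly_decreasing_in_duration(self):
        fit = CPFit(cp=274.0, w_prime=14800.0, r_squared=1.0, see_cp=0.0, n_points=3)
        powers = [predict_tt_power(fit, d) for d in (60, 180, 420, 720, 1200)]
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_nonpositive_duration_rejected(self):
        fit = CPFit(cp=274.0, w_prime=14800.0, r_squared=1.0, see_cp=0.0, n_points=3)
        with pytest.raises(ValidationError):
            predict_tt_power(fit, 0)


def _physio_from_vo2(vo2, hr=None, vco2=None):
    vo2 = np.asarray(vo2, dtype=float)
    hr = np.full_like(vo2, 150.0) if hr is None else np.asarray(hr, float)
    return PhysioTimeSeries(t=np.arange(vo2.size), vo2=vo2, hr=hr, vco2=vco2)


class TestRollingPeakMean:
    def test_constant_trace(self):
        assert rolling_peak_mean(_physio_from_vo2(np.full(120, 50.0))) == 50.0

    def test_ramp_equals_last_window(self):
        vo2 = np.arange(600) / 10.0
        expected = vo2[-30:].mean()
        assert rolling_peak_mean(_physio_from_vo2(vo2)) == pytest.approx(expected)

    def test_single_spike(self):
        vo2 = np.full(200, 40.0)
        vo2[100] += 30.0
        assert rolling_peak_mean(_physio_from_vo2(vo2)) == pytest.approx(40.0 + 1.0)

    def test_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vo2 = np.abs(rng.normal(45, 8, rng.integers(40, 300)))
            brute = max(vo2[i:i + 30].mean() for i in range(vo2.size - 29))
            assert rolling_peak_mean(_physio_from_vo2(vo2)) == pytest.approx(brute)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            rolling_peak_mean(_physio_from_vo2(np.full(20, 50.0)))


class TestVo2maxCriteria:
    def _series(self, rer_max=1.2, hr_max=180.0):
        vo2 = np.linspace(30, 55, 120)
        vco2 = vo2 * np.linspace(0.9, rer_max, 120)
        hr = np.linspace(120, hr_max, 120)
        return PhysioTimeSeries(t=np.arange(120), vo2=vo2, hr=hr, vco2=vco2)

    def test_two_criteria_give_vo2max(self):
        bins = [(0, 60, 55.0), (60, 120, 55.9)]     # delta 0.9 < 1.5
        d = vo2max_criteria(self._series(rer_max=1.20, hr_max=180.0), bins, age=30)
        # HR 180 is below 95% of 190 = 180.5, so only plateau + RER are met
        assert (d.plateau_met, d.rer_met, d.hr_met) == (True, True, False)
        assert d.criteria_count == 2 and d.classification == "VO2max"

    def test_no_criteria_give_vo2peak(self):
        bins = [(0, 60, 50.0), (60, 120, 52.0)]     # delta 2.0
        d = vo2max_criteria(self._series(rer_max=1.10, hr_max=150.0), bins, age=30)
        assert d.criteria_count == 0 and d.classification == "VO2peak"

    def test_unassessable_criteria_count_as_not_met(self):
        vo2 = np.linspace(30, 55, 120)
        physio = PhysioTimeSeries(t=np.arange(120), vo2=vo2,
                                  hr=np.zeros(120), vco2=None)
        bins = [(0, 60, 54.0), (60, 120, 54.5)]
        with pytest.warns(UserWarning):
            d = vo2max_criteria(physio, bins, age=30)
        assert d.criteria_count == 1 and d.classification == "VO2peak"


class TestPredictedHrmax:
    @pytest.mark.parametrize("age,expected", [(30, 190.0), (20, 200.0),
                                              (31.71, 188.29)])
    def test_values(self, age, expected):
        assert predicted_hrmax(age) == pytest.approx(expected)


class TestDetectGetVslope:
    def _two_segment(self, break_vo2=37.4, s1=0.9, s2=1.3, n=200):
        vo2 = np.linspace(15, 60, n)
        vco2 = np.where(vo2 <= break_vo2,
                        s1 * vo2,
                        s1 * break_vo2 + s2 * (vo2 - break_vo2))
        hr = np.linspace(100, 180, n)
        return PhysioTimeSeries(t=np.arange(n), vo2=vo2, hr=hr, vco2=vco2)

    def test_recovers_constructed_breakpoint(self):
        physio = self._two_segment(break_vo2=37.4)
        got = detect_get_vslope(physio)
        step = (60 - 15) / 199
        assert abs(got - 37.4) <= step + 1e-9

    def test_single_slope_returns_none(self):
        n = 100
        vo2 = np.linspace(15, 60, n)
        physio = PhysioTimeSeries(t=np.arange(n), vo2=vo2,
                                  hr=np.full(n, 150.0), vco2=0.95 * vo2)
        with pytest.warns(UserWarning):
            assert detect_get_vslope(physio) is None

    def test_chosen_breakpoint_minimises_sse(self):
        physio = self._two_segment(break_vo2=40.0)
        got = detect_get_vslope(physio)
        x, y = physio.vo2, physio.vco2

        def sse_at(i):
            r1 = np.polyfit(x[:i], y[:i], 1, full=True)[1]
            r2 = np.polyfit(x[i:], y[i:], 1, full=True)[1]
            return (r1[0] if r1.size else 0.0) + (r2[0] if r2.size else 0.0)

        best_i = int(np.where(x == got)[0][0])
        all_sse = [sse_at(i) for i in range(10, x.size - 10 + 1)]
        assert sse_at(best_i) <= min(all_sse) + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            detect_get_vslope(self._two_segment(n=15))
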