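"""MTY pipeline: plateau detection against a brute-force oracle, stability
screening, internal step calibration and shift-estimate invariances."""

import math

import numpy as np
import pytest

from mitotherm import build_scenario, render_mty_trace
from mitotherm.mty import (MtyThermometry, check_stability, detect_plateau,
                           estimate_temperature_shift, fit_step_calibration,
                           quantify_rewarming, segment_calibration_steps)
from mitotherm.synthgen import MtyProbeModel, mty_protocol
from mitotherm.traces import CALIBRATION_EVENT, FluorescenceTrace


def brute_force_plateau(series, window, slope_tol, dt=1.0):
    """Independent oracle: per-window polyfit slope scan."""
    f = np.asarray(series, dtype=float)
    width = int(round(window / dt))
    t = np.arange(width) * dt
    for i in range(f.size - width + 1):
        slope = np.polyfit(t, f[i:i + width], 1)[0] * 60.0
        if abs(slope) < slope_tol:
            return i * dt
    return None


class TestDetectPlateau:
    def test_constant_series_plateaus_at_first_window(self):
        assert detect_plateau(np.full(600, 5.0), 300.0, 0.1) == 0.0

    def test_steep_ramp_never_plateaus(self):
        tol = 0.1
        series = (10 * tol / 60.0) * np.arange(1200.0)  # slope 10x tolerance
        assert detect_plateau(series, 300.0, tol) is None

    def test_saturating_exponential_matches_brute_force_oracle(self):
        t = np.arange(4000.0)
        series = 1.0 - np.exp(-t / 400.0)
        for tol in (0.5, 0.05, 0.005):
            got = detect_plateau(series, 200.0, tol)
            want = brute_force_plateau(series, 200.0, tol)
            assert got == want

    def test_noisy_series_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(3000.0)
        series = 100.0 * (1.0 - np.exp(-t / 300.0)) + rng.normal(0, 0.5, t.size)
        got = detect_plateau(series, 300.0, 0.1)
        want = brute_force_plateau(series, 300.0, 0.1)
        assert got == want

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_plateau(np.ones(100), 300.0, 0.1)


class TestCheckStability:
    def test_plateauing_trace_is_stable(self, oligomycin_scenario, mty_probe):
        tr = render_mty_trace(oligomycin_scenario, mty_probe, 0.005, seed=1)
        stable, diag = check_stability(tr, "oligomycin")
        assert stable
        assert diag["plateau_onset"] is not None

    def test_monotone_rise_through_long_record_is_unstable(self):
        # S2/oligomycin phenotype: fluorescence still rising 2 h post-drug
        scn = build_scenario("inhibitor", dict(duration=7200.0),
                             protocol=mty_protocol(cal_start=6000.0))
        tr = render_mty_trace(scn, MtyProbeModel(leakage=True), 0.002, seed=9)
        stable, _ = check_stability(tr, "oligomycin")
        assert not stable

    def test_drug_too_close_to_record_end_raises(self, mty_probe):
        scn = build_scenario("inhibitor", dict(drug_time=3570.0),
                             protocol=mty_protocol(cal_start=1200.0))
        tr = render_mty_trace(scn, mty_probe)
        with pytest.raises(ValueError, match="insufficient post-drug record"):
            check_stability(tr, "oligomycin", min_span=600.0)


class TestCalibration:
    def test_zero_noise_step_means_lie_on_generator_line(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        points, warnings = segment_calibration_steps(tr)
        assert warnings == []
        for temp, mean_f in points:
            assert mean_f == pytest.approx(mty_probe.response(temp), abs=1e-6)

    def test_fit_recovers_generator_slope_and_perfect_r2(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        fit = fit_step_calibration(segment_calibration_steps(tr)[0])
        assert fit.slope == pytest.approx(
            -mty_probe.gain * mty_probe.relative_slope, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closely_spaced_steps_warn_but_still_measure(self, mty_probe):
        proto = mty_protocol(37.0, cal_start=2700.0, step_duration=120.0, lag=0.0)
        scn = build_scenario("inhibitor", {}, protocol=proto)
        tr = render_mty_trace(scn, mty_probe)
        points, warnings = segment_calibration_steps(tr, equilibration_discard=30.0)
        assert len(points) == 3
        assert any("minimum interval" in w for w in warnings)

    def test_trace_without_steps_raises(self, mty_probe):
        from mitotherm.synthgen import constant_protocol
        scn = build_scenario("inhibitor", {}, protocol=constant_protocol())
        tr = render_mty_trace(scn, mty_probe)
        with pytest.raises(ValueError, match="calibration-step"):
            segment_calibration_steps(tr)

    def test_two_points_give_interpolating_line(self):
        fit = fit_step_calibration([(34.0, 530.0), (40.0, 470.0)])
        assert fit.slope == pytest.approx(-10.0)
        assert fit.r_squared == 1.0

    def test_identical_temperatures_singular(self):
        with pytest.raises(ValueError, match="singular"):
            fit_step_calibration([(37.0, 500.0), (37.0, 510.0)])

    def test_positive_slope_flagged_suspicious(self):
        fit = fit_step_calibration([(34.0, 470.0), (37.0, 500.0), (40.0, 530.0)])
        assert any("non-negative" in w for w in fit.warnings)


def _toy_trace(f_base=500.0, f_resp=530.0):
    """Minimal trace: baseline, drug, response plateau, two cal steps."""
    times = np.arange(0.0, 1400.0)
    f = np.where(times < 200.0, f_base, f_resp)
    f = np.where(times >= 1000.0, f_resp - 30.0, f)   # +3 °C step: slope −10
    f = np.where(times >= 1200.0, f_resp + 30.0, f)   # −3 °C step
    sp = np.full(times.shape, 37.0)
    sp[(times >= 1000.0) & (times < 1200.0)] = 40.0
    sp[times >= 1200.0] = 34.0
    events = [(200.0, "drug"), (1000.0, CALIBRATION_EVENT),
              (1200.0, CALIBRATION_EVENT)]
    return FluorescenceTrace(times, f[None, :], sp, events)


class TestEstimateShift:
    def test_hand_arithmetic_three_degree_cooling(self):
        tr = _toy_trace(500.0, 530.0)
        fit = fit_step_calibration(segment_calibration_steps(tr)[0])
        assert fit.slope == pytest.approx(-10.0)
        est = estimate_temperature_shift(tr, fit, drug_event="drug")
        assert est.delta_t == pytest.approx(-3.0, abs=1e-9)
        assert est.magnitude == pytest.approx(3.0, abs=1e-9)

    def test_no_response_means_zero_shift(self):
        tr = _toy_trace(500.0, 500.0)
        fit = fit_step_calibration(segment_calibration_steps(tr)[0])
        est = estimate_temperature_shift(tr, fit, drug_event="drug")
        assert est.delta_t == pytest.approx(0.0, abs=1e-12)

    def test_zero_noise_round_trip_recovers_truth_drop(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        res = MtyThermometry(tr).fit()
        assert res.magnitude == pytest.approx(
            exact_oligomycin_scenario.truth_drop, abs=1e-6)
        assert res.delta_t < 0  # cooling is signed negative
        assert res.stable

    def test_gain_invariance(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        base = MtyThermometry(tr).fit()
        scaled = MtyThermometry(tr.scaled(3.7)).fit()
        assert scaled.calibration.slope == pytest.approx(
            3.7 * base.calibration.slope, rel=1e-9)
        assert scaled.delta_t == pytest.approx(base.delta_t, rel=1e-9)

    def test_offset_invariance(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        base = MtyThermometry(tr).fit()
        shifted = MtyThermometry(tr.offset(123.4)).fit()
        assert shifted.delta_t == pytest.approx(base.delta_t, rel=1e-9)

    def test_monotone_in_truth_drop(self, mty_probe):
        mags = []
        for e0 in (6.0, 12.0, 18.0):
            scn = build_scenario("inhibitor", dict(initial_elevation=e0, decay_tau=100.0),
                                 protocol=mty_protocol(37.0, lag=0.0))
            tr = render_mty_trace(scn, mty_probe)
            mags.append(MtyThermometry(tr).fit().magnitude)
        assert mags[0] < mags[1] < mags[2]

    def test_zero_slope_not_identifiable(self):
        tr = _toy_trace()
        from mitotherm.mty import CalibrationFit
        fit = CalibrationFit(slope=0.0, intercept=0.0, r_squared=1.0,
                             temperature_range=(34.0, 40.0), n_points=2)
        with pytest.raises(ValueError, match="identifiable"):
            estimate_temperature_shift(tr, fit, drug_event="drug")


class TestRewarming:
    def test_held_plateau_reports_zero_rewarming(self, exact_oligomycin_scenario, mty_probe):
        tr = render_mty_trace(exact_oligomycin_scenario, mty_probe)
        res = MtyThermometry(tr).fit()
        rw = res.rewarming([20.0, 30.0])
        assert np.allclose(rw, 0.0, atol=0.02)

    def test_full_recovery_bounded_by_initial_drop(self, mty_probe):
        scn = build_scenario("aox_inhibitor", dict(
            drop=10.0, rewarm_tau=600.0, rewarm_delay=300.0))
        tr = render_mty_trace(scn, mty_probe)
        res = MtyThermometry(tr).fit()
        rw = res.rewarming([30.0, 60.0, 85.0])
        assert np.all(np.diff(rw) > 0)
        assert rw[-1] <= 10.0 + 1e-6

    def test_recovered_curve_tracks_scenario_truth(self, mty_probe):
        noise = 0.005
        scn = build_scenario("aox_inhibitor", dict(drop=10.0))
        tr = render_mty_trace(scn, mty_probe, noise, seed=17)
        res = MtyThermometry(tr).fit()
        t_drug = 600.0
        timepoints = [30.0, 45.0, 60.0, 80.0]
        rw = res.rewarming(timepoints)
        elev = scn.elevation(np.array([t_drug + m * 60.0 for m in timepoints]))
        trough = scn.elevation(np.array([t_drug + 900.0]))[0]
        truth = elev - trough
        # 3x the window-averaged noise SD, plus an allowance for the
        # deterministic ~2% slope bias from rewarming drift during the
        # terminal calibration staircase
        sigma = 3.0 * noise * mty_probe.gain / abs(res.calibration.slope) / math.sqrt(60)
        tol = max(sigma, 0.15) + 0.04 * truth
        assert np.all(np.abs(rw - truth) < tol)

    def test_no_post_drug_samples_raises(self, mty_probe):
        tr = _toy_trace()
        fit = fit_step_calibration(segment_calibration_steps(tr)[0])
        with pytest.raises(ValueError):
            quantify_rewarming(tr, fit, "drug", [30.0])
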