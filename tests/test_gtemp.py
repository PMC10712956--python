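"""Ratiometric pipeline: ratio semantics, drug-background QC, in-vivo
calibration, inversion/extrapolation and parameter recovery."""

import numpy as np
import pytest

from mitotherm import build_scenario
from mitotherm.gtemp import (GtempThermometry, RatioCalibration,
                             check_drug_background, compute_ratio,
                             fit_ratio_calibration, infer_temperature_trace,
                             peak_temperature, summarize_interval)
from mitotherm.synthgen import (GtempProbeModel, gtemp_staircase_protocol,
                                render_gtemp_blank, render_gtemp_trace)
from mitotherm.traces import FluorescenceTrace


def _two_channel(f_sap, f_sir, dt=1.0):
    n = len(f_sap)
    times = np.arange(n, dtype=float) * dt
    return FluorescenceTrace(times, np.vstack([f_sap, f_sir]),
                             np.full(n, 37.0))


class TestComputeRatio:
    def test_equal_channels_give_unit_ratio(self):
        tr = _two_channel(np.full(100, 500.0), np.full(100, 500.0))
        ratio = compute_ratio(tr)
        assert np.allclose(ratio.values, 1.0)
        assert ratio.n_masked == 0

    def test_common_gain_cancels(self):
        rng = np.random.default_rng(0)
        sap = 400.0 + rng.normal(0, 10, 200)
        sir = 500.0 + rng.normal(0, 10, 200)
        r1 = compute_ratio(_two_channel(sap, sir)).values
        r2 = compute_ratio(_two_channel(3.0 * sap, 3.0 * sir)).values
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_floor_samples_masked_not_zero_filled(self):
        sir = np.full(1000, 500.0)
        sir[[10, 20, 30]] = 0.1
        ratio = compute_ratio(_two_channel(np.full(1000, 400.0), sir))
        assert ratio.n_masked == 3
        assert np.isnan(ratio.values[[10, 20, 30]]).all()
        assert np.isfinite(ratio.values[50])

    def test_denominator_collapse_raises(self):
        sir = np.full(100, 500.0)
        sir[:20] = 0.0
        with pytest.raises(ValueError, match="denominator collapse"):
            compute_ratio(_two_channel(np.full(100, 400.0), sir))

    def test_single_channel_rejected(self):
        tr = FluorescenceTrace(np.arange(10.0), np.ones((1, 10)), np.full(10, 37.0))
        with pytest.raises(ValueError, match="two-channel"):
            compute_ratio(tr)


class TestDrugBackgroundQC:
    probe = GtempProbeModel(channel_backgrounds=(50.0, 40.0))

    def _blanks(self, shift):
        p = GtempProbeModel(channel_backgrounds=(50.0, 40.0),
                            drug_background_shift=shift)
        with_drug = render_gtemp_blank(p, True, noise_sd=0.002, seed=1)
        without = render_gtemp_blank(p, False, noise_sd=0.002, seed=2)
        return with_drug, without

    def test_rotenone_style_no_change_passes(self):
        ok, diag = check_drug_background(*self._blanks((0.0, 0.0)))
        assert ok

    def test_oligomycin_style_common_shift_ratio_preserved_passes(self):
        # both channels up ~5%, ratio constant
        ok, diag = check_drug_background(*self._blanks((2.5, 2.0)))
        assert ok
        assert diag["channels"]["sirius"]["relative_shift"] > 0.02

    def test_antimycin_style_sirius_shift_fails(self):
        ok, diag = check_drug_background(*self._blanks((0.0, 8.0)))
        assert not ok
        assert diag["ratio_shift"] > 0.02

    def test_unequal_blank_durations_raise(self):
        p = GtempProbeModel(channel_backgrounds=(50.0, 40.0))
        a = render_gtemp_blank(p, True, duration=300.0)
        b = render_gtemp_blank(p, False, duration=200.0)
        with pytest.raises(ValueError, match="equal duration"):
            check_drug_background(a, b)


class TestRatioCalibration:
    def test_zero_noise_staircase_recovers_generator_line(self, exact_gtemp_calibration_trace, gtemp_probe):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        c0, c1 = gtemp_probe.ratio_line()
        assert cal.c1 == pytest.approx(c1, rel=1e-12)
        assert cal.c0 == pytest.approx(c0, rel=1e-12)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_staircase_contributes_five_step_means(self, exact_gtemp_calibration_trace):
        from mitotherm.gtemp import _calibration_points
        points, _ = _calibration_points(exact_gtemp_calibration_trace, 120.0, 60.0, 120.0)
        assert [p[0] for p in points] == [30.0, 33.0, 36.0, 39.0, 42.0]

    def test_forty_minute_record_rejected(self, gtemp_probe):
        scn = build_scenario(
            "baseline", dict(initial_elevation=0.0, duration=2400.0),
            protocol=gtemp_staircase_protocol(start=1500.0, lag=0.0))
        tr = render_gtemp_trace(scn, gtemp_probe)
        with pytest.raises(ValueError, match="photodamage"):
            fit_ratio_calibration(tr)

    def test_replicate_averaging_close_to_pooled_truth(self, gtemp_probe):
        traces = []
        for seed in range(3):
            scn = build_scenario(
                "inhibitor", dict(drug_time=60.0, duration=1800.0),
                protocol=gtemp_staircase_protocol())
            traces.append(render_gtemp_trace(scn, gtemp_probe, 0.01, seed=seed))
        cal = fit_ratio_calibration(traces)
        assert cal.n_replicates == 3
        c0, c1 = gtemp_probe.ratio_line()
        assert cal.c1 == pytest.approx(c1, rel=0.05)


class TestInversion:
    cal = RatioCalibration(c0=0.26, c1=0.02)

    def test_affine_ratio_inverts_identically(self):
        T = np.linspace(25.0, 58.0, 100)
        R = self.cal.predict(T)
        tt = infer_temperature_trace(R, self.cal)
        assert np.allclose(tt.temperatures, T, atol=1e-12)

    def test_extrapolation_mask_semantics(self):
        R = self.cal.predict(np.array([29.0, 35.0, 53.0]))
        tt = infer_temperature_trace(R, self.cal)
        assert tt.extrapolated.tolist() == [True, False, True]

    def test_zero_noise_oligomycin_plateau_reads_cuvette_ambient(self, exact_gtemp_calibration_trace, gtemp_probe):
        from mitotherm.synthgen import constant_protocol
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        scn = build_scenario("inhibitor",
                             dict(drug_time=300.0, decay_tau=60.0, duration=1800.0),
                             protocol=constant_protocol(lag=0.0))
        tr = render_gtemp_trace(scn, gtemp_probe)
        res = GtempThermometry(tr, cal).fit()
        sel = (tr.times >= 1400.0) & (tr.times < 1500.0)
        assert np.allclose(res.temperature_trace.temperatures[sel], 37.0, atol=1e-6)

    def test_zero_slope_not_constructible(self):
        with pytest.raises(ValueError, match="invertible|slope"):
            RatioCalibration(c0=0.26, c1=0.0)


class TestIntervalSummaries:
    def test_constant_trace_mean_sd(self):
        from mitotherm.gtemp import TemperatureTrace
        times = np.arange(0.0, 2100.0)
        tt = TemperatureTrace(times, np.full(times.size, 53.0),
                              np.zeros(times.size, dtype=bool))
        s = summarize_interval(tt, [(11.0, 16.0), (30.0, 35.0)])
        assert s[0]["mean_c"] == pytest.approx(53.0)
        assert s[0]["sd_c"] == pytest.approx(0.0)

    def test_interval_beyond_record_raises(self):
        from mitotherm.gtemp import TemperatureTrace
        times = np.arange(0.0, 600.0)
        tt = TemperatureTrace(times, np.full(times.size, 50.0),
                              np.zeros(times.size, dtype=bool))
        with pytest.raises(ValueError, match="beyond"):
            summarize_interval(tt, [(30.0, 35.0)])

    def test_bka_intervals_match_brute_force_average(self, gtemp_probe, exact_gtemp_calibration_trace):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        scn = build_scenario("bka")
        tr = render_gtemp_trace(scn, gtemp_probe, 0.01, seed=4)
        res = GtempThermometry(tr, cal).fit()
        got = res.interval_summary([(11.0, 16.0), (30.0, 35.0)])
        temp = res.temperature_trace.temperatures
        for (a, b), row in zip(((11.0, 16.0), (30.0, 35.0)), got):
            sel = (tr.times >= a * 60.0) & (tr.times < b * 60.0)
            assert row["mean_c"] == pytest.approx(float(np.mean(temp[sel])), abs=1e-12)
            assert row["sd_c"] == pytest.approx(float(np.std(temp[sel], ddof=1)), abs=1e-12)


class TestRecoveryProperties:
    def test_expression_invariance_of_inferred_temperature(self, exact_gtemp_calibration_trace):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        scn = build_scenario("starvation")
        t_lo = render_gtemp_trace(scn, GtempProbeModel(expression=300.0))
        t_hi = render_gtemp_trace(scn, GtempProbeModel(expression=3000.0))
        a = GtempThermometry(t_lo, cal).fit().temperature_trace.temperatures
        b = GtempThermometry(t_hi, cal).fit().temperature_trace.temperatures
        assert np.allclose(a, b, atol=1e-9)

    def test_calibration_inversion_consistency_on_staircase(self, gtemp_probe):
        # 4-min steps with a 3-min equilibration discard: the 40 s cuvette
        # lag leaves < 0.05 °C residual in every measurement window
        scn = build_scenario(
            "baseline", dict(initial_elevation=0.0, duration=1800.0),
            protocol=gtemp_staircase_protocol(start=600.0, step_duration=240.0))
        tr = render_gtemp_trace(scn, gtemp_probe)
        cal = fit_ratio_calibration(tr, equilibration_discard=180.0)
        res = GtempThermometry(tr, cal).fit()
        for t_step, setpoint in scn.protocol.steps:
            sel = (tr.times >= t_step + 180.0) & (tr.times < t_step + 240.0)
            got = float(np.nanmean(res.temperature_trace.temperatures[sel]))
            assert got == pytest.approx(setpoint, abs=0.05)

    def test_extrapolation_linearity_across_37_to_56(self, exact_gtemp_calibration_trace, gtemp_probe):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        T_true = np.linspace(37.0, 56.0, 200)
        sap, sir = gtemp_probe.channels(T_true)
        ratio = sap / sir
        tt = infer_temperature_trace(ratio, cal)
        assert np.max(np.abs(tt.temperatures - T_true)) < 1e-6

    def test_noisy_elevation_recovery_mae_below_half_degree(self, gtemp_probe, exact_gtemp_calibration_trace):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        errors = []
        from mitotherm.synthgen import constant_protocol
        for seed in range(20):
            scn = build_scenario("inhibitor", dict(duration=2000.0),
                                 protocol=constant_protocol())
            tr = render_gtemp_trace(scn, gtemp_probe, 0.01, seed=seed)
            res = GtempThermometry(tr, cal).fit()
            temp = res.temperature_trace.temperatures
            pre = np.nanmean(temp[(tr.times >= 540.0) & (tr.times < 600.0)])
            post = np.nanmean(temp[(tr.times >= 1800.0) & (tr.times < 1860.0)])
            errors.append(abs((pre - post) - scn.truth_drop))
        assert float(np.mean(errors)) < 0.5

    def test_peak_extraction_uses_smoothing(self, exact_gtemp_calibration_trace, gtemp_probe):
        cal = fit_ratio_calibration(exact_gtemp_calibration_trace)
        scn = build_scenario("starvation")
        tr = render_gtemp_trace(scn, gtemp_probe, 0.01, seed=5)
        res = GtempThermometry(tr, cal).fit()
        raw_max = float(np.nanmax(res.temperature_trace.temperatures))
        smoothed = res.peak((5.0, 15.0))
        assert smoothed < raw_max  # raw argmax carries the noise bias
        times, _, _, tmito = scn.sample()
        assert smoothed == pytest.approx(float(tmito.max()), abs=0.5)
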