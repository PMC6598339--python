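"""Curve model, generation, closed-form parameters and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptt_cwa.curves import (
    ClottingCurve,
    GeneratorPreset,
    WaveformTargets,
    analytic_parameters,
    calibrate_preset,
    generate_curve,
    model_absorbance,
    read_curve,
    read_curves,
    read_preset,
    write_curve,
    write_curves,
    write_preset,
)
from aptt_cwa.errors import CalibrationError, SchemaError, ValidationError

from conftest import random_preset


class TestModelAbsorbance:
    def test_zero_amplitude_is_flat_baseline(self):
        p = GeneratorPreset(amplitude=0.0, center=40.0, slope=4.0, baseline=10.0)
        t = np.linspace(0, 200, 50)
        assert np.allclose(model_absorbance(p, t), 10.0)

    def test_symmetric_sigmoid_midpoint_is_half_amplitude(self, logistic_preset):
        assert model_absorbance(logistic_preset, 40.0) == pytest.approx(200.0)

    def test_biphasic_ramp_direct_evaluation(self):
        # B + c*min(t, t_b) + A/(1 + e^{-(t-m)/s}) at t = 30:
        # 0.5*30 + 400/(1 + e^{2.5})
        p = GeneratorPreset(
            amplitude=400.0, center=40.0, slope=4.0, asymmetry=1.0,
            biphasic_slope=0.5, biphasic_end=30.0,
        )
        expected = 15.0 + 400.0 / (1.0 + math.exp(2.5))
        assert model_absorbance(p, 30.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(45.343, abs=5e-4)

    def test_nondecreasing_when_ramp_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_preset(rng)
            t = np.arange(p.t_start, p.t_end, 0.05)
            y = model_absorbance(p, t)
            assert np.all(np.diff(y) >= -1e-9)

    def test_gompertz_limit_is_continuous(self):
        t = np.linspace(0, 200, 500)
        lo = GeneratorPreset(amplitude=400, center=50, slope=5, asymmetry=-1e-9)
        hi = GeneratorPreset(amplitude=400, center=50, slope=5, asymmetry=1e-9)
        np.testing.assert_allclose(
            model_absorbance(lo, t), model_absorbance(hi, t), atol=1e-5
        )


class TestGenerateCurve:
    def test_noiseless_curve_equals_model(self, logistic_preset):
        c = generate_curve(logistic_preset, seed=3)
        np.testing.assert_allclose(
            c.absorbance, model_absorbance(logistic_preset, c.time)
        )

    def test_deterministic_given_preset_and_seed(self, logistic_preset):
        from dataclasses import replace

        p = replace(logistic_preset, noise_sd=5.0)
        a = generate_curve(p, seed=11)
        b = generate_curve(p, seed=11)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_noise_sd_recovered_from_residuals(self, logistic_preset):
        from dataclasses import replace

        p = replace(logistic_preset, noise_sd=5.0)
        c = generate_curve(p, seed=42)
        resid = c.absorbance - model_absorbance(p, c.time)
        assert len(c.time) == 2001
        assert abs(resid.std() - 5.0) / 5.0 < 0.10

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorPreset(amplitude=400, center=40, slope=-1.0)
        with pytest.raises(ValidationError):
            GeneratorPreset(amplitude=400, center=40, slope=4, asymmetry=-0.6)
        with pytest.raises(ValidationError):
            GeneratorPreset(amplitude=400, center=250, slope=4)  # center past window


class TestAnalyticParameters:
    def test_logistic_closed_forms(self, logistic_preset):
        """For nu=1: 1stDP at m with height A/(4s); 2ndDP1 at
        m - s*ln(2+sqrt(3)) with height A*sqrt(3)/(18 s^2); FWHM of the
        velocity peak 2 s ln(3+2 sqrt(2))."""
        ap = analytic_parameters(logistic_preset)
        assert ap.t_1st == pytest.approx(40.0)
        assert ap.h_1st == pytest.approx(25.0)
        assert ap.t_2nd1 == pytest.approx(40.0 - 4.0 * math.log(2 + math.sqrt(3)), rel=1e-9)
        assert ap.t_2nd1 == pytest.approx(34.73, abs=5e-3)
        assert ap.h_2nd1 == pytest.approx(400.0 * math.sqrt(3) / (18 * 16), rel=1e-9)
        assert ap.h_2nd1 == pytest.approx(2.406, abs=5e-4)
        assert ap.w_1st == pytest.approx(2 * 4.0 * math.log(3 + 2 * math.sqrt(2)), rel=1e-6)
        assert ap.w_1st == pytest.approx(14.10, abs=5e-3)
        assert ap.t_halfff == pytest.approx(40.0)
        assert ap.h_halfff == pytest.approx(200.0)

    def test_logistic_second_derivative_peaks_symmetric_about_center(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = rng.uniform(2, 10)
            m = rng.uniform(40, 100)
            p = GeneratorPreset(amplitude=300, center=m, slope=s, asymmetry=1.0)
            ap = analytic_parameters(p)
            assert (m - ap.t_2nd1) == pytest.approx(ap.t_2nd2 - m, rel=1e-9)
            assert ap.nh_2nd2 == pytest.approx(ap.h_2nd1, rel=1e-9)

    @pytest.mark.parametrize("nu", [3.0, 0.3, -0.3])
    def test_matches_finite_difference_oracle(self, nu):
        """Closed forms agree with brute-force differentiation of the
        model on a fine grid."""
        p = GeneratorPreset(amplitude=500, center=60, slope=6, asymmetry=nu)
        ap = analytic_parameters(p)
        t = np.arange(20.0, 120.0, 1e-3)
        y = model_absorbance(p, t)
        d1 = np.gradient(y, t)
        d2 = np.gradient(d1, t)
        i1 = np.argmax(d1)
        assert t[i1] == pytest.approx(ap.t_1st, rel=1e-3)
        assert d1[i1] == pytest.approx(ap.h_1st, rel=1e-3)
        pre = t < ap.t_1st
        i2 = np.argmax(np.where(pre, d2, -np.inf))
        assert t[i2] == pytest.approx(ap.t_2nd1, rel=1e-3)
        assert d2[i2] == pytest.approx(ap.h_2nd1, rel=1e-3)
        post = t > ap.t_1st
        i3 = np.argmin(np.where(post, d2, np.inf))
        assert t[i3] == pytest.approx(ap.t_2nd2, rel=1e-3)
        assert -d2[i3] == pytest.approx(ap.nh_2nd2, rel=1e-3)
        i_half = np.argmax(y >= 250.0)
        assert t[i_half] == pytest.approx(ap.t_halfff, rel=1e-3)

    def test_peak_ordering_and_logistic_half_time(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = random_preset(rng)
            ap = analytic_parameters(p)
            assert ap.t_2nd1 < ap.t_1st < ap.t_2nd2

    def test_velocity_height_strictly_decreasing_in_slope(self):
        heights = [
            analytic_parameters(
                GeneratorPreset(amplitude=400, center=40, slope=s, asymmetry=1.0)
            ).h_1st
            for s in (2.0, 3.0, 5.0, 8.0)
        ]
        assert all(a > b for a, b in zip(heights, heights[1:]))

    def test_rejects_biphasic_preset(self):
        p = GeneratorPreset(
            amplitude=400, center=40, slope=4, biphasic_slope=0.5, biphasic_end=30
        )
        with pytest.raises(ValidationError):
            analytic_parameters(p)


class TestCalibration:
    def test_round_trip_recovers_parameters(self):
        rng = np.random.default_rng(3)
        done = 0
        while done < 10:
            p = random_preset(rng)
            if p.asymmetry > 0.95:
                continue  # above nu=1 the half-formation time precedes
                # the velocity peak and cannot be expressed as targets
            done += 1
            ap = analytic_parameters(p)
            targets = WaveformTargets(
                t_2nd1=ap.t_2nd1, t_1st=ap.t_1st, t_halfff=ap.t_halfff,
                h_2nd1=ap.h_2nd1, h_1st=ap.h_1st, h_halfff=ap.h_halfff,
            )
            q = calibrate_preset(targets)
            aq = analytic_parameters(q)
            for key in ("t_2nd1", "t_1st", "t_halfff", "h_2nd1", "h_1st", "h_halfff"):
                assert getattr(aq, key) == pytest.approx(getattr(ap, key), rel=0.01)

    def test_published_hv_column_calibrates_within_one_percent(self):
        targets = WaveformTargets(
            t_2nd1=35.5, t_1st=38.7, t_halfff=40.9,
            h_2nd1=457.0, h_1st=183.0, h_halfff=242.0,
        )
        p = calibrate_preset(targets)
        ap = analytic_parameters(p)
        for key, want in targets.provided().items():
            assert getattr(ap, key) == pytest.approx(want, rel=0.01)

    def test_calibration_deterministic(self):
        targets = WaveformTargets(
            t_2nd1=43.9, t_1st=50.2, t_halfff=52.5,
            h_2nd1=648.0, h_1st=389.0, h_halfff=462.0,
        )
        a = calibrate_preset(targets)
        b = calibrate_preset(targets)
        assert a == b

    def test_unordered_peak_times_rejected(self):
        with pytest.raises(ValidationError):
            WaveformTargets(t_2nd1=50.0, t_1st=40.0)

    def test_infeasible_targets_raise_with_diagnostics(self):
        # time ratio beyond the family's reachable asymmetry
        targets = WaveformTargets(t_2nd1=38.0, t_1st=40.0, t_halfff=48.0)
        with pytest.raises(CalibrationError) as exc:
            calibrate_preset(targets)
        assert "relative_residuals" in exc.value.diagnostics


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    s=st.floats(2.0, 10.0),
    m=st.floats(35.0, 90.0),
    amp=st.floats(100.0, 900.0),
)
def test_generated_curves_nondecreasing_property(s, m, amp):
    """Fibrin formation accrues: noiseless curves never decrease."""
    p = GeneratorPreset(amplitude=amp, center=m, slope=s, asymmetry=1.0)
    c = generate_curve(p, seed=0)
    assert np.all(np.diff(c.absorbance) >= -1e-9)


class TestCurveIO:
    def test_single_curve_round_trip(self, tmp_path, logistic_preset):
        c = generate_curve(logistic_preset, seed=1)
        path = tmp_path / "curve.csv"
        write_curve(c, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.absorbance, c.absorbance)
        np.testing.assert_allclose(back.time, c.time)

    def test_long_format_round_trip(self, tmp_path, logistic_preset):
        curves = [generate_curve(logistic_preset, seed=i, sample_id=f"c{i}") for i in range(3)]
        path = tmp_path / "curves.csv"
        write_curves(curves, path)
        back = read_curves(path)
        assert [c.sample_id for c in back] == ["c0", "c1", "c2"]
        np.testing.assert_allclose(back[2].absorbance, curves[2].absorbance)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,signal\n0,1\n0.1,2\n")
        with pytest.raises(SchemaError):
            read_curve(path)

    def test_preset_round_trip(self, tmp_path, logistic_preset):
        path = tmp_path / "preset.yaml"
        write_preset(logistic_preset, path)
        assert read_preset(path) == logistic_preset

    def test_curve_validation(self):
        with pytest.raises(ValidationError):
            ClottingCurve(time=np.array([0.0, 1.0, 1.0]), absorbance=np.zeros(3))
        with pytest.raises(ValidationError):
            ClottingCurve(time=np.array([0.0, 1.0]), absorbance=np.zeros(3))
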