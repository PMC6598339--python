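"""Waveform extraction: differentiation, parameters, biphasic flag."""

from dataclasses import replace

import numpy as np
import pytest

from aptt_cwa.curves import (
    ClottingCurve,
    GeneratorPreset,
    analytic_parameters,
    generate_curve,
)
from aptt_cwa.errors import (
    MalformedCurveError,
    NoCoagulationError,
    ValidationError,
)
from aptt_cwa.extraction import (
    ExtractionSettings,
    detect_biphasic,
    differentiate,
    extract_batch,
    extract_curve,
    extract_parameters,
)

from conftest import random_preset


def _flat_curve(level=100.0, n=2001, dt=0.1):
    t = dt * np.arange(n)
    return ClottingCurve(time=t, absorbance=np.full(n, level), sample_id="flat")


class TestDifferentiate:
    def test_linear_ramp_has_constant_slope(self):
        t = 0.1 * np.arange(500)
        c = ClottingCurve(time=t, absorbance=2.0 * t, window=(0.0, 50.0))
        d = differentiate(c)
        interior = slice(20, -20)
        np.testing.assert_allclose(d.first[interior], 2.0, atol=1e-8)
        np.testing.assert_allclose(d.second[interior], 0.0, atol=1e-6)

    def test_constant_curve_has_zero_derivatives(self):
        d = differentiate(_flat_curve())
        np.testing.assert_allclose(d.first, 0.0, atol=1e-9)
        np.testing.assert_allclose(d.second, 0.0, atol=1e-8)

    def test_logistic_velocity_peak_matches_closed_form(self, logistic_preset):
        # A/(4s) = 25 at fine sampling
        p = replace(logistic_preset, sampling_interval=0.01, t_start=20.0, t_end=60.0)
        c = generate_curve(p, seed=0)
        d = differentiate(c)
        assert d.first.max() == pytest.approx(25.0, abs=0.125)

    def test_too_few_samples_rejected(self):
        t = 0.1 * np.arange(10)
        c = ClottingCurve(time=t, absorbance=np.zeros(10), window=(0.0, 1.0))
        with pytest.raises(ValidationError):
            differentiate(c)


class TestExtractParameters:
    def test_matches_analytic_oracle_on_noiseless_curves(self):
        """Extraction on noiseless sampled sigmoids reproduces the
        continuous-domain parameters: times within 0.5%, heights
        within 1%."""
        rng = np.random.default_rng(10)
        for _ in range(25):
            p = random_preset(rng)
            ap = analytic_parameters(p)
            wp = extract_curve(generate_curve(p, seed=0))
            for key in ("t_2nd1", "t_1st", "t_halfff"):
                assert getattr(wp, key) == pytest.approx(getattr(ap, key), rel=5e-3)
            for key in ("h_1st", "h_2nd1", "nh_2nd2", "h_halfff"):
                want = getattr(ap, key)
                if key in ("h_1st",):
                    want /= p.scale_1st
                elif key in ("h_2nd1", "nh_2nd2"):
                    want /= p.scale_2nd
                assert getattr(wp, key) == pytest.approx(want, rel=1e-2)

    def test_peak_ordering_on_extracted_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = random_preset(rng)
            if p.asymmetry > 1.0:
                continue  # half-formation precedes the velocity peak above nu=1
            wp = extract_curve(generate_curve(p, seed=1))
            assert wp.t_2nd1 < wp.t_1st <= wp.t_halfff + 1e-6

    def test_flat_curve_raises_no_coagulation(self):
        d = differentiate(_flat_curve())
        with pytest.raises(NoCoagulationError):
            extract_parameters(d)

    def test_slow_curve_right_censors_velocity_width(self):
        """A transition so slow that the velocity never falls back to
        half maximum in-window reports the window cap and a censored
        flag."""
        p = GeneratorPreset(amplitude=600.0, center=145.0, slope=50.0, asymmetry=-0.3)
        wp = extract_curve(generate_curve(p, seed=0))
        assert "w_1st" in wp.censored_widths
        assert wp.w_1st == pytest.approx(200.0)

    def test_scale_equivariance(self):
        """Scaling absorbance by lambda scales all heights by lambda
        and leaves times and widths unchanged."""
        p = GeneratorPreset(amplitude=300.0, center=55.0, slope=5.0, asymmetry=0.5)
        c = generate_curve(p, seed=0)
        lam = 2.5
        c2 = ClottingCurve(
            time=c.time, absorbance=lam * c.absorbance,
            sample_id="scaled", window=c.window,
        )
        a, b = extract_curve(c), extract_curve(c2)
        for key in ("t_2nd1", "t_1st", "t_halfff", "w_1st", "w_2nd1", "w_2nd2"):
            assert getattr(b, key) == pytest.approx(getattr(a, key), rel=1e-6)
        for key in ("h_2nd1", "h_1st", "nh_2nd2", "h_halfff"):
            assert getattr(b, key) == pytest.approx(lam * getattr(a, key), rel=1e-6)

    def test_velocity_peak_time_robust_to_noise(self):
        """At noise sd = 2% of the amplitude, the median velocity-peak
        time error over 100 seeded replicates stays within 2%."""
        from aptt_cwa.presets import builtin_preset

        base = builtin_preset("hv", noise_sd=0.0)
        p = replace(base, noise_sd=0.02 * base.amplitude)
        errs = [
            abs(extract_curve(generate_curve(p, seed)).t_1st - p.center)
            for seed in range(100)
        ]
        assert np.median(errs) <= 0.02 * p.center


class TestDetectBiphasic:
    def test_pure_sigmoid_is_not_biphasic(self):
        p = GeneratorPreset(amplitude=500.0, center=60.0, slope=5.0, asymmetry=1.0)
        wp = extract_curve(generate_curve(p, seed=0))
        assert wp.biphasic is False
        assert abs(wp.pre_clot_slope) < 0.1  # well below the 0.2 mabs/s threshold

    def test_preclot_ramp_detected_with_measured_slope(self):
        p = GeneratorPreset(
            amplitude=500.0, center=60.0, slope=5.0, asymmetry=1.0,
            biphasic_slope=1.0, biphasic_end=50.0,
        )
        wp = extract_curve(generate_curve(p, seed=0))
        assert wp.biphasic is True
        assert wp.pre_clot_slope == pytest.approx(1.0, abs=0.1)

    def test_subthreshold_ramp_not_flagged(self):
        p = GeneratorPreset(
            amplitude=500.0, center=60.0, slope=5.0, asymmetry=1.0,
            biphasic_slope=0.05, biphasic_end=50.0,
        )
        wp = extract_curve(generate_curve(p, seed=0))
        assert wp.biphasic is False

    def test_short_preclot_segment_is_undetermined(self):
        # acceleration peak so close to the window start that the
        # pre-clot segment is shorter than the smoothing window
        p = GeneratorPreset(
            amplitude=500.0, center=7.0, slope=2.0, asymmetry=-0.4, t_start=0.0
        )
        settings = ExtractionSettings(smooth_window=2.5, poly_order=3)
        c = generate_curve(p, seed=0)
        d = differentiate(c, settings=settings)
        params = extract_parameters(d, window=c.window)
        res = detect_biphasic(c, d, params)
        assert res.flag is None


class TestExtractBatch:
    def test_clean_batch_has_no_failures(self):
        from aptt_cwa.presets import builtin_preset

        p = builtin_preset("hv", noise_sd=0.0)
        curves = [generate_curve(p, seed=i, sample_id=f"hv-{i}") for i in range(30)]
        table = extract_batch(curves)
        assert len(table) == 30
        assert (table["status"] == "ok").all()

    def test_flat_curve_recorded_as_failure_row(self, logistic_preset):
        curves = [
            generate_curve(logistic_preset, seed=0, sample_id="good"),
            _flat_curve(),
        ]
        table = extract_batch(curves)
        assert len(table) == 2
        assert table.set_index("sample_id").loc["good", "status"] == "ok"
        assert table.set_index("sample_id").loc["flat", "status"] == "no-coagulation"

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            extract_batch([])
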