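"""Spectrum handling, g-factor arithmetic and G+L deconvolution recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from humepr.deconvolution import (
    Spectrum,
    estimate_initial_params,
    experimental_dBpp,
    field_for_g,
    fit_deconvolution,
    g_value,
)
from humepr.exceptions import DegenerateSpectrumError, InvalidParameterError
from humepr.lineshapes import LineComponent


class TestSpectrumType:
    def test_rejects_short_nonmonotone_or_mismatched(self):
        B = np.linspace(330, 340, 64)
        with pytest.raises(InvalidParameterError):
            Spectrum(B[:8], np.zeros(8), 9.45)
        with pytest.raises(InvalidParameterError):
            Spectrum(B, np.zeros(63), 9.45)
        with pytest.raises(InvalidParameterError):
            Spectrum(B[::-1], np.zeros(64), 9.45)
        with pytest.raises(InvalidParameterError):
            Spectrum(B, np.zeros(64), 0.0)


class TestGValue:
    def test_known_x_band_point(self):
        """337.2 mT at 9.45 GHz resonates at g ≈ 2.0023 (CODATA h, μ_B)."""
        assert g_value(337.2, 9.45) == pytest.approx(2.00232, abs=1e-5)

    def test_round_trip_with_field_for_g(self):
        for g0 in (2.0028, 2.0036, 2.0055):
            assert g_value(field_for_g(g0, 9.45), 9.45) == pytest.approx(g0, rel=1e-12)

    @given(B0=st.floats(100.0, 1000.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_inverse_proportionality_in_field(self, B0):
        assert g_value(B0 / 2, 9.45) == pytest.approx(2 * g_value(B0, 9.45), rel=1e-12)
        assert g_value(B0 + 1.0, 9.45) < g_value(B0, 9.45)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            g_value(-1.0, 9.45)
        with pytest.raises(InvalidParameterError):
            g_value(337.0, 0.0)


class TestExperimentalWidth:
    @pytest.mark.parametrize("shape,width", [("lorentzian", 0.45), ("gaussian", 1.52)])
    def test_single_line_width_to_grid_resolution(self, make_spectrum, shape, width):
        c = LineComponent(shape, 337.0, width, 1.0)
        span = 6 * width
        n = int(2 * span / 0.005) + 1  # 0.005 mT grid
        s, _ = make_spectrum([c], n_points=n, span=span)
        assert experimental_dBpp(s) == pytest.approx(width, abs=2 * 0.005)

    def test_composite_width_between_components_near_narrow(self, make_spectrum):
        g = LineComponent("gaussian", 337.0, 1.52, 1.0)
        l = LineComponent("lorentzian", 337.0, 0.355, 1.0)
        s, _ = make_spectrum([g, l], n_points=8192)
        w = experimental_dBpp(s)
        assert 0.355 < w < 1.52
        assert w < 0.7  # extrema pinned by the narrow Lorentzian

    def test_flat_spectrum_degenerate(self):
        B = np.linspace(330, 340, 128)
        with pytest.raises(DegenerateSpectrumError):
            experimental_dBpp(Spectrum(B, np.zeros(128), 9.45))


class TestInitialEstimates:
    def test_single_lorentzian_center_within_grid_step(self, make_spectrum):
        c = LineComponent("lorentzian", 337.0, 0.45, 1.0)
        span = 3.0
        n = int(2 * span / 0.005) + 1
        s, _ = make_spectrum([c], n_points=n, span=span)
        est = estimate_initial_params(s)
        step = s.step
        for comp in est:
            assert comp.B0 == pytest.approx(337.0, abs=step)
        shapes = sorted(c.shape for c in est)
        assert shapes == ["gaussian", "lorentzian"]

    def test_constant_spectrum_raises(self):
        B = np.linspace(330, 340, 128)
        with pytest.raises(DegenerateSpectrumError):
            estimate_initial_params(Spectrum(B, np.full(128, 3.0), 9.45))

    def test_plant_fixture_width_near_narrow_component(self, make_spectrum):
        """With amplitudes matched to the published raw width, the
        experimental ΔBpp estimate tracks the narrow Lorentzian."""
        from humepr.synthetic import preset_components

        comps = preset_components("plant", "experimental_width")
        s, _ = make_spectrum(comps, n_points=16384, span=8.0)
        narrow = min(c.dBpp for c in comps)
        est_width = experimental_dBpp(s)
        assert est_width == pytest.approx(narrow, rel=0.05)


class TestFitDeconvolution:
    def test_noiseless_recovery_and_residual(self, make_spectrum, forest_components):
        """Exact model class: all parameters back to 0.1%, correlation
        > 0.9999, residual RMS < 1e−8 of the peak amplitude."""
        s, truth = make_spectrum(forest_components, n_points=1024)
        r = fit_deconvolution(s)
        fit = {c.shape: c for c in r.components}
        for t in truth["components"]:
            f = fit[t.shape]
            assert f.B0 == pytest.approx(t.B0, rel=1e-3)
            assert f.dBpp == pytest.approx(t.dBpp, rel=1e-3)
            assert f.Ym == pytest.approx(t.Ym, rel=1e-3)
        assert r.correlation > 0.9999
        peak = np.max(np.abs(s.intensity))
        assert r.residual_rms < 1e-8 * peak
        assert -1.0 <= r.correlation <= 1.0
        for g in r.g_values:
            assert 1.9 < g < 2.1

    def test_noisy_recovery_meets_quality_bar(self, make_spectrum, forest_components):
        """2% additive noise: parameters within 2%, correlation ≥ 0.99."""
        s, truth = make_spectrum(forest_components, noise_sigma=0.02, seed=42,
                                 n_points=2048)
        r = fit_deconvolution(s)
        fit = {c.shape: c for c in r.components}
        for t in truth["components"]:
            f = fit[t.shape]
            assert f.dBpp == pytest.approx(t.dBpp, rel=0.02)
            assert f.Ym == pytest.approx(t.Ym, rel=0.02)
        assert r.correlation >= 0.99

    def test_pure_gaussian_collapses_lorentzian(self, make_spectrum):
        c = LineComponent("gaussian", 337.0, 1.5, 1.0)
        s, _ = make_spectrum([c], n_points=1024)
        r = fit_deconvolution(s)
        assert r.A_L < 0.01 * r.A_G
        assert any(f.startswith("collapsed") for f in r.flags)

    def test_ratio_invariant_under_intensity_rescale(self, make_spectrum,
                                                     forest_components):
        s, _ = make_spectrum(forest_components, noise_sigma=0.01, seed=7,
                             n_points=1024)
        r1 = fit_deconvolution(s)
        s2 = Spectrum(s.field, 37.5 * s.intensity, s.frequency)
        r2 = fit_deconvolution(s2)
        assert r2.ratio_AG_AL == pytest.approx(r1.ratio_AG_AL, rel=1e-6)

    def test_inverted_phase_detected_and_fitted(self, make_spectrum,
                                                forest_components):
        s, truth = make_spectrum(forest_components, n_points=1024)
        flipped = Spectrum(s.field, -s.intensity, s.frequency)
        r = fit_deconvolution(flipped)
        assert r.inverted
        fit = {c.shape: c for c in r.components}
        for t in truth["components"]:
            assert fit[t.shape].dBpp == pytest.approx(t.dBpp, rel=1e-3)

    def test_independent_centers_mode(self, make_spectrum):
        g = LineComponent("gaussian", 336.8, 1.5, 0.5)
        l = LineComponent("lorentzian", 337.1, 0.4, 1.0)
        s, _ = make_spectrum([g, l], n_points=2048, span=9.5)
        r = fit_deconvolution(s, shared_B0=False)
        fit = {c.shape: c for c in r.components}
        assert fit["gaussian"].B0 == pytest.approx(336.8, abs=0.01)
        assert fit["lorentzian"].B0 == pytest.approx(337.1, abs=0.01)
        assert not r.shared_B0

    def test_offset_cofit(self, make_spectrum, forest_components):
        s, _ = make_spectrum(forest_components, n_points=1024, baseline=0.25)
        r = fit_deconvolution(s)
        assert r.offset == pytest.approx(0.25, abs=1e-6)

    def test_parameter_recovery_ensemble(self):
        """Median relative error < 2% over 50 random G+L spectra with
        parameters in realistic ranges and 0–2% noise."""
        from humepr.synthetic import EPRGeneratorConfig, generate_epr

        rng = np.random.default_rng(2024)
        errors = []
        for i in range(50):
            B0 = field_for_g(rng.uniform(2.002, 2.004), 9.45)
            dB_g = rng.uniform(1.3, 1.7)
            dB_l = rng.uniform(0.3, 0.5)
            ym_g = rng.uniform(0.2, 1.2)
            comps = (
                LineComponent("gaussian", B0, dB_g, ym_g),
                LineComponent("lorentzian", B0, dB_l, 1.0),
            )
            cfg = EPRGeneratorConfig(
                components=comps,
                field_min=B0 - 6 * dB_g,
                field_max=B0 + 6 * dB_g,
                n_points=1024,
                noise_sigma=rng.uniform(0.0, 0.02),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            s, truth = generate_epr(cfg)
            r = fit_deconvolution(s)
            fit = {c.shape: c for c in r.components}
            for t in truth["components"]:
                f = fit[t.shape]
                errors.append(abs(f.B0 - t.B0) / t.B0)
                errors.append(abs(f.dBpp - t.dBpp) / t.dBpp)
                errors.append(abs(f.Ym - t.Ym) / t.Ym)
        assert float(np.median(errors)) < 0.02
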