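"""Derivative lineshape models checked against dense-grid and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid, quad

from humepr.exceptions import InvalidParameterError
from humepr.lineshapes import (
    LineComponent,
    composite,
    evaluate,
    gaussian_derivative,
    integral_intensity,
    lorentzian_derivative,
)

SHAPES = ["gaussian", "lorentzian"]


def dense_extrema(c, n=400_001, half_span_widths=6.0):
    """Oracle: locate the derivative extrema by dense evaluation."""
    B = np.linspace(c.B0 - half_span_widths * c.dBpp,
                    c.B0 + half_span_widths * c.dBpp, n)
    y = evaluate(B, c)
    return B[np.argmax(y)], float(np.max(y)), B[np.argmin(y)], float(np.min(y)), B[1] - B[0]


def area_by_parts(c):
    """Oracle: double integral via the identity A = |∫ (B−B0)·Y(B) dB|.

    Integration by parts turns the double integral of the derivative
    (with the absorption vanishing at ±∞) into a single absolutely
    convergent integral, evaluated by adaptive quadrature over a window
    of ±10⁶ linewidths (the 1/x² Lorentzian tail of the transformed
    integrand then contributes < 1e−5 relative).
    """
    f = lambda u: u * float(evaluate(c.B0 + u, c))
    w = c.dBpp
    edges = [-1e6 * w, -1e3 * w, -50 * w, 50 * w, 1e3 * w, 1e6 * w]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        piece, _ = quad(f, lo, hi, limit=800)
        total += piece
    return abs(total)


def gaussian_area_two_stage(c, widths=50.0, n=200_001):
    """Oracle: cumulative trapezoid → absorption, trapezoid → area."""
    B = np.linspace(c.B0 - widths * c.dBpp, c.B0 + widths * c.dBpp, n)
    absorption = cumulative_trapezoid(evaluate(B, c), B, initial=0.0)
    return abs(np.trapezoid(absorption, B))


class TestShapes:
    @pytest.mark.parametrize("shape", SHAPES)
    @pytest.mark.parametrize("B0,dBpp,Ym", [(337.0, 0.355, 1.0), (340.0, 1.52, 0.47),
                                            (100.0, 5.0, 3.0)])
    def test_extrema_at_half_width_with_amplitude(self, shape, B0, dBpp, Ym):
        """Extrema sit at B0 ± ΔBpp/2 with values ±Ym (dense-grid oracle)."""
        c = LineComponent(shape, B0, dBpp, Ym)
        bmax, ymax, bmin, ymin, step = dense_extrema(c)
        assert bmax == pytest.approx(B0 + dBpp / 2, abs=2 * step)
        assert bmin == pytest.approx(B0 - dBpp / 2, abs=2 * step)
        assert ymax == pytest.approx(Ym, rel=1e-8)
        assert ymin == pytest.approx(-Ym, rel=1e-8)
        # exact closed-form value at the extremum field
        assert evaluate(B0 + dBpp / 2, c) == pytest.approx(Ym, rel=1e-12)
        assert evaluate(B0, c) == 0.0

    @pytest.mark.parametrize("shape", SHAPES)
    @given(delta=st.floats(0.01, 10.0), )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_odd_about_center(self, shape, delta):
        c = LineComponent(shape, 337.0, 0.8, 2.0)
        left = evaluate(c.B0 - delta, c)
        right = evaluate(c.B0 + delta, c)
        assert left == pytest.approx(-right, rel=1e-12, abs=1e-300)

    def test_lorentzian_tails_heavier_than_gaussian(self):
        g = LineComponent("gaussian", 337.0, 0.5, 1.0)
        l = LineComponent("lorentzian", 337.0, 0.5, 1.0)
        for sgn in (-1, 1):
            B = 337.0 + sgn * 5 * 0.5
            assert abs(lorentzian_derivative(B, l)) > abs(gaussian_derivative(B, g))

    def test_shape_mismatch_and_invalid_params(self):
        g = LineComponent("gaussian", 337.0, 0.5, 1.0)
        with pytest.raises(InvalidParameterError):
            lorentzian_derivative(337.2, g)
        with pytest.raises(InvalidParameterError):
            LineComponent("gaussian", 337.0, -0.5, 1.0)
        with pytest.raises(InvalidParameterError):
            LineComponent("gaussian", 337.0, 0.5, 0.0)
        with pytest.raises(InvalidParameterError):
            LineComponent("voigt", 337.0, 0.5, 1.0)


class TestComposite:
    def test_single_component_identity_and_linearity(self, single_lorentzian):
        B = np.linspace(330, 344, 257)
        one = composite(B, [single_lorentzian])
        np.testing.assert_array_equal(one, lorentzian_derivative(B, single_lorentzian))
        two = composite(B, [single_lorentzian, single_lorentzian])
        np.testing.assert_allclose(two, 2 * one, rtol=0, atol=0)

    def test_additivity_over_mixed_components(self, forest_components):
        B = np.linspace(329, 345, 513)
        g, l = forest_components
        total = composite(B, [g, l])
        np.testing.assert_array_equal(total, composite(B, [g]) + composite(B, [l]))

    def test_empty_component_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            composite(np.linspace(0, 1, 10), [])

    def test_invert_flips_sign(self, single_gaussian):
        B = np.linspace(330, 344, 129)
        np.testing.assert_array_equal(
            composite(B, [single_gaussian], invert=True),
            -composite(B, [single_gaussian]),
        )

    def test_narrow_lorentzian_dominates_composite_width(self):
        """G(1.52 mT) + L(0.355 mT) at equal Ym: the summed line's
        peak-to-peak width stays near the narrow Lorentzian's."""
        g = LineComponent("gaussian", 337.0, 1.52, 1.0)
        l = LineComponent("lorentzian", 337.0, 0.355, 1.0)
        B = np.linspace(332.0, 342.0, 2_000_001)
        y = composite(B, [g, l])
        width = abs(B[np.argmax(y)] - B[np.argmin(y)])
        assert 0.355 < width < 1.52
        assert width < 0.5 * (0.355 + 1.52)  # nearer the narrow line


class TestIntegralIntensity:
    def test_gaussian_closed_form_vs_numeric(self):
        """Gaussian area ≈ 1.0333·Ym·ΔBpp², two independent oracles."""
        c = LineComponent("gaussian", 0.0, 1.0, 1.0)
        a = integral_intensity(c)
        # e^{1/2}·sqrt(2π)/4, frozen from the two-stage numeric oracle
        assert a == pytest.approx(1.03318, abs=1e-5)
        assert a == pytest.approx(gaussian_area_two_stage(c), rel=1e-6)
        assert a == pytest.approx(area_by_parts(c), rel=1e-6)

    def test_lorentzian_closed_form_vs_numeric(self):
        """Lorentzian area ≈ 3.6276·Ym·ΔBpp²; heavy tails need the
        parts-identity quadrature oracle."""
        c = LineComponent("lorentzian", 0.0, 1.0, 1.0)
        a = integral_intensity(c)
        assert a == pytest.approx(3.6276, abs=5e-5)
        assert a == pytest.approx(area_by_parts(c), rel=1e-4)

    @pytest.mark.parametrize("shape", SHAPES)
    @pytest.mark.parametrize("B0,dBpp,Ym", [(337.0, 0.355, 0.5), (10.0, 2.0, 3.0)])
    def test_numeric_agreement_off_origin(self, shape, B0, dBpp, Ym):
        c = LineComponent(shape, B0, dBpp, Ym)
        rel = 1e-6 if shape == "gaussian" else 1e-4
        assert integral_intensity(c) == pytest.approx(area_by_parts(c), rel=rel)

    @pytest.mark.parametrize("shape", SHAPES)
    @given(dBpp=st.floats(0.01, 50.0), Ym=st.floats(0.01, 100.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_quadratic_width_scaling(self, shape, dBpp, Ym):
        """Doubling ΔBpp at fixed Ym quadruples the area."""
        a1 = integral_intensity(LineComponent(shape, 0.0, dBpp, Ym))
        a2 = integral_intensity(LineComponent(shape, 0.0, 2 * dBpp, Ym))
        assert a2 == pytest.approx(4 * a1, rel=1e-12)
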