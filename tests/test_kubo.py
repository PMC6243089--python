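"""Kubo-model core: FFCF evaluation, lineshape function, linear synthesis."""

import numpy as np
import pytest

from ir2d.kubo import (
    C_CM_PER_PS,
    GAUSSIAN_FWHM_FACTOR,
    FFCFParams,
    LinearSpectrum,
    MotionalNarrowingWarning,
    SpectralComponent,
    ffcf_inhomogeneous,
    fwhm_of,
    lineshape_g,
    synth_linear,
    voigt_fwhm,
)
from tests.conftest import PDX_LOW_FFCF, WT_FFCF


class TestFFCF:
    def test_zero_time_value_is_total_inhomogeneous_variance(self):
        # 3.0² + 4.1² for the free-enzyme parameter set
        assert ffcf_inhomogeneous(WT_FFCF, 0.0) == pytest.approx(25.81)

    def test_one_tau_value(self):
        # 9·e⁻¹ + 16.81, by direct evaluation
        assert ffcf_inhomogeneous(WT_FFCF, 20.7) == pytest.approx(20.12, abs=0.01)

    def test_long_time_limit_is_static_variance(self):
        assert ffcf_inhomogeneous(WT_FFCF, 1e6) == pytest.approx(4.1**2)

    def test_monotone_nonincreasing_and_bounded(self):
        t = np.linspace(0.0, 200.0, 400)
        c = ffcf_inhomogeneous(WT_FFCF, t)
        assert np.all(np.diff(c) <= 1e-12)
        assert np.all(c <= 25.81 + 1e-9)
        assert np.all(c >= 4.1**2 - 1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ffcf_inhomogeneous(WT_FFCF, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FFCFParams(-1.0, 3.0, 20.0, 4.0)
        with pytest.raises(ValueError):
            FFCFParams(1.6, 3.0, -2.0, 4.0)

    def test_motional_narrowing_warns(self):
        with pytest.warns(MotionalNarrowingWarning):
            FFCFParams(1.6, 0.5, 1.0, 0.0)  # 2πc·Δ₁·τ₁ ≈ 0.09 ≪ 1


class TestLineshapeG:
    def test_zero_at_origin(self):
        assert lineshape_g(WT_FFCF, np.array([0.0]))[0] == 0.0

    def test_homogeneous_limit_is_linear(self):
        p = FFCFParams(2.0, 0.0, 1.0, 0.0)
        t = np.linspace(0.0, 50.0, 101)
        g = lineshape_g(p, t)
        assert np.allclose(g, np.pi * C_CM_PER_PS * 2.0 * t)

    @pytest.mark.parametrize("params", [WT_FFCF, PDX_LOW_FFCF])
    def test_matches_quadrature_oracle(self, params):
        """g(t) equals the double time integral of the FFCF (trapezoid oracle)."""

        def ffcf_angular(tau):
            d1 = 2 * np.pi * C_CM_PER_PS * params.delta_1
            ds = 2 * np.pi * C_CM_PER_PS * params.delta_s
            return d1**2 * np.exp(-tau / params.tau_1) + ds**2

        rng = np.random.default_rng(42)
        for t_end in rng.uniform(1.0, 100.0, 5):
            tau = np.linspace(0.0, t_end, 10001)
            oracle = np.trapezoid(
                (t_end - tau) * ffcf_angular(tau), tau
            ) + np.pi * C_CM_PER_PS * params.gamma_h * t_end
            g = lineshape_g(params, np.array([t_end]))[0]
            assert g == pytest.approx(oracle, rel=1e-4)

    def test_convex_increasing(self):
        t = np.linspace(0.0, 100.0, 400)
        g = lineshape_g(WT_FFCF, t)
        assert np.all(np.diff(g) > 0)
        assert np.all(np.diff(g, 2) > -1e-9)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            lineshape_g(WT_FFCF, np.array([0.0, 2.0, 1.0]))


class TestSynthLinear:
    def test_free_enzyme_width(self, wide_axis):
        """The free-enzyme FFCF gives the reported 12.9 ± 0.5 cm⁻¹ band."""
        spec = synth_linear(SpectralComponent(1939.4, WT_FFCF), wide_axis)
        assert fwhm_of(spec) == pytest.approx(12.9, abs=0.5)

    def test_bound_complex_low_band_width(self, wide_axis):
        """The effector-bound low band gives the reported 7.6 ± 0.3 cm⁻¹."""
        spec = synth_linear(SpectralComponent(1931.3, PDX_LOW_FFCF), wide_axis)
        assert fwhm_of(spec) == pytest.approx(7.6, abs=0.3)

    def test_homogeneous_limit_is_lorentzian(self):
        p = FFCFParams(2.0, 0.0, 1.0, 0.0)
        axis = np.linspace(1850.0, 2020.0, 8001)
        spec = synth_linear(SpectralComponent(1935.0, p), axis)
        assert fwhm_of(spec) == pytest.approx(2.0, abs=0.02)
        assert axis[np.argmax(spec.absorbance)] == pytest.approx(1935.0, abs=0.05)

    def test_area_scales_with_population_and_dipole_squared(self, wide_axis):
        base = synth_linear(SpectralComponent(1935.0, WT_FFCF), wide_axis).area
        for pop in (0.25, 0.5, 1.0):
            a = synth_linear(
                SpectralComponent(1935.0, WT_FFCF, population=pop), wide_axis
            ).area
            assert a == pytest.approx(pop * base, rel=1e-6)
        for dip in (1.1, 1.27, 1.5):
            a = synth_linear(
                SpectralComponent(1935.0, WT_FFCF, dipole=dip), wide_axis
            ).area
            assert a == pytest.approx(dip**2 * base, rel=1e-6)

    def test_narrow_axis_rejected(self):
        with pytest.raises(ValueError):
            synth_linear(
                SpectralComponent(1935.0, WT_FFCF), np.linspace(1930.0, 1940.0, 64)
            )

    def test_quasi_static_width_matches_voigt_prediction(self, wide_axis):
        """In the slow-modulation regime the band is a Voigt profile."""
        for params in (WT_FFCF, PDX_LOW_FFCF):
            assert 2 * np.pi * C_CM_PER_PS * params.delta_1 * params.tau_1 > 5
            spec = synth_linear(SpectralComponent(1935.0, params), wide_axis)
            predicted = voigt_fwhm(
                GAUSSIAN_FWHM_FACTOR * params.inhomogeneous_width, params.gamma_h
            )
            assert fwhm_of(spec) == pytest.approx(predicted, rel=0.02)


class TestVoigtFwhm:
    def test_pure_limits(self):
        assert voigt_fwhm(8.5, 0.0) == 8.5
        assert voigt_fwhm(0.0, 3.4) == pytest.approx(3.4, rel=1e-3)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            voigt_fwhm(0.0, 0.0)

    def test_against_numerical_convolution(self):
        """Olivero–Longbothum approximation vs a brute-force convolution."""
        g_fwhm, l_fwhm = 11.96, 1.6
        x = np.arange(-300.0, 300.0, 0.002)
        sigma = g_fwhm / GAUSSIAN_FWHM_FACTOR
        gauss = np.exp(-0.5 * (x / sigma) ** 2)
        lor = (l_fwhm / 2) ** 2 / (x**2 + (l_fwhm / 2) ** 2)
        conv = np.convolve(gauss, lor, mode="same")
        half = conv.max() / 2
        above = np.nonzero(conv > half)[0]
        oracle = x[above[-1]] - x[above[0]]
        assert voigt_fwhm(g_fwhm, l_fwhm) == pytest.approx(oracle, abs=0.02)


class TestFwhmOf:
    def test_gaussian_self_consistency(self):
        x = np.arange(1900.0, 1970.0, 0.1)
        sigma = 8.5 / GAUSSIAN_FWHM_FACTOR
        spec = LinearSpectrum(x, np.exp(-0.5 * ((x - 1935.0) / sigma) ** 2))
        assert fwhm_of(spec) == pytest.approx(8.5, abs=0.01)

    def test_lorentzian_self_consistency(self):
        x = np.arange(1800.0, 2070.0, 0.1)
        spec = LinearSpectrum(x, 1.0 / (1.0 + ((x - 1935.0) / 1.7) ** 2))
        assert fwhm_of(spec) == pytest.approx(3.4, abs=0.01)

    def test_two_gaussian_composite_matches_grid_scan(self):
        """Composite width equals the dense-grid oracle for the bound-complex bands."""
        x = np.arange(1900.0, 1970.0, 0.02)
        bands = [(1936.8, 8.6, 0.35), (1931.3, 7.6, 0.65)]
        y = np.zeros_like(x)
        for c, w, area in bands:
            s = w / GAUSSIAN_FWHM_FACTOR
            y += area / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / s) ** 2)
        half = y.max() / 2
        above = np.nonzero(y > half)[0]
        oracle = x[above[-1]] - x[above[0]]
        spec = LinearSpectrum(x, y)
        assert fwhm_of(spec) == pytest.approx(oracle, abs=0.05)

    def test_uncrossed_half_maximum_rejected(self):
        x = np.linspace(0.0, 10.0, 64)
        with pytest.raises(ValueError):
            fwhm_of(LinearSpectrum(x, np.exp(-((x - 10.0) ** 2))))


class TestLinearSpectrum:
    def test_nonuniform_axis_rejected(self):
        x = np.linspace(0.0, 10.0, 64)
        x[10] += 0.01
        with pytest.raises(ValueError):
            LinearSpectrum(x, np.ones(64))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            LinearSpectrum(np.arange(8.0), np.ones(8))


class TestPropertyBased:
    def test_voigt_width_bounds(self):
        """The Voigt FWHM lies between max(G, L) and G + L."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(
            g=st.floats(0.1, 50.0, allow_nan=False),
            l=st.floats(0.1, 50.0, allow_nan=False),
        )
        def check(g, l):
            v = voigt_fwhm(g, l)
            assert max(g, l) - 1e-9 <= v <= g + l + 1e-9

        check()

    def test_ffcf_bounds_hold_for_random_parameters(self):
        """C_inh(t) stays within [Δs², Δ₁²+Δs²] and decreases, any params."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(
            d1=st.floats(0.0, 10.0),
            tau=st.floats(0.5, 100.0),
            ds=st.floats(0.0, 10.0),
        )
        def check(d1, tau, ds):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                p = FFCFParams(1.0, d1, tau, ds)
            t = np.linspace(0.0, 300.0, 50)
            c = ffcf_inhomogeneous(p, t)
            assert np.all(c <= d1**2 + ds**2 + 1e-9)
            assert np.all(c >= ds**2 - 1e-9)
            assert np.all(np.diff(c) <= 1e-9)

        check()
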