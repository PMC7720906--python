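import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ramanmc.sampling import (
    absorption_occurs,
    fresnel_reflectance,
    hg_cos_theta,
    reflect_or_transmit,
    refract,
    rotate_direction,
    sample_azimuth,
    sample_polar_hg,
    sample_shift_wavelength,
    sample_step_length,
)

RNG = np.random.default_rng(1234)


class TestStepLength:
    @pytest.mark.parametrize("xi,mu_s,expected", [
        (0.0, 3.0, 0.0),
        (1.0 - math.exp(-1.0), 10.0, 0.1),
    ])
    def test_inverse_cdf(self, xi, mu_s, expected):
        assert sample_step_length(xi, mu_s) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_mu_s(self):
        with pytest.raises(ValueError):
            sample_step_length(0.5, 0.0)

    def test_mean_is_reciprocal_mu_s(self):
        # exponential mean 1/mu_s within 3 sigma of the sample mean
        n = 200_000
        draws = np.array([sample_step_length(u, 5.0) for u in RNG.random(n)])
        assert abs(draws.mean() - 0.2) < 3 * 0.2 / math.sqrt(n)


class TestAzimuth:
    def test_endpoints(self):
        assert sample_azimuth(0.0) == 0.0
        assert sample_azimuth(0.5) == pytest.approx(math.pi)

    def test_cosine_averages_to_zero(self):
        n = 200_000
        c = np.cos([sample_azimuth(u) for u in RNG.random(n)])
        assert abs(c.mean()) < 3 / math.sqrt(2 * n)  # var(cos) = 1/2


class TestPolarHG:
    def test_endpoints_forward_backward(self):
        assert sample_polar_hg(0.0, 0.9) == pytest.approx(math.pi)
        assert sample_polar_hg(1.0, 0.9) == pytest.approx(0.0, abs=1e-7)

    def test_isotropic_median(self):
        assert sample_polar_hg(0.5, 0.0) == pytest.approx(math.pi / 2)

    def test_median_cosine_at_g09(self):
        # direct evaluation of the inverse CDF at xi = 1/2
        frac = (1 - 0.81) / (1 - 0.9 + 2 * 0.9 * 0.5)
        expected = (1 + 0.81 - frac * frac) / 1.8
        assert hg_cos_theta(0.5, 0.9) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9855, abs=1e-4)

    def test_rejects_bad_g(self):
        with pytest.raises(ValueError):
            sample_polar_hg(0.5, 1.0)

    @pytest.mark.parametrize("g", [-0.5, 0.0, 0.5, 0.9, 0.99])
    def test_mean_cosine_equals_g(self, g):
        n = 200_000
        c = np.array([hg_cos_theta(u, g) for u in RNG.random(n)])
        sigma = c.std() / math.sqrt(n)
        assert abs(c.mean() - g) < max(3 * sigma, 1e-3)


class TestAbsorptionRoulette:
    def test_never_absorbed_without_absorption(self):
        assert not absorption_occurs(0.0, 0.0, 5.0)

    def test_threshold_example(self):
        # mu_a*l = 1e-4: threshold ~9.9995e-5, so 0.5 survives
        assert not absorption_occurs(0.5, 0.001, 0.1)
        assert absorption_occurs(5e-5, 0.001, 0.1)

    def test_half_absorption_at_ln2(self):
        n = 200_000
        l = math.log(2)
        frac = np.mean([absorption_occurs(u, 1.0, l) for u in RNG.random(n)])
        assert abs(frac - 0.5) < 3 * 0.5 / math.sqrt(n)


class TestShiftSampling:
    def test_zero_cdf_never_shifts(self):
        cdf = np.zeros(5)
        assert sample_shift_wavelength(0.0, cdf) is None
        assert sample_shift_wavelength(0.999, cdf) is None

    def test_selects_shortest_winning_wavelength(self):
        cdf = np.array([0.2e-6, 0.6e-6, 1.0e-6])
        assert sample_shift_wavelength(0.5e-6, cdf) == 1
        assert sample_shift_wavelength(0.1e-6, cdf) == 0

    def test_exceeding_total_probability_is_elastic(self):
        cdf = np.array([0.2e-6, 0.6e-6, 1.0e-6])
        assert sample_shift_wavelength(0.5, cdf) is None


class TestFresnel:
    def test_matched_media_never_reflect(self):
        for th in (0.0, 0.3, 1.2):
            assert fresnel_reflectance(1.4, 1.4, th) == pytest.approx(0.0, abs=1e-15)

    def test_normal_incidence_closed_form(self):
        assert fresnel_reflectance(1.0, 1.4, 0.0) == pytest.approx(1.0 / 36.0)

    def test_total_internal_reflection(self):
        assert fresnel_reflectance(1.4, 1.0, math.radians(60.0)) == 1.0

    def test_continuous_at_critical_angle(self):
        crit = math.asin(1.0 / 1.4)
        assert fresnel_reflectance(1.4, 1.0, crit - 1e-6) > 0.99

    def test_reciprocity_for_transmitted_rays(self):
        th1 = 0.4
        th2 = math.asin(math.sin(th1) * 1.4 / 1.0)
        assert fresnel_reflectance(1.4, 1.0, th1) == pytest.approx(
            fresnel_reflectance(1.0, 1.4, th2), abs=1e-12)

    def test_bernoulli_boundary_decision(self):
        assert reflect_or_transmit(0.3, 0.0) == "TRANSMIT"
        assert reflect_or_transmit(0.3, 1.0) == "REFLECT"
        n = 100_000
        frac = np.mean([reflect_or_transmit(u, 0.25) == "REFLECT"
                        for u in RNG.random(n)])
        assert abs(frac - 0.25) < 3 * math.sqrt(0.25 * 0.75 / n)

    def test_refract_matches_reflectance_and_snell(self):
        d = np.array([0.0, math.sin(0.3), math.cos(0.3)])
        normal = np.array([0.0, 0.0, -1.0])
        R, refr = refract(d, normal, 1.0, 1.4)
        assert R == pytest.approx(fresnel_reflectance(1.0, 1.4, 0.3), abs=1e-12)
        # Snell: sin(theta2) = sin(theta1)/1.4, direction stays in plane
        assert math.hypot(refr[0], refr[1]) == pytest.approx(
            math.sin(0.3) / 1.4, abs=1e-12)
        assert np.linalg.norm(refr) == pytest.approx(1.0, abs=1e-12)


class TestRotateDirection:
    def test_zero_deflection_is_identity(self):
        u = np.array([0.6, 0.0, 0.8])
        np.testing.assert_allclose(rotate_direction(u, 0.0, 1.3), u, atol=1e-12)

    def test_axis_case(self):
        out = rotate_direction(np.array([0.0, 0.0, 1.0]), math.pi / 2, 0.0)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    def test_rejects_non_unit_input(self):
        with pytest.raises(ValueError):
            rotate_direction(np.array([1.0, 1.0, 0.0]), 0.1, 0.1)

    @given(st.floats(0, math.pi), st.floats(0, 2 * math.pi),
           st.floats(-1, 1), st.floats(0, 2 * math.pi))
    def test_always_unit_norm(self, theta, phi, uz, az):
        sz = math.sqrt(1 - uz * uz)
        u = np.array([sz * math.cos(az), sz * math.sin(az), uz])
        out = rotate_direction(u, theta, phi)
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12

    def test_deflection_angle_matches_theta(self):
        u = np.array([0.36, -0.48, 0.8])
        for theta in (0.2, 1.1, 2.9):
            out = rotate_direction(u, theta, 0.77)
            assert float(u @ out) == pytest.approx(math.cos(theta), abs=1e-12)

    def test_hg_mean_deflection_cosine_is_g(self):
        # u . u' over HG draws estimates g
        g, n = 0.9, 100_000
        u = np.array([0.0, 0.6, 0.8])
        dots = []
        for xi, ph in zip(RNG.random(n), RNG.random(n)):
            out = rotate_direction(u, sample_polar_hg(xi, g), 2 * math.pi * ph)
            dots.append(float(u @ out))
        dots = np.asarray(dots)
        assert abs(dots.mean() - g) < 3 * dots.std() / math.sqrt(n)
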