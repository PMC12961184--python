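"""Boundary-kernel identities, smoothed Grenander endpoint and the
oversmoothed bootstrap density, checked against quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

import curefollowup as cf
from curefollowup.exceptions import (
    DegenerateBoundaryError,
    InvalidBandwidthError,
    InvalidInputError,
    OutOfRangeError,
)
from curefollowup.smoothing import boundary_coeffs, smoothed_majorant


class TestKernelMoments:
    def test_full_range_moments(self, triweight):
        m0, m1, m2 = cf.kernel_moments(triweight, 1.0)
        assert m0 == pytest.approx(1.0, abs=1e-10)
        assert m1 == pytest.approx(0.0, abs=1e-10)
        assert m2 == pytest.approx(1 / 9, abs=1e-10)

    def test_empty_range_moments(self, triweight):
        assert cf.kernel_moments(triweight, -1.0) == pytest.approx((0, 0, 0))

    def test_half_range_against_quadrature(self, triweight):
        m0, m1, m2 = cf.kernel_moments(triweight, 0.0)
        assert m0 == pytest.approx(0.5, abs=1e-10)
        q1, _ = quad(lambda v: v * triweight(v), -1, 0)
        assert m1 == pytest.approx(q1, abs=1e-10)
        assert m1 == pytest.approx(-35 / 256, abs=1e-10)
        assert m2 == pytest.approx(1 / 18, abs=1e-10)

    def test_out_of_range_s_rejected(self, triweight):
        with pytest.raises(InvalidInputError):
            cf.kernel_moments(triweight, 1.5)


class TestBoundaryCoeffs:
    def test_interior_limit(self, triweight):
        bc = cf.boundary_coeffs(triweight, 1.0)
        assert bc.phi == pytest.approx(1.0, abs=1e-12)
        assert bc.psi == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", np.linspace(0.05, 1.0, 12))
    def test_moment_equations_hold(self, triweight, s):
        bc = cf.boundary_coeffs(triweight, s)
        m0, m1, m2 = cf.kernel_moments(triweight, s)
        assert bc.phi * m0 + bc.psi * m1 == pytest.approx(1.0, abs=1e-10)
        assert bc.phi * m1 + bc.psi * m2 == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_boundary_rejected(self, triweight):
        with pytest.raises(DegenerateBoundaryError):
            cf.boundary_coeffs(triweight, -1.0)


class TestBoundaryKernel:
    def test_interior_branch_is_plain_kernel(self, triweight):
        v = 0.3
        assert cf.boundary_kernel_value(triweight, 2.0, v, 0.5, 5.0) == \
            pytest.approx(triweight(v))

    def test_right_edge_branch_formula(self, triweight):
        bc = boundary_coeffs(triweight, 0.0)
        v = -0.4
        got = cf.boundary_kernel_value(triweight, 5.0, v, 0.5, 5.0)
        assert got == pytest.approx((bc.phi - bc.psi * v) * triweight(v))

    def test_outside_support_is_zero(self, triweight):
        assert cf.boundary_kernel_value(triweight, 5.0, 1.2, 0.5, 5.0) == 0.0

    def test_overlapping_branches_rejected(self, triweight):
        with pytest.raises(InvalidBandwidthError):
            cf.boundary_kernel_value(triweight, 1.0, 0.0, 3.0, 5.0)

    @pytest.mark.parametrize("s", np.linspace(0.1, 1.0, 7))
    def test_corrected_kernel_moment_identities(self, triweight, s):
        # zeroth and first moments over the truncated range [-1, s]
        bc = boundary_coeffs(triweight, s)
        kb = lambda v: (bc.phi + bc.psi * v) * triweight(v)  # noqa: E731
        m0, _ = quad(kb, -1, s)
        m1, _ = quad(lambda v: v * kb(v), -1, s)
        assert m0 == pytest.approx(1.0, abs=1e-8)
        assert m1 == pytest.approx(0.0, abs=1e-8)


class TestBandwidths:
    def test_caps_bind_for_tiny_samples(self):
        bw = cf.bandwidths(1, 1.0)
        assert bw.h == pytest.approx(0.5)
        assert bw.h0 == pytest.approx(0.5)

    def test_rates(self):
        bw = cf.bandwidths(500, 1.0)
        assert bw.h == pytest.approx(500 ** -0.2)
        assert bw.h0 == pytest.approx(0.7 * 500 ** (-1 / 9))

    def test_scaling_in_tau_g(self):
        assert cf.bandwidths(500, 3.0).h == pytest.approx(3 * cf.bandwidths(500, 1.0).h)


class TestSmoothedEndpoint:
    def test_constant_density_reproduced_exactly(self, triweight):
        dens = cf.MonotoneDensity(edges=[0.0, 3.0], heights=[0.4])
        got = cf.smoothed_grenander_endpoint(dens, triweight, 0.7, 3.0)
        assert got == pytest.approx(0.4, abs=1e-12)

    def test_two_height_density_matches_quadrature_oracle(self, triweight):
        h, tau_g = 0.5, 3.0
        dens = cf.MonotoneDensity(edges=[0.0, 2.8, 3.0], heights=[0.6, 0.2])
        bc = boundary_coeffs(triweight, 0.0)
        kb = lambda u: (bc.phi - bc.psi * u) * triweight(u)  # noqa: E731
        oracle, _ = quad(
            lambda v: (1 / h) * kb((tau_g - v) / h) * (0.6 if v <= 2.8 else 0.2),
            tau_g - h, tau_g, points=[2.8], limit=200,
        )
        got = cf.smoothed_grenander_endpoint(dens, triweight, h, tau_g)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_redundant_breakpoint_leaves_value_unchanged(self, triweight):
        dens = cf.MonotoneDensity(edges=[0.0, 1.5, 3.0], heights=[0.5, 0.2])
        refined = cf.MonotoneDensity(
            edges=[0.0, 1.5, 2.7, 3.0], heights=[0.5, 0.2, 0.2]
        )
        a = cf.smoothed_grenander_endpoint(dens, triweight, 0.6, 3.0)
        b = cf.smoothed_grenander_endpoint(refined, triweight, 0.6, 3.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_short_region_rejected(self, triweight):
        dens = cf.MonotoneDensity(edges=[2.8, 3.0], heights=[0.2])
        with pytest.raises(InvalidInputError):
            cf.smoothed_grenander_endpoint(dens, triweight, 0.5, 3.0)

    def test_generic_callable_kernel_agrees_with_polynomial_path(self):
        tri_callable = cf.KernelSpec(
            name="triweight-generic", coef=None,
            func=lambda u: (35 / 32) * (1 - u**2) ** 3,
        )
        dens = cf.MonotoneDensity(edges=[0.0, 2.6, 3.0], heights=[0.5, 0.1])
        a = cf.smoothed_grenander_endpoint(dens, cf.TRIWEIGHT, 0.5, 3.0)
        b = cf.smoothed_grenander_endpoint(dens, tri_callable, 0.5, 3.0)
        assert a == pytest.approx(b, abs=1e-10)


class TestOversmoothedDensity:
    def test_linear_majorant_recovers_slope(self, triweight):
        maj = cf.ConcaveMajorant(x=[0.0, 4.0], y=[0.0, 0.8])
        for t in (0.0, 1.7, 4.0):
            got = cf.oversmoothed_density(maj, triweight, 0.9, 4.0, t)
            assert got == pytest.approx(0.2, abs=1e-4)

    def test_matches_finite_difference_oracle(self, triweight):
        rng = np.random.default_rng(3)
        x = np.array([0.0, 0.5, 1.1, 2.0, 3.2, 4.0])
        y = np.array([0.0, 0.30, 0.52, 0.72, 0.87, 0.9])  # concave
        maj = cf.ConcaveMajorant(x=x, y=y)
        h0, tau_g = 0.9, 4.0
        for t in rng.uniform(0.05, 3.95, size=20):
            delta = 5e-5
            oracle = (
                smoothed_majorant(maj, triweight, h0, tau_g, t + delta)
                - smoothed_majorant(maj, triweight, h0, tau_g, t - delta)
            ) / (2 * delta)
            got = cf.oversmoothed_density(maj, triweight, h0, tau_g, t)
            assert got == pytest.approx(max(oracle, 0.0), rel=1e-4, abs=1e-6)

    def test_out_of_range_rejected(self, triweight):
        maj = cf.ConcaveMajorant(x=[0.0, 4.0], y=[0.0, 0.8])
        with pytest.raises(OutOfRangeError):
            cf.oversmoothed_density(maj, triweight, 0.9, 4.0, 4.5)

    def test_negative_derivative_clipped_to_zero(self, triweight, monkeypatch):
        maj = cf.ConcaveMajorant(x=[0.0, 4.0], y=[0.0, 0.8])
        # force a negative raw derivative through the smoothed-majorant map
        import curefollowup.smoothing as sm
        monkeypatch.setattr(
            sm, "smoothed_majorant", lambda *a, **k: -a[-1]
        )
        assert sm.oversmoothed_density(maj, triweight, 0.9, 4.0, 2.0) == 0.0


class TestScalingEquivariance:
    def test_time_rescaling_scales_density_inversely(self, triweight):
        rng = np.random.default_rng(8)
        times = rng.exponential(1.0, size=80)
        events = (rng.uniform(size=80) < 0.7).astype(int)
        lam = 2.5
        s1 = cf.SurvivalSample(times, events)
        s2 = cf.SurvivalSample(times * lam, events)
        tau1 = s1.y_max
        tau2 = lam * tau1
        F1, F2 = cf.km_distribution(s1), cf.km_distribution(s2)
        assert F2(lam * 0.8) == pytest.approx(F1(0.8))
        m1 = cf.lcm(F1, (0.0, tau1))
        m2 = cf.lcm(F2, (0.0, tau2))
        h1 = cf.bandwidths(s1.n, tau1).h
        h2 = cf.bandwidths(s2.n, tau2).h
        e1 = cf.smoothed_grenander_endpoint(
            cf.grenander_density(m1), triweight, h1, tau1)
        e2 = cf.smoothed_grenander_endpoint(
            cf.grenander_density(m2), triweight, h2, tau2)
        assert e2 == pytest.approx(e1 / lam, rel=1e-10)
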