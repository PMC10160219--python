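"""Continuous kernel families: unit areas, causality, the two numerical
routes to the limit kernel, shape statistics, and the comparison models."""

import math

import numpy as np
import pytest
from scipy import integrate

from timecausal.cascade import filter_signal, impulse_response
from timecausal.kernels import (
    ExGaussianParams,
    KoenderinkParams,
    LimitKernelParams,
    ex_gaussian,
    koenderink_kernel,
    limit_kernel_fourier,
    limit_kernel_mean,
    limit_kernel_mu,
    limit_kernel_temporal,
    partial_fraction_rep,
    skewness_kurtosis,
    truncated_exponential,
    uniform_composed_kernel,
)
from timecausal.layout import logarithmic_levels, uniform_levels


class TestTruncatedExponential:
    def test_value_at_origin_and_causality(self):
        assert truncated_exponential(0.0, 2.5) == pytest.approx(1 / 2.5)
        assert truncated_exponential(-1.0, 2.5) == 0.0

    def test_unit_area(self):
        mu = 3.0
        val, _ = integrate.quad(lambda t: truncated_exponential(t, mu), 0, 50 * mu)
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            truncated_exponential(1.0, 0.0)


class TestUniformComposedKernel:
    def test_single_stage_reduces_to_exponential(self):
        t = np.linspace(-1, 10, 200)
        np.testing.assert_allclose(
            uniform_composed_kernel(t, 2.0, 1), truncated_exponential(t, 2.0)
        )

    def test_moments_by_quadrature(self):
        mu, K = 1.5, 4
        m0, _ = integrate.quad(lambda t: uniform_composed_kernel(t, mu, K), 0, 100)
        m1, _ = integrate.quad(lambda t: t * uniform_composed_kernel(t, mu, K), 0, 100)
        m2, _ = integrate.quad(lambda t: t * t * uniform_composed_kernel(t, mu, K), 0, 200)
        assert m0 == pytest.approx(1.0, abs=1e-9)
        assert m1 == pytest.approx(K * mu, rel=1e-8)
        assert m2 - m1 * m1 == pytest.approx(K * mu * mu, rel=1e-7)

    def test_matches_numeric_cascade_convolution(self):
        # Gamma form vs FFT convolution of four continuous exponentials
        mu, K = 1.0, 4
        dt = 0.001
        t = np.arange(0.0, 40.0, dt)
        h = truncated_exponential(t, mu)
        h_tr = h.copy()
        h_tr[0] *= 0.5  # trapezoid endpoint weight
        acc = h_tr
        for _ in range(K - 1):
            acc = np.convolve(acc, h_tr)[: t.size] * dt
        cont = uniform_composed_kernel(t, mu, K)
        assert np.max(np.abs(acc - cont)) < 1e-5


class TestLimitKernelFourier:
    def test_unit_dc_gain(self):
        p = LimitKernelParams(tau=3.0, c=1.7)
        assert limit_kernel_fourier(0.0, p, 8) == pytest.approx(1.0 + 0.0j)

    def test_conjugate_symmetry_and_monotone_magnitude(self):
        p = LimitKernelParams(tau=1.0, c=2.0)
        w = np.linspace(0.0, 10.0, 101)
        vals = limit_kernel_fourier(w, p, 16)
        neg = limit_kernel_fourier(-w, p, 16)
        np.testing.assert_allclose(neg, np.conj(vals), rtol=1e-12)
        mags = np.abs(vals)
        assert np.all(np.diff(mags) <= 1e-12)

    def test_truncation_convergence(self):
        # missing tail variance after K factors is tau * c**(-2K), so the
        # magnitude deviation shrinks geometrically with the truncation depth
        p = LimitKernelParams(tau=1.0, c=2.0)
        w = np.linspace(-10, 10, 201)
        b = np.abs(limit_kernel_fourier(w, p, 50))
        a8 = np.abs(limit_kernel_fourier(w, p, 8))
        a12 = np.abs(limit_kernel_fourier(w, p, 12))
        assert np.max(np.abs(a8 - b)) < 2e-5
        assert np.max(np.abs(a12 - b)) < 1e-6


class TestLimitKernelTemporal:
    def test_causality(self):
        p = LimitKernelParams(tau=1.0, c=2.0)
        t = np.array([-5.0, -0.001])
        assert np.all(limit_kernel_temporal(t, p, 8) == 0.0)

    def test_unit_area_by_quadrature(self):
        p = LimitKernelParams(tau=1.0, c=2.0)
        upper = limit_kernel_mean(p) + 20.0
        val, _ = integrate.quad(
            lambda t: limit_kernel_temporal(np.array([t]), p, 32)[0], 0, upper, limit=400
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_partial_fraction_matches_cascade_fft(self):
        p = LimitKernelParams(tau=1.0, c=2.0)
        t = np.linspace(0.0, 10.0, 1001)
        a = limit_kernel_temporal(t, p, 12, method="partial_fraction")
        b = limit_kernel_temporal(t, p, 12, method="cascade_fft")
        assert np.max(np.abs(a - b)) < 1e-6

    def test_small_c_falls_back_to_fft(self):
        # ill-conditioned decomposition region: both methods must agree
        p = LimitKernelParams(tau=1.0, c=1.1)
        t = np.linspace(0.0, 10.0, 501)
        a = limit_kernel_temporal(t, p, 16, method="partial_fraction")
        b = limit_kernel_temporal(t, p, 16, method="cascade_fft")
        np.testing.assert_allclose(a, b)

    def test_recurrence_between_adjacent_scales(self):
        # Psi(.; tau, c) = h_exp(.; sqrt(c^2-1)/c sqrt(tau)) * Psi(.; tau/c^2, c)
        tau, c, K = 4.0, 2.0, 20
        dt = 0.001
        t = np.arange(0, 30, dt)
        fine = limit_kernel_temporal(t, LimitKernelParams(tau=tau / c**2, c=c), K)
        h = truncated_exponential(t, math.sqrt(c * c - 1.0) / c * math.sqrt(tau))
        h_tr = h.copy()
        h_tr[0] *= 0.5  # trapezoid endpoint weight (fine[0] == 0 already)
        conv = np.convolve(h_tr, fine)[: t.size] * dt
        coarse = limit_kernel_temporal(t, LimitKernelParams(tau=tau, c=c), K)
        assert np.max(np.abs(conv - coarse)) < 1e-6

    @pytest.mark.parametrize("S", [2.0, 0.5])
    def test_scaling_covariance(self, S):
        # S Psi(S t; S^2 tau, c) == Psi(t; tau, c)
        p = LimitKernelParams(tau=1.0, c=2.0)
        t = np.linspace(0.0, 8.0, 400)
        lhs = S * limit_kernel_temporal(
            S * t, LimitKernelParams(tau=S * S * p.tau, c=p.c), 24
        )
        rhs = limit_kernel_temporal(t, p, 24)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_fourier_temporal_consistency(self):
        # FFT of the temporal kernel matches the analytic Fourier product
        p = LimitKernelParams(tau=1.0, c=2.0)
        dt = 0.005
        n = 2**15
        t = np.arange(n) * dt
        vals = limit_kernel_temporal(t, p, 24)
        spec = np.fft.rfft(vals) * dt
        freqs = np.fft.rfftfreq(n, d=dt) * 2 * math.pi
        band = freqs < 20.0
        analytic = limit_kernel_fourier(freqs[band], p, 24)
        assert np.max(np.abs(spec[band] - analytic)) < 1e-3


class TestPartialFractions:
    def test_coefficients_sum_to_one(self):
        p = LimitKernelParams(tau=1.0, c=2.0)
        for K in (4, 8, 16, 32):
            rep = partial_fraction_rep(p, K)
            assert rep.A.sum() == pytest.approx(1.0, abs=1e-10)

    def test_time_constants_geometric(self):
        p = LimitKernelParams(tau=2.0, c=1.5)
        mu = limit_kernel_mu(p, 6)
        np.testing.assert_allclose(mu[1:] / mu[:-1], 1.0 / 1.5)


class TestSkewnessKurtosis:
    def test_against_cumulant_sums(self):
        # oracle: cumulants of the truncated product at large depth,
        # k3 = 2 sum mu^3, k4 = 6 sum mu^4
        for c in (math.sqrt(2.0), 2.0):
            mu = limit_kernel_mu(LimitKernelParams(tau=1.0, c=c), 60)
            v = np.sum(mu**2)
            g1 = 2.0 * np.sum(mu**3) / v**1.5
            g2 = 6.0 * np.sum(mu**4) / v**2
            got1, got2 = skewness_kurtosis(c)
            assert got1 == pytest.approx(g1, rel=1e-12)
            assert got2 == pytest.approx(g2, rel=1e-12)

    def test_known_values(self):
        assert skewness_kurtosis(math.sqrt(2.0))[1] == pytest.approx(2.0)
        assert skewness_kurtosis(2.0)[0] == pytest.approx(6.0 * math.sqrt(3.0) / 7.0)

    def test_large_c_limit(self):
        # single-exponential limit: excess kurtosis -> 6
        assert skewness_kurtosis(1e8)[1] == pytest.approx(6.0, rel=1e-6)

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            skewness_kurtosis(1.0)


class TestKoenderinkKernel:
    def test_zero_for_nonpositive_time(self):
        p = KoenderinkParams(sigma=0.5, delta=2.0)
        assert koenderink_kernel(0.0, p) == 0.0
        assert koenderink_kernel(-3.0, p) == 0.0

    def test_unit_area(self):
        p = KoenderinkParams(sigma=0.5, delta=2.0)
        val, _ = integrate.quad(lambda t: koenderink_kernel(t, p), 0, np.inf, limit=400)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_skewed_shape(self):
        # the Gaussian sits in log time, so the peak is at delta exactly
        # (no 1/t factor, unlike a log-normal density) while the mean is
        # pushed beyond delta by the heavy right tail: delta * e^{3 sigma^2/2}
        p = KoenderinkParams(sigma=0.5, delta=2.0)
        t = np.linspace(1e-4, 60, 60000)
        vals = koenderink_kernel(t, p)
        assert t[np.argmax(vals)] == pytest.approx(p.delta, abs=1e-2)
        mean = np.trapezoid(t * vals, t)
        assert mean == pytest.approx(p.delta * math.exp(1.5 * p.sigma**2), rel=1e-3)
        assert mean > p.delta


class TestExGaussian:
    def test_closed_form_matches_quadrature(self):
        p = ExGaussianParams(mu=4.0, sigma=0.5, m=2.0)
        for t0 in np.linspace(-2.0, 15.0, 12):
            direct, _ = integrate.quad(
                lambda u: math.exp(-((t0 - p.m - u) ** 2) / (2 * p.sigma**2))
                * math.exp(-u / p.mu),
                0,
                np.inf,
                limit=400,
            )
            assert ex_gaussian(t0, p) == pytest.approx(direct, abs=1e-8)

    def test_small_sigma_approaches_shifted_exponential(self):
        sigma = 1e-3
        p = ExGaussianParams(mu=2.0, sigma=sigma, m=1.0)
        t = np.array([2.0, 4.0, 6.0])
        expected = math.sqrt(2 * math.pi) * sigma * 2.0 * truncated_exponential(t - 1.0, 2.0)
        np.testing.assert_allclose(ex_gaussian(t, p), expected, rtol=1e-3)

    def test_dc_offset_at_minus_infinity(self):
        p = ExGaussianParams(mu=1.0, sigma=0.5, m=0.0, a0=0.7)
        assert ex_gaussian(-50.0, p) == pytest.approx(0.7, abs=1e-12)
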