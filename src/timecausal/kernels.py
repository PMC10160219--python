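"""Continuous-domain temporal smoothing kernels.

The primitive time-causal smoothing kernel is the truncated exponential
``h(t; mu) = exp(-t/mu)/mu`` for ``t >= 0`` (a first-order integrator).
Chaining infinitely many of them with geometrically distributed time
constants ``mu_k = c**(-k) sqrt(c**2-1) sqrt(tau)`` yields the
scale-covariant time-causal limit kernel ``Psi(t; tau, c)``, defined by
its Fourier transform

    Psi_hat(omega) = prod_k 1 / (1 + i mu_k omega).

There is no compact closed form for ``Psi`` in the time domain; two
numerical routes are provided and cross-validated: a partial-fraction
expansion into a weighted sum of truncated exponentials, and an FFT
inversion of the truncated Fourier product.

Also provided: the Gamma-shaped kernel of a uniform cascade, Koenderink's
scale-time kernel (Gaussian smoothing over log-remapped past time), and
the ex-Gaussian (exponentially modified Gaussian) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "LimitKernelParams",
    "KoenderinkParams",
    "ExGaussianParams",
    "PartialFractionRep",
    "truncated_exponential",
    "uniform_composed_kernel",
    "limit_kernel_fourier",
    "limit_kernel_mu",
    "limit_kernel_mean",
    "partial_fraction_rep",
    "limit_kernel_temporal",
    "skewness_kurtosis",
    "koenderink_kernel",
    "ex_gaussian",
]

#: Below this value of c the partial-fraction decomposition is too
#: ill-conditioned (nearly equal time constants); fall back to FFT.
PARTIAL_FRACTION_C_MIN = 1.2


@dataclass(frozen=True)
class LimitKernelParams:
    """Time-causal limit kernel parameters: scale tau (time^2), ratio c > 1."""

    tau: float
    c: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.c <= 1:
            raise ValueError("c must be > 1")


@dataclass(frozen=True)
class KoenderinkParams:
    """Scale-time kernel parameters: log-domain width sigma, delay delta."""

    sigma: float
    delta: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclass(frozen=True)
class ExGaussianParams:
    """Ex-Gaussian model ``a0 + a1 * (unnormalized Gaussian * truncated exp)``.

    mu is the exponential time constant, sigma the Gaussian width, m the
    Gaussian position, a0 a DC offset and a1 the amplitude.  Neither
    component is area-normalized: relative to the unit-area exponentially
    modified Gaussian density the kernel carries a factor
    ``a1 * sqrt(2 pi) * sigma * mu``.
    """

    mu: float
    sigma: float
    m: float
    a0: float = 0.0
    a1: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.a1 <= 0:
            raise ValueError("a1 must be > 0")


@dataclass(frozen=True)
class PartialFractionRep:
    """Sum-of-exponentials representation ``Psi(t) = sum A_k/mu_k e^{-t/mu_k}``."""

    mu: np.ndarray
    A: np.ndarray
    K_trunc: int


def truncated_exponential(t, mu: float):
    """Unit-area first-order integrator kernel ``exp(-t/mu)/mu`` for t >= 0."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    t = np.asarray(t, float)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / mu) / mu, 0.0)
    return out if out.ndim else float(out)


def uniform_composed_kernel(t, mu: float, K: int):
    """Gamma-shaped kernel of K equal stages: ``t**(K-1) e^{-t/mu} / (mu**K (K-1)!)``."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    t = np.asarray(t, float)
    tc = np.clip(t, 0, None)
    out = np.where(
        t >= 0,
        tc ** (K - 1) * np.exp(-tc / mu) / (mu**K * special.gamma(K)),
        0.0,
    )
    return out if out.ndim else float(out)


def limit_kernel_mu(params: LimitKernelParams, K_trunc: int) -> np.ndarray:
    """Time constants ``mu_k = c**(-k) sqrt(c**2-1) sqrt(tau)``, k = 1..K_trunc."""
    if K_trunc < 1:
        raise ValueError("K_trunc must be >= 1")
    k = np.arange(1, K_trunc + 1)
    return params.c ** (-k.astype(float)) * math.sqrt(params.c**2 - 1.0) * math.sqrt(params.tau)


def limit_kernel_mean(params: LimitKernelParams) -> float:
    """Temporal mean (delay) ``sqrt(tau (c+1)/(c-1))`` of the full limit kernel."""
    return math.sqrt(params.tau * (params.c + 1.0) / (params.c - 1.0))


def limit_kernel_fourier(omega, params: LimitKernelParams, K_trunc: int = 32):
    """Fourier transform of the limit kernel, truncated at K_trunc factors.

    Unit DC gain; magnitude non-increasing in |omega|; conjugate-symmetric.
    """
    mu = limit_kernel_mu(params, K_trunc)
    omega = np.asarray(omega, float)
    out = np.ones(omega.shape, complex)
    for m in mu:
        out /= 1.0 + 1j * m * omega
    return out if out.ndim else complex(out)


def partial_fraction_rep(params: LimitKernelParams, K_trunc: int) -> PartialFractionRep:
    """Coefficients ``A_k = prod_{i != k} 1/(1 - mu_i/mu_k)`` of the expansion.

    With geometric time constants ``mu_i/mu_k = c**(k-i)``, so the products
    are accumulated over powers of c in ascending order of |1 - c**(k-i)|
    (smallest factors first) for numerical stability.  ``sum(A_k) -> 1`` as
    K_trunc grows (unit DC gain).
    """
    if K_trunc < 2:
        raise ValueError("K_trunc must be >= 2 for a partial-fraction expansion")
    c = params.c
    mu = limit_kernel_mu(params, K_trunc)
    if np.any(np.diff(mu) >= 0):  # cannot happen for c > 1; guard anyway
        raise ValueError("degenerate decomposition: time constants not distinct")
    A = np.empty(K_trunc)
    for k in range(1, K_trunc + 1):
        diffs = sorted(
            (1.0 - c ** float(k - i) for i in range(1, K_trunc + 1) if i != k),
            key=abs,
        )
        prod = 1.0
        for d in diffs:
            prod *= d
        A[k - 1] = 1.0 / prod
    return PartialFractionRep(mu=mu, A=A, K_trunc=K_trunc)


def _temporal_by_partial_fraction(t_grid, params, K_trunc):
    rep = partial_fraction_rep(params, K_trunc)
    t = np.asarray(t_grid, float)[:, None]
    vals = np.sum(rep.A / rep.mu * np.exp(-np.clip(t, 0, None) / rep.mu), axis=1)
    return np.where(np.asarray(t_grid, float) >= 0, vals, 0.0)


def _temporal_by_cascade_fft(t_grid, params, K_trunc):
    """Invert the truncated Fourier product on a dense grid, then interpolate."""
    t = np.asarray(t_grid, float)
    mu = limit_kernel_mu(params, K_trunc)
    # resolve the fastest stage, cover the slowest tail
    dt = min(mu[-1] / 8.0, 0.01 * math.sqrt(params.tau))
    t_span = limit_kernel_mean(params) + 40.0 * math.sqrt(params.tau)
    t_span = max(t_span, float(t.max(initial=0.0)) + 10.0 * dt)
    n = int(2 ** math.ceil(math.log2(t_span / dt)))
    freqs = np.fft.rfftfreq(n, d=dt) * 2.0 * math.pi
    spectrum = limit_kernel_fourier(freqs, params, K_trunc)
    dense = np.fft.irfft(spectrum, n=n) / dt
    grid = np.arange(n) * dt
    vals = np.interp(t, grid, dense, left=0.0, right=0.0)
    return np.where(t >= 0, vals, 0.0)


def limit_kernel_temporal(
    t_grid,
    params: LimitKernelParams,
    K_trunc: int = 32,
    method: str = "partial_fraction",
) -> np.ndarray:
    """Evaluate ``Psi(t; tau, c)`` on a grid.

    ``method="partial_fraction"`` uses the sum-of-exponentials expansion;
    ``method="cascade_fft"`` inverts the truncated Fourier product
    numerically.  For ``c < 1.2`` the decomposition is ill-conditioned and
    the FFT route is used regardless of the requested method.
    """
    if K_trunc < 2:
        raise ValueError("K_trunc must be >= 2")
    if method == "partial_fraction" and params.c >= PARTIAL_FRACTION_C_MIN:
        return _temporal_by_partial_fraction(t_grid, params, K_trunc)
    if method in ("partial_fraction", "cascade_fft"):
        return _temporal_by_cascade_fft(t_grid, params, K_trunc)
    raise ValueError(f"unknown method {method!r}")


def skewness_kurtosis(c: float) -> tuple[float, float]:
    """Skewness and excess kurtosis of the limit kernel as functions of c.

    gamma1 = 2 (c+1) sqrt(c**2-1) / (c**2+c+1), increasing from 0 (c -> 1)
    to 2 (c -> inf); gamma2 = 6 (c**2-1) / (c**2+1), increasing from 0 to 6
    (the excess kurtosis of a single exponential).
    """
    if c <= 1:
        raise ValueError("c must be > 1")
    gamma1 = 2.0 * (c + 1.0) * math.sqrt(c * c - 1.0) / (c * c + c + 1.0)
    gamma2 = 6.0 * (c * c - 1.0) / (c * c + 1.0)
    return gamma1, gamma2


def koenderink_kernel(t, params: KoenderinkParams):
    """Scale-time kernel: unit-area Gaussian over logarithmically remapped past.

    ``h(t) = exp(-log(t/delta)**2 / (2 sigma**2) - sigma**2/2)
    / (sqrt(2 pi) sigma delta)`` for t > 0, and 0 for t <= 0.
    """
    t = np.asarray(t, float)
    s, d = params.sigma, params.delta
    tc = np.where(t > 0, t, 1.0)
    out = np.where(
        t > 0,
        np.exp(-np.log(tc / d) ** 2 / (2.0 * s * s) - s * s / 2.0)
        / (math.sqrt(2.0 * math.pi) * s * d),
        0.0,
    )
    return out if out.ndim else float(out)


def ex_gaussian(t, params: ExGaussianParams):
    """Ex-Gaussian kernel ``a0 + a1 * int_0^inf exp(-(t-m-u)^2/(2 sigma^2)) e^{-u/mu} du``.

    Evaluated in closed form through the exponentially modified Gaussian
    density, scaled by ``sqrt(2 pi) sigma mu`` to undo its normalization.
    """
    t = np.asarray(t, float)
    p = params
    scale = math.sqrt(2.0 * math.pi) * p.sigma * p.mu
    pdf = stats.exponnorm.pdf(t, K=p.mu / p.sigma, loc=p.m, scale=p.sigma)
    out = p.a0 + p.a1 * scale * pdf
    return out if out.ndim else float(out)
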