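"""Moment-based model fitting and inter-model parameter maps.

The limit-kernel model ``b0 + b1 Psi(t - t0; tau, c)`` can be fitted to
any non-negative, roughly unimodal, decaying function of t >= 0 by
matching temporal moments over the half line:

* second-order fit (t0 = 0): with ``delta = M1/M0`` and
  ``V = M2/M0 - delta**2``, the map is ``b1 = M0``, ``tau = V`` and
  ``c = (delta**2 + V) / (delta**2 - V)``;
* third-order fit: additionally match skewness, which for the limit kernel
  is the monotone function ``gamma1(c) = 2 (c+1) sqrt(c**2-1)/(c**2+c+1)``,
  then recover the offset as ``t0 = delta - mean(Psi)``.

All moments are taken over ``t in [0, inf)``.  For the ex-Gaussian model
the half-line moments are evaluated in closed form with error-function
terms; using full-line moments instead gives visibly wrong fits whenever
the Gaussian component places appreciable mass at t < 0.

Also provided: the moment-matching map between the limit kernel and
Koenderink's scale-time kernel, and the derived peak-delay estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import erf

from .kernels import (
    ExGaussianParams,
    KoenderinkParams,
    LimitKernelParams,
    limit_kernel_mean,
    skewness_kurtosis,
)

__all__ = [
    "MomentSet",
    "LimitKernelModel",
    "InfeasibleFitError",
    "exgauss_moments",
    "moments_from_samples",
    "fit_limit_kernel",
    "fit_limit_kernel_with_offset",
    "fit_signal",
    "koenderink_map",
    "koenderink_map_inverse",
    "tmax_estimate",
]


class InfeasibleFitError(ValueError):
    """Raised when the moment constraints admit no valid model parameters."""


@dataclass(frozen=True)
class MomentSet:
    """Raw temporal moments ``M_k = int_0^inf t**k h(t) dt`` for k = 0..3.

    M3 may be NaN if only a second-order fit is required.
    """

    M0: float
    M1: float
    M2: float
    M3: float = float("nan")

    def __post_init__(self) -> None:
        if not self.M0 > 0:
            raise InfeasibleFitError("zeroth moment must be positive")

    @property
    def delta_mean(self) -> float:
        """Temporal mean ``M1 / M0``."""
        return self.M1 / self.M0

    @property
    def V(self) -> float:
        """Central variance ``M2/M0 - (M1/M0)**2``."""
        return self.M2 / self.M0 - self.delta_mean**2

    @property
    def third_central(self) -> float:
        """Third central moment (needs M3)."""
        d = self.delta_mean
        return self.M3 / self.M0 - 3.0 * d * self.M2 / self.M0 + 2.0 * d**3

    @property
    def skewness(self) -> float:
        return self.third_central / self.V**1.5


@dataclass(frozen=True)
class LimitKernelModel:
    """Fitted model ``b0 + b1 Psi(t - t0; tau, c)``."""

    b0: float
    b1: float
    t0: float
    tau: float
    c: float
    residual: float = float("nan")

    @property
    def params(self) -> LimitKernelParams:
        return LimitKernelParams(tau=self.tau, c=self.c)


def _halfline_gauss_moments(a: float, sigma: float) -> tuple[float, ...]:
    """``I_k = int_0^inf t**k exp(-(t-a)**2/(2 sigma**2)) dt`` for k = 0..3."""
    s2 = sigma * sigma
    i0 = math.sqrt(math.pi / 2.0) * sigma * (1.0 + erf(a / (math.sqrt(2.0) * sigma)))
    e = s2 * math.exp(-a * a / (2.0 * s2))
    i1 = a * i0 + e
    i2 = (a * a + s2) * i0 + a * e
    i3 = a * (a * a + 3.0 * s2) * i0 + (a * a + 2.0 * s2) * e
    return i0, i1, i2, i3


def exgauss_moments(params: ExGaussianParams, order_max: int = 3) -> MomentSet:
    """Half-line moments of the ex-Gaussian kernel with ``a0 = 0``.

    Writing the kernel as
    ``h(t) = a1 int_0^inf exp(-(t-m-u)**2/(2 sigma**2)) e^{-u/mu} du``,
    the t-integral over [0, inf) for fixed u is a half-line Gaussian
    moment, and the remaining u-integrals reduce to erf/exp primitives
    (integration by parts against ``e^{-u/mu}``).  The DC offset a0 is
    excluded: its half-line moments diverge.
    """
    if params.a0 != 0.0:
        raise InfeasibleFitError("moment fitting requires a0 = 0 (offset disregarded)")
    if not 0 <= order_max <= 3:
        raise ValueError("order_max must be in 0..3")
    mu, sigma, m, a1 = params.mu, params.sigma, params.m, params.a1
    s2 = sigma * sigma
    root = math.sqrt(math.pi / 2.0) * sigma

    # A_j = int_0^inf u**j e^{-u/mu} du
    A = [math.factorial(j) * mu ** (j + 1) for j in range(4)]

    # C_j = int_0^inf u**j e^{-u/mu} exp(-(m+u)**2 / (2 sigma**2)) du:
    # completing the square gives a half-line Gaussian moment at mean -b
    b = m + s2 / mu
    pref = math.exp((b * b - m * m) / (2.0 * s2))
    C = [pref * _halfline_gauss_moments(-b, sigma)[j] for j in range(4)]

    # B_j = int_0^inf u**j e^{-u/mu} erf((m+u)/(sqrt(2) sigma)) du,
    # by parts: d/du erf(.) = sqrt(2/pi)/sigma * exp(-(m+u)**2/(2 s2))
    erf0 = erf(m / (math.sqrt(2.0) * sigma))
    g = mu * math.sqrt(2.0 / math.pi) / sigma
    B = [
        mu * erf0 + g * C[0],
        mu * mu * erf0 + g * (C[1] + mu * C[0]),
        2.0 * mu**3 * erf0 + g * (C[2] + 2.0 * mu * C[1] + 2.0 * mu * mu * C[0]),
        6.0 * mu**4 * erf0
        + g * (C[3] + 3.0 * mu * C[2] + 6.0 * mu * mu * C[1] + 6.0 * mu**3 * C[0]),
    ]

    AB = [A[j] + B[j] for j in range(4)]
    M0 = a1 * root * AB[0]
    M1 = a1 * (root * (m * AB[0] + AB[1]) + s2 * C[0])
    M2 = a1 * (
        root * ((m * m + s2) * AB[0] + 2.0 * m * AB[1] + AB[2])
        + s2 * (m * C[0] + C[1])
    )
    M3 = a1 * (
        root
        * (
            m * (m * m + 3.0 * s2) * AB[0]
            + 3.0 * (m * m + s2) * AB[1]
            + 3.0 * m * AB[2]
            + AB[3]
        )
        + s2 * ((m * m + 2.0 * s2) * C[0] + 2.0 * m * C[1] + C[2])
    )
    out = [M0, M1, M2, M3]
    for j in range(order_max + 1, 4):
        out[j] = float("nan")
    return MomentSet(*out)


def moments_from_samples(t, values, order_max: int = 3) -> MomentSet:
    """Trapezoidal moments of a sampled non-negative function of t >= 0."""
    t = np.asarray(t, float)
    v = np.asarray(values, float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("t and values must be matching 1-D arrays")
    if np.any(v < 0):
        raise ValueError("values must be non-negative for moment fitting")
    M = [float(np.trapezoid(v * t**k, t)) for k in range(order_max + 1)]
    while len(M) < 4:
        M.append(float("nan"))
    if M[0] <= 0:
        raise InfeasibleFitError("zeroth moment is not positive")
    return MomentSet(*M[:4])


def fit_limit_kernel(moments: MomentSet) -> LimitKernelModel:
    """Second-order moment fit (zero temporal offset).

    Feasible exactly when ``delta**2 > V``; at the boundary c diverges
    (single-exponential limit), below it no c > 1 exists.
    """
    d, V = moments.delta_mean, moments.V
    if V <= 0:
        raise InfeasibleFitError(f"non-positive variance V={V!r}")
    if d * d <= V:
        raise InfeasibleFitError(
            f"infeasible moments: mean^2={d*d:.6g} <= variance={V:.6g} "
            "(implied c <= 1)"
        )
    c = (d * d + V) / (d * d - V)
    return LimitKernelModel(b0=0.0, b1=moments.M0, t0=0.0, tau=V, c=c)


_C_BRACKET = (1.0 + 1e-9, 100.0)


def fit_limit_kernel_with_offset(moments: MomentSet) -> LimitKernelModel:
    """Third-order moment fit with a free temporal offset t0.

    b1 and tau follow from M0 and the central variance as before; c is
    recovered from the skewness (monotone in c, ranging over (0, 2)), and
    t0 is whatever mean shift remains after accounting for the mean of
    ``Psi(.; tau, c)``.  Requires ``t0 >= -delta`` (model support must
    reach the data).
    """
    if math.isnan(moments.M3):
        raise InfeasibleFitError("third-order fit requires M3")
    V = moments.V
    if V <= 0:
        raise InfeasibleFitError(f"non-positive variance V={V!r}")
    g1 = moments.skewness
    lo, hi = _C_BRACKET
    g_lo, g_hi = skewness_kurtosis(lo)[0], skewness_kurtosis(hi)[0]
    if not g_lo < g1 < g_hi:
        raise InfeasibleFitError(
            f"skewness {g1:.6g} outside attainable range ({g_lo:.3g}, {g_hi:.3g})"
        )
    c = optimize.brentq(lambda cc: skewness_kurtosis(cc)[0] - g1, lo, hi, xtol=1e-14)
    tau = V
    t0 = moments.delta_mean - limit_kernel_mean(LimitKernelParams(tau=tau, c=c))
    if t0 < -moments.delta_mean:
        raise InfeasibleFitError(f"recovered offset t0={t0:.6g} below -mean")
    return LimitKernelModel(b0=0.0, b1=moments.M0, t0=t0, tau=tau, c=c)


def fit_signal(t, values, with_offset: bool = False) -> LimitKernelModel:
    """Fit the limit-kernel model to a sampled signal by trapezoidal moments.

    The samples must be non-negative, defined for t >= 0, roughly unimodal
    and decaying.  Returns the model with a relative L2 residual on the
    sample grid as a goodness diagnostic.
    """
    from .kernels import limit_kernel_temporal

    t = np.asarray(t, float)
    v = np.asarray(values, float)
    moments = moments_from_samples(t, v, order_max=3 if with_offset else 2)
    model = fit_limit_kernel_with_offset(moments) if with_offset else fit_limit_kernel(moments)
    fitted = model.b0 + model.b1 * limit_kernel_temporal(
        t - model.t0, model.params, K_trunc=32
    )
    denom = float(np.linalg.norm(v))
    residual = float(np.linalg.norm(fitted - v)) / denom if denom > 0 else float("nan")
    return LimitKernelModel(
        b0=model.b0,
        b1=model.b1,
        t0=model.t0,
        tau=model.tau,
        c=model.c,
        residual=residual,
    )


_SIGMA_SUP = math.sqrt(math.log(2.0))


def koenderink_map(params: LimitKernelParams) -> KoenderinkParams:
    """Map limit-kernel (tau, c) to scale-time (sigma, delta) by matching
    first- and second-order moments:
    ``sigma = sqrt(log(2c/(c+1)))``,
    ``delta = (c+1)**2 sqrt(tau) / (2 sqrt(2) sqrt((c-1) c**3))``.

    sigma is bounded by ``sqrt(log 2) ~= 0.832`` as c -> inf.
    """
    tau, c = params.tau, params.c
    sigma = math.sqrt(math.log(2.0 * c / (c + 1.0)))
    delta = (c + 1.0) ** 2 * math.sqrt(tau) / (2.0 * math.sqrt(2.0) * math.sqrt((c - 1.0) * c**3))
    return KoenderinkParams(sigma=sigma, delta=delta)


def koenderink_map_inverse(params: KoenderinkParams) -> LimitKernelParams:
    """Inverse map: ``tau = delta**2 e^{3 sigma**2} (e^{sigma**2} - 1)``,
    ``c = e^{sigma**2} / (2 - e^{sigma**2})``; valid for sigma < sqrt(log 2)."""
    s2 = params.sigma**2
    if params.sigma >= _SIGMA_SUP:
        raise ValueError(
            f"sigma={params.sigma:.6g} >= sqrt(log 2) ~= {_SIGMA_SUP:.4g}: "
            "outside the domain of the scale-time map"
        )
    es = math.exp(s2)
    tau = params.delta**2 * math.exp(3.0 * s2) * (es - 1.0)
    c = es / (2.0 - es)
    return LimitKernelParams(tau=tau, c=c)


def tmax_estimate(params: LimitKernelParams) -> float:
    """Estimate of the limit kernel's peak location: the delay delta of the
    moment-matched scale-time kernel.  Tends to overestimate the true peak,
    but is a better delay measure than the temporal mean."""
    return koenderink_map(params).delta
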