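"""Scale-normalized temporal derivatives.

Raw derivative amplitudes decay with increasing smoothing scale.  Two
normalizations make responses comparable across scales:

* variance-based: multiply the order-n derivative by ``tau**(n*gamma/2)``;
* Lp-norm-based: choose a factor ``alpha_{n,gamma}(tau)`` so that the Lp
  norm of the composed derivative kernel equals the Lp norm of the
  corresponding Gaussian derivative at the same scale, with
  ``p = 1 / (1 + n (1 - gamma))``.

For ``gamma = 1`` (p = 1), derivative magnitudes at matching scales are
invariant under temporal rescalings by integer powers of the distribution
parameter c of the limit kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

from .cascade import ScaleSpaceArray, difference_kernel, impulse_response

__all__ = [
    "NormalizationSpec",
    "p_from_gamma",
    "variance_norm_factor",
    "gaussian_derivative_lp_norm",
    "gaussian_derivative_norm",
    "lp_norm_factor",
    "normalize",
]


@dataclass(frozen=True)
class NormalizationSpec:
    """How to scale-normalize an order-n derivative stack."""

    scheme: str  # "variance" or "lp"
    gamma: float
    n: int

    def __post_init__(self) -> None:
        if self.scheme not in ("none", "variance", "lp"):
            raise ValueError("scheme must be 'none', 'variance' or 'lp'")

    @property
    def p(self) -> float:
        return p_from_gamma(self.n, self.gamma)


def p_from_gamma(n: int, gamma: float) -> float:
    """Lp exponent matched to normalization power gamma (1-D signal):
    ``p = 1 / (1 + n (1 - gamma))``; gamma = 1 gives p = 1 for all orders."""
    if n < 1:
        raise ValueError("derivative order n must be >= 1")
    denom = 1.0 + n * (1.0 - gamma)
    if denom <= 0:
        raise ValueError("1 + n (1 - gamma) must be > 0")
    return 1.0 / denom


def variance_norm_factor(tau: float, n: int, gamma: float) -> float:
    """Variance-based factor ``tau**(n*gamma/2)``."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return float(tau ** (n * gamma / 2.0))


def _gaussian_derivative(t: np.ndarray, n: int, sigma: float) -> np.ndarray:
    """n-th derivative of the unit-area Gaussian with standard deviation sigma."""
    from numpy.polynomial.hermite_e import hermeval

    x = t / sigma
    coeffs = np.zeros(n + 1)
    coeffs[n] = 1.0
    he = hermeval(x, coeffs)
    g = np.exp(-x * x / 2.0) / (math.sqrt(2.0 * math.pi) * sigma)
    return (-1.0 / sigma) ** n * he * g


@lru_cache(maxsize=256)
def gaussian_derivative_lp_norm(n: int, tau: float, p: float) -> float:
    """Lp norm of the raw (unnormalized) order-n Gaussian derivative at
    variance tau.  Closed forms for p = 1, n in {1, 2}:
    ``sqrt(2/pi)/sqrt(tau)`` and ``4 exp(-1/2)/(sqrt(2 pi) tau)``;
    otherwise quadrature."""
    sigma = math.sqrt(tau)
    if p == 1.0:
        if n == 1:
            return math.sqrt(2.0 / math.pi) / sigma
        if n == 2:
            return 4.0 * math.exp(-0.5) / (math.sqrt(2.0 * math.pi) * tau)
    span = (n + 10.0) * sigma
    val, _ = integrate.quad(
        lambda t: abs(_gaussian_derivative(np.array([t]), n, sigma)[0]) ** p,
        -span,
        span,
        limit=200,
    )
    return float(val ** (1.0 / p))


def gaussian_derivative_norm(n: int, gamma: float, tau: float) -> float:
    """Reference norm ``G_{n,gamma}``: the Lp norm of the gamma-normalized
    order-n Gaussian derivative, ``tau**(n*gamma/2) * ||g_{t^n}(.;tau)||_p``
    with p matched to gamma.

    With the matched p this quantity is independent of tau (that is what
    gamma-normalization achieves); it is evaluated at the tau supplied so
    that quadrature happens at a well-conditioned scale.
    """
    p = p_from_gamma(n, gamma)
    return tau ** (n * gamma / 2.0) * gaussian_derivative_lp_norm(n, tau, p)


def lp_norm_factor(discrete_kernel, n: int, gamma: float, tau: float) -> float:
    """Factor ``alpha = G_{n,gamma}(tau) / ||h_{t^n}||_p`` for a materialized
    order-n discrete derivative kernel at scale tau.

    For p < 1 the quasi-norm ``(sum |x|**p)**(1/p)`` is used (no triangle
    inequality claimed).
    """
    h = np.asarray(discrete_kernel, float)
    p = p_from_gamma(n, gamma)
    norm = float(np.sum(np.abs(h) ** p) ** (1.0 / p))
    if norm == 0.0:
        raise ValueError("zero derivative kernel")
    return gaussian_derivative_norm(n, gamma, tau) / norm


def _lp_factors(ss: ScaleSpaceArray, spec: NormalizationSpec, mass_tol: float = 1e-10):
    kernels = impulse_response(ss.layout, mass_tol=mass_tol)
    factors = []
    for k, kern in enumerate(kernels):
        dk = difference_kernel(kern, spec.n)
        factors.append(lp_norm_factor(dk, spec.n, spec.gamma, ss.layout.tau_levels[k]))
    return np.asarray(factors)


def normalize(ss: ScaleSpaceArray, spec: NormalizationSpec) -> ScaleSpaceArray:
    """Multiply each scale column by its normalization factor."""
    if ss.derivative_order != spec.n:
        raise ValueError(
            f"derivative order {ss.derivative_order} does not match spec.n={spec.n}"
        )
    if spec.scheme == "none":
        factors = np.ones(ss.layout.K)
    elif spec.scheme == "variance":
        factors = np.array(
            [variance_norm_factor(t, spec.n, spec.gamma) for t in ss.layout.tau_levels]
        )
    else:
        factors = _lp_factors(ss, spec)
    return ScaleSpaceArray(
        values=ss.values * factors[None, :],
        layout=ss.layout,
        derivative_order=ss.derivative_order,
        normalization=spec.scheme,
        gamma=spec.gamma,
    )
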