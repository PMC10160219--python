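"""Time-causal wavelet and time-frequency analysis.

Temporal derivatives of the limit kernel integrate to zero, so after
normalization they serve as mother wavelets over a time-causal domain.
With dilation factors restricted to integer powers of the distribution
parameter c, the whole wavelet transform lives inside the algebra of the
cascade scale-space: coefficients are normalized temporal derivatives of
the recursive-filter representation, computed strictly time-recursively.

For time-frequency analysis the limit kernel replaces the Gaussian window
of the Gabor transform:

    S(t, omega) = sum_u f(t-u) Psi(u) e^{i omega u}.

The strictly time-recursive variant filters the demodulated signal
``f(t) e^{-i omega t}`` through the real cascade (twice, for the real and
imaginary parts); magnitudes equal the windowed transform exactly and
phases match after a-posteriori multiplication by ``e^{+i omega t}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cascade import (
    ScaleSpaceArray,
    _apply_difference,
    difference_kernel,
    filter_signal,
    impulse_response,
)
from .kernels import LimitKernelParams, limit_kernel_mean
from .layout import ScaleLayout, logarithmic_levels

__all__ = [
    "WaveletBank",
    "Spectrogram",
    "wavelet_kernel",
    "build_wavelet_bank",
    "wavelet_transform",
    "complex_kernel",
    "windowed_transform",
    "recursive_spectrogram",
    "transient_length",
]


@dataclass
class WaveletBank:
    """Wavelets on a c**2-geometric scale grid, realized inside one cascade.

    ``layout`` holds the full recursive ladder: ``pad`` extra sub-scale
    stages below the first analysis scale so that every analysis level is
    a deep cascade approximation of the limit kernel.  ``kernels`` are the
    materialized, normalized child wavelets (order-n differences of the
    per-level impulse responses); ``norms`` the per-level normalization
    divisors shared with the time-recursive route.
    """

    n: int
    scales: np.ndarray
    norm: str
    c: float
    layout: ScaleLayout
    pad: int
    kernels: list
    norms: np.ndarray

    @property
    def J(self) -> int:
        return len(self.scales)


@dataclass
class Spectrogram:
    """Complex time x frequency matrix with its frequency grid and window scale."""

    values: np.ndarray
    omega_grid: np.ndarray
    tau: float
    compensated: bool = True


def _norm(kernel: np.ndarray, norm: str) -> float:
    if norm == "L1":
        return float(np.sum(np.abs(kernel)))
    if norm == "L2":
        return float(np.sqrt(np.sum(kernel**2)))
    raise ValueError("norm must be 'L1' or 'L2'")


def wavelet_kernel(
    n: int,
    params: LimitKernelParams,
    norm: str = "L1",
    K_trunc: int = 8,
    mass_tol: float = 1e-10,
) -> np.ndarray:
    """Discrete mother-wavelet kernel: the order-n difference derivative of
    the K_trunc-stage cascade approximation of Psi, normalized to unit L1
    or L2 norm.  Its coefficients sum to ~0 (a zero-mean wavelet)."""
    if n < 1:
        raise ValueError("wavelet order n must be >= 1 (order 0 is not zero-mean)")
    layout = logarithmic_levels(params.tau, params.c, K_trunc)
    smooth = impulse_response(layout, mass_tol=mass_tol)[-1]
    deriv = difference_kernel(smooth, n)
    return deriv / _norm(deriv, norm)


def build_wavelet_bank(
    n: int,
    tau0: float,
    c: float,
    J: int,
    norm: str = "L1",
    K_trunc: int = 8,
    mass_tol: float = 1e-12,
) -> WaveletBank:
    """Bank of J wavelets at dilation scales ``tau_j = c**(2j) tau0``.

    The underlying cascade carries ``K_trunc - 1`` extra sub-scale stages
    below tau0 so that the finest analysis level is already a K_trunc-deep
    approximation of the limit kernel.
    """
    if n < 1:
        raise ValueError("wavelet order n must be >= 1 (order 0 is not zero-mean)")
    if J < 1:
        raise ValueError("need at least one scale")
    scales = tau0 * c ** (2.0 * np.arange(J))
    pad = max(K_trunc - 1, 0)
    layout = logarithmic_levels(float(scales[-1]), c, J + pad)
    responses = impulse_response(layout, mass_tol=mass_tol)[pad:]
    kernels, norms = [], []
    for smooth in responses:
        deriv = difference_kernel(smooth, n)
        norms.append(_norm(deriv, norm))
        kernels.append(deriv / norms[-1])
    return WaveletBank(
        n=n,
        scales=scales,
        norm=norm,
        c=c,
        layout=layout,
        pad=pad,
        kernels=kernels,
        norms=np.asarray(norms),
    )


def _check_geometric(scales: np.ndarray, c: float) -> None:
    ratios = scales[1:] / scales[:-1]
    if not np.allclose(ratios, c * c, rtol=1e-8):
        raise ValueError("wavelet scale grid must be c**2-geometric")


def wavelet_transform(signal, bank: WaveletBank) -> np.ndarray:
    """Wavelet coefficients, computed time-recursively.

    The signal runs once through the bank's recursive cascade; the
    coefficient at scale j is the order-n temporal difference of the
    corresponding scale column, divided by the same norm that normalizes
    the materialized child wavelet.  Up to kernel mass truncation this
    equals direct convolution with ``bank.kernels``; the first
    ``bank.n`` samples lack a full difference stencil and are NaN.
    """
    x = np.asarray(signal, float)
    if len(bank.scales) > 1:
        _check_geometric(np.asarray(bank.scales, float), bank.c)
    ss = filter_signal(x, bank.layout, init="zero")
    deriv = _apply_difference(ss.values[:, bank.pad :], bank.n)
    return deriv / bank.norms[None, :]


def complex_kernel(t, omega: float, params: LimitKernelParams, K_trunc: int = 32):
    """Time-causal Gabor analogue ``chi(t, omega) = Psi(t) e^{i omega t}``."""
    from .kernels import limit_kernel_temporal

    t = np.asarray(t, float)
    psi = limit_kernel_temporal(t, params, K_trunc=K_trunc)
    out = psi * np.exp(1j * omega * t)
    return out if out.ndim else complex(out)


def _window_kernel(params: LimitKernelParams, K_trunc: int, mass_tol: float) -> np.ndarray:
    layout = logarithmic_levels(params.tau, params.c, K_trunc)
    return impulse_response(layout, mass_tol=mass_tol)[-1]


def windowed_transform(
    signal,
    omega_grid,
    params: LimitKernelParams,
    K_trunc: int = 8,
    mass_tol: float = 1e-12,
) -> Spectrogram:
    """Windowed Fourier transform with the limit kernel as causal window.

    ``S(t, omega) = sum_u f(t-u) Psi_d(u) e^{i omega u}`` over the
    mass-truncated discrete window ``Psi_d``.
    """
    x = np.asarray(signal, float)
    omegas = np.atleast_1d(np.asarray(omega_grid, float))
    if omegas.size == 0:
        raise ValueError("omega grid must be non-empty")
    window = _window_kernel(params, K_trunc, mass_tol)
    u = np.arange(window.size)
    out = np.empty((x.size, omegas.size), complex)
    for i, w in enumerate(omegas):
        kern = window * np.exp(1j * w * u)
        full = np.convolve(x, kern)
        out[:, i] = full[: x.size]
    return Spectrogram(values=out, omega_grid=omegas, tau=params.tau, compensated=True)


def recursive_spectrogram(
    signal,
    omega_grid,
    layout: ScaleLayout,
    compensate: bool = True,
) -> Spectrogram:
    """Strictly time-recursive spectrogram.

    Per frequency, the demodulated signal ``f(t) e^{-i omega t}`` is run
    through the recursive cascade (real and imaginary parts through
    identical real filters).  Without compensation the result is
    ``e^{-i omega t} S(t, omega)``: magnitudes already match the windowed
    transform; multiplying by ``e^{+i omega t}`` restores the phases.
    """
    x = np.asarray(signal, float)
    omegas = np.atleast_1d(np.asarray(omega_grid, float))
    t = np.arange(x.size)
    out = np.empty((x.size, omegas.size), complex)
    for i, w in enumerate(omegas):
        phase = np.exp(-1j * w * t)
        re = filter_signal(x * phase.real, layout, init="zero").values[:, -1]
        im = filter_signal(x * phase.imag, layout, init="zero").values[:, -1]
        col = re + 1j * im
        if compensate:
            col = col * np.exp(1j * w * t)
        out[:, i] = col
    return Spectrogram(
        values=out,
        omega_grid=omegas,
        tau=float(layout.tau_max),
        compensated=compensate,
    )


def transient_length(params: LimitKernelParams) -> int:
    """Startup samples to exclude from steady-state comparisons:
    kernel delay plus five standard deviations."""
    return int(math.ceil(limit_kernel_mean(params) + 5.0 * math.sqrt(params.tau)))
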