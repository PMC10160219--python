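"""Synthetic test signals and the scale-covariance harness.

Generators for the standard study inputs: a Wiener-process (Brownian)
path, a sine wave whose frequency decays exponentially over time,
``f(t) = sin(exp((b - t)/a))`` with defaults a = 200, b = 1000, and a
two-peak signal built from discrete limit-kernel approximations at
tau = 16 and tau = 256 plus white Gaussian noise.  All generators are
pure functions of their parameters and seed.

Temporal rescaling is realized by integer subsampling (interpolating a
discrete signal to a finer grid is formally ill-defined), which is how
the commutative-diagram scale-covariance checks pair a signal at scale
tau with its S-fold subsampling at scale tau / S**2.
"""

from __future__ import annotations

import math

import numpy as np

from .cascade import filter_signal, impulse_response
from .layout import logarithmic_levels

__all__ = [
    "wiener_process",
    "varying_frequency_sine",
    "two_peak_signal",
    "rescale_signal",
    "covariance_paths",
]

#: Clamp for the exponent in the varying-frequency sine; beyond this the
#: oscillation is far below the sampling rate anyway.
_EXP_CLAMP = 30.0


def wiener_process(length: int, seed: int, step_sd: float = 1.0) -> np.ndarray:
    """Brownian path: cumulative sum of i.i.d. Gaussian increments, start 0."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=length - 1)
    return np.concatenate(([0.0], np.cumsum(steps)))


def varying_frequency_sine(length: int, a: float = 200.0, b: float = 1000.0) -> np.ndarray:
    """``f(t) = sin(exp((b - t)/a))`` at integer t: wavelength grows with t."""
    if a <= 0:
        raise ValueError("a must be > 0")
    t = np.arange(length, dtype=float)
    return np.sin(np.exp(np.minimum((b - t) / a, _EXP_CLAMP)))


def two_peak_signal(
    length: int = 2048,
    tau1: float = 16.0,
    tau2: float = 256.0,
    delay: int = 512,
    noise_sd: float | None = None,
    seed: int = 0,
    c: float = 2.0,
    K: int = 8,
) -> np.ndarray:
    """Two unit-mass temporal events of different durations plus noise.

    The events are discrete limit-kernel approximations at scales tau1
    and tau2, the second offset by ``delay`` samples.  noise_sd defaults
    to 1% of the taller peak.
    """
    k1 = impulse_response(logarithmic_levels(tau1, c, K), mass_tol=1e-10)[-1]
    k2 = impulse_response(logarithmic_levels(tau2, c, K), mass_tol=1e-10)[-1]
    out = np.zeros(length)
    n1 = min(k1.size, length)
    out[:n1] += k1[:n1]
    n2 = min(k2.size, max(length - delay, 0))
    if n2 > 0:
        out[delay : delay + n2] += k2[:n2]
    if noise_sd is None:
        noise_sd = 0.01 * float(max(k1.max(), k2.max()))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=length)
    return out


def rescale_signal(signal, S: int) -> np.ndarray:
    """S-fold temporal compression by subsampling: every S-th sample."""
    if int(S) != S or S < 2:
        raise ValueError("S must be an integer >= 2")
    return np.asarray(signal, float)[:: int(S)].copy()


def covariance_paths(
    signal,
    sqrt_tau: float = 64.0,
    S: int = 2,
    c: float = 2.0,
    K: int = 8,
) -> tuple[np.ndarray, np.ndarray, int]:
    """The two routes around the scale-covariance commutative diagram.

    Route one smooths the signal at scale ``(S * sqrt_tau)**2`` and then
    subsamples by S; route two subsamples first and smooths at
    ``sqrt_tau**2``.  Returns both outputs on the subsampled time axis
    plus the number of startup-transient samples to discard before
    comparing (kernel delay plus five standard deviations, in subsampled
    units).
    """
    x = np.asarray(signal, float)
    tau_coarse = (S * sqrt_tau) ** 2
    tau_fine = sqrt_tau**2
    smooth_first = filter_signal(x, logarithmic_levels(tau_coarse, c, K)).values[:, -1]
    path_a = rescale_signal(smooth_first, S)
    path_b = filter_signal(
        rescale_signal(x, S), logarithmic_levels(tau_fine, c, K)
    ).values[:, -1]
    delay = sqrt_tau * math.sqrt((c + 1.0) / (c - 1.0))
    transient = int(math.ceil(delay + 5.0 * sqrt_tau))
    return path_a, path_b, transient
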