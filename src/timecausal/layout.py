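"""Temporal scale ladders for cascades of first-order integrators.

A temporal scale-space is built by chaining first-order smoothing stages,
each with a time constant ``mu_k``.  The temporal scale (variance) reached
after stage ``k`` is ``tau_k = sum_{i<=k} mu_i**2`` in the continuous model.
This module constructs the two standard ladders of intermediate scale
levels -- geometric (uniform in log tau, ratio ``c**2`` between adjacent
levels) and uniform -- together with the continuous time constants and the
discrete time constants used by the recursive-filter implementation.

All scales are expressed in squared sample units internally; conversion
from physical seconds happens only at the I/O boundary via
:func:`physical_to_sample_scale`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleLayout",
    "logarithmic_levels",
    "uniform_levels",
    "c_from_range",
    "cascade_moments",
    "discrete_time_constants",
    "physical_to_sample_scale",
]

#: Default number of recursive-filter stages used to approximate the limit
#: kernel at its top scale level.
DEFAULT_K = 8


@dataclass(frozen=True)
class ScaleLayout:
    """A ladder of temporal scale levels and their stage time constants.

    Attributes
    ----------
    kind:
        ``"logarithmic"`` (geometric ladder, ratio ``c**2``) or ``"uniform"``.
    c:
        Distribution parameter (> 1) for logarithmic ladders; for uniform
        ladders stored as ``nan``.
    K:
        Number of smoothing stages.
    tau_levels:
        Strictly increasing temporal variances ``tau_k`` (time^2), one per
        stage output; ``tau_levels[-1] == tau_max``.
    mu_cont:
        Continuous-model time constants, ``sum(mu_cont**2) == tau_max``.
    mu_disc:
        Discrete recursive-filter time constants solving
        ``mu**2 + mu == delta_tau_k`` for each scale increment.
    tau_min, tau_max:
        Scale bounds (time^2).
    """

    kind: str
    c: float
    K: int
    tau_levels: np.ndarray
    mu_cont: np.ndarray
    mu_disc: np.ndarray
    tau_min: float
    tau_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_levels", np.asarray(self.tau_levels, float))
        object.__setattr__(self, "mu_cont", np.asarray(self.mu_cont, float))
        object.__setattr__(self, "mu_disc", np.asarray(self.mu_disc, float))
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        for arr in (self.tau_levels, self.mu_cont, self.mu_disc):
            if len(arr) != self.K:
                raise ValueError("layout arrays must have length K")
        if np.any(np.diff(self.tau_levels) <= 0):
            raise ValueError("tau_levels must be strictly increasing")

    @property
    def delta_tau(self) -> np.ndarray:
        """Scale increments ``tau_k - tau_{k-1}`` with ``tau_0 = 0``."""
        return np.diff(self.tau_levels, prepend=0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "c": None if math.isnan(self.c) else self.c,
                "K": self.K,
                "tau_max": self.tau_max,
                "tau_levels": self.tau_levels.tolist(),
                "mu_cont": self.mu_cont.tolist(),
                "mu_disc": self.mu_disc.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaleLayout":
        d = json.loads(text)
        tau = np.asarray(d["tau_levels"], float)
        return cls(
            kind=d["kind"],
            c=float("nan") if d["c"] is None else float(d["c"]),
            K=int(d["K"]),
            tau_levels=tau,
            mu_cont=np.asarray(d["mu_cont"], float),
            mu_disc=np.asarray(d["mu_disc"], float),
            tau_min=float(tau[0]),
            tau_max=float(d["tau_max"]),
        )


def logarithmic_levels(tau_max: float, c: float, K: int) -> ScaleLayout:
    """Geometric ladder ``tau_k = c**(2(k-K)) * tau_max`` for ``k = 1..K``.

    The continuous time constants follow from variance additivity:
    ``mu_1 = c**(1-K) * sqrt(tau_max)`` and
    ``mu_k = c**(k-K-1) * sqrt(c**2-1) * sqrt(tau_max)`` for ``k >= 2``,
    which telescopes so that ``sum(mu_k**2) == tau_max``.
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    if c <= 1:
        raise ValueError("distribution parameter c must be > 1")
    if K < 1:
        raise ValueError("K must be >= 1")
    k = np.arange(1, K + 1)
    tau = c ** (2.0 * (k - K)) * tau_max
    sq = math.sqrt(tau_max)
    mu = np.empty(K)
    mu[0] = c ** (1.0 - K) * sq
    if K > 1:
        mu[1:] = c ** (k[1:] - K - 1.0) * math.sqrt(c * c - 1.0) * sq
    mu_disc = discrete_time_constants(np.diff(tau, prepend=0.0))
    return ScaleLayout(
        kind="logarithmic",
        c=float(c),
        K=int(K),
        tau_levels=tau,
        mu_cont=mu,
        mu_disc=mu_disc,
        tau_min=float(tau[0]),
        tau_max=float(tau_max),
    )


def uniform_levels(tau_max: float, K: int) -> ScaleLayout:
    """Uniform ladder ``tau_k = (k/K) tau_max`` with equal time constants."""
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    k = np.arange(1, K + 1)
    tau = k / K * tau_max
    mu = np.full(K, math.sqrt(tau_max / K))
    mu_disc = discrete_time_constants(np.diff(tau, prepend=0.0))
    return ScaleLayout(
        kind="uniform",
        c=float("nan"),
        K=int(K),
        tau_levels=tau,
        mu_cont=mu,
        mu_disc=mu_disc,
        tau_min=float(tau[0]),
        tau_max=float(tau_max),
    )


def c_from_range(tau_min: float, tau_max: float, K: int) -> float:
    """Distribution parameter reaching ``tau_min`` at the first of K levels.

    ``c = (tau_max/tau_min) ** (1 / (2 (K-1)))``; feeding the result into
    :func:`logarithmic_levels` yields ``tau_levels[0] == tau_min``.
    """
    if K < 2:
        raise ValueError("K must be >= 2 to span a scale range")
    if not 0 < tau_min < tau_max:
        raise ValueError("need 0 < tau_min < tau_max")
    return float((tau_max / tau_min) ** (1.0 / (2.0 * (K - 1))))


def cascade_moments(mu_list) -> tuple[float, float]:
    """Temporal mean ``sum(mu_k)`` and variance ``sum(mu_k**2)`` of a cascade.

    The mean is a coarse measure of the temporal delay of the composed
    kernel; the variance is the temporal scale it reaches.
    """
    mu = np.asarray(mu_list, float)
    if mu.size == 0:
        raise ValueError("mu_list must be non-empty")
    if np.any(mu <= 0):
        raise ValueError("all time constants must be > 0")
    return float(mu.sum()), float(np.sum(mu * mu))


def discrete_time_constants(delta_tau) -> np.ndarray:
    """Solve ``mu**2 + mu == delta_tau`` for each scale increment.

    A first-order recursive filter with coefficient ``1/(1+mu)`` has
    discrete variance ``mu**2 + mu``, so this map makes the discrete
    cascade variances match the continuous scale levels exactly.
    """
    dt = np.asarray(delta_tau, float)
    if np.any(dt < 0):
        raise ValueError("scale increments must be non-negative")
    return (np.sqrt(1.0 + 4.0 * dt) - 1.0) / 2.0


def physical_to_sample_scale(sigma_t: float, r: float) -> float:
    """Convert a physical scale ``sigma_t`` [s] at frame rate ``r`` [1/s]
    to a temporal variance in squared sample units: ``tau = (r sigma_t)**2``."""
    if r <= 0:
        raise ValueError("frame rate must be > 0")
    if sigma_t < 0:
        raise ValueError("sigma_t must be >= 0")
    return float(r * r * sigma_t * sigma_t)
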