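"""Discrete, strictly time-recursive scale-space computation.

The discrete analogue of a first-order integrator is the normalized
first-order recursive filter

    y(t) - y(t-1) = (x(t) - y(t-1)) / (1 + mu),

which is a discrete scale-space kernel: it can never increase the number
of local extrema (or zero-crossings) of any input.  Chaining one such
filter per scale increment gives the discrete approximation of the
time-causal limit kernel; each stage's discrete variance ``mu**2 + mu``
matches its scale increment exactly, so the cascade variances equal the
continuous scale levels.

Computation needs no memory of the past beyond the per-stage outputs at
the previous sample -- the scale-space representation itself is the
temporal memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .layout import ScaleLayout, discrete_time_constants

__all__ = [
    "CascadeState",
    "ScaleSpaceArray",
    "step",
    "filter_signal",
    "impulse_response",
    "temporal_derivative",
    "temporal_jet",
    "count_local_extrema",
]


@dataclass
class CascadeState:
    """Per-stage last outputs; sufficient state for the next time step."""

    outputs: np.ndarray
    t_index: int = 0

    def __post_init__(self) -> None:
        self.outputs = np.asarray(self.outputs, float)


@dataclass
class ScaleSpaceArray:
    """Time x scale matrix ``L(t; tau_k)`` plus provenance.

    ``values[t, k]`` is the smoothed signal (or its derivative of order
    ``derivative_order``) at sample t and scale level ``tau_levels[k]``.
    The first ``derivative_order`` rows of a derivative stack are boundary
    samples without a full difference stencil and are set to NaN.
    """

    values: np.ndarray
    layout: ScaleLayout
    derivative_order: int = 0
    normalization: str = "none"
    gamma: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def step(state: CascadeState, sample: float, layout: ScaleLayout) -> CascadeState:
    """Advance the cascade by one sample.

    Stage k sees the output of stage k-1 at the current sample (stage 1
    sees the input) and updates ``y_k += (in_k - y_k) / (1 + mu_k)``.
    """
    if len(state.outputs) != layout.K:
        raise ValueError("state length does not match layout K")
    y = state.outputs.copy()
    incoming = float(sample)
    # same arithmetic as the batch lfilter route, so streaming and batch
    # computation agree bit-for-bit
    for k, mu in enumerate(layout.mu_disc):
        alpha = 1.0 / (1.0 + mu)
        y[k] = alpha * incoming + (1.0 - alpha) * y[k]
        incoming = y[k]
    return CascadeState(outputs=y, t_index=state.t_index + 1)


def _run_single_stage(x: np.ndarray, mu: float, y0: float) -> np.ndarray:
    """One recursive stage over a whole signal, previous output y0."""
    alpha = 1.0 / (1.0 + mu)
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    zi = np.array([(1.0 - alpha) * y0])
    y, _ = _signal.lfilter(b, a, x, zi=zi)
    return y


def filter_signal(
    signal,
    layout: ScaleLayout,
    mode: str = "cascade",
    init: str = "first_sample",
) -> ScaleSpaceArray:
    """Filter a signal through the recursive-filter ladder.

    mode="cascade" chains the stages (each scale level is a formal
    simplification of the previous one); mode="parallel" runs one
    single-stage filter per scale level, with its time constant solving
    ``mu**2 + mu = tau_k`` so the discrete variances match.

    init="first_sample" seeds every stage with signal[0], making constants
    exact fixed points; init="zero" is the natural choice for impulse
    responses.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if init not in ("first_sample", "zero"):
        raise ValueError("init must be 'first_sample' or 'zero'")
    y0 = float(x[0]) if init == "first_sample" else 0.0
    out = np.empty((x.size, layout.K))
    if mode == "cascade":
        current = x
        for k, mu in enumerate(layout.mu_disc):
            current = _run_single_stage(current, mu, y0)
            out[:, k] = current
    elif mode == "parallel":
        mus = discrete_time_constants(layout.tau_levels)
        for k, mu in enumerate(mus):
            out[:, k] = _run_single_stage(x, mu, y0)
    else:
        raise ValueError("mode must be 'cascade' or 'parallel'")
    return ScaleSpaceArray(values=out, layout=layout)


def impulse_response(
    layout: ScaleLayout, mass_tol: float = 1e-10, mode: str = "cascade"
) -> list[np.ndarray]:
    """Materialize the discrete kernels of each scale level.

    Each kernel is the response to a unit impulse (zero initial state),
    truncated once its cumulative mass reaches ``1 - mass_tol``.  The
    kernels are non-negative, sum to ~1 and the variance of kernel k
    equals ``tau_k`` up to the truncated tail.
    """
    if not 0 < mass_tol < 1:
        raise ValueError("mass_tol must be in (0, 1)")
    # initial length guess: delay + many standard deviations of the top scale
    length = int(np.sum(layout.mu_disc) + 20.0 * np.sqrt(layout.tau_max)) + 8
    while True:
        x = np.zeros(length)
        x[0] = 1.0
        ss = filter_signal(x, layout, mode=mode, init="zero")
        if ss.values[:, -1].sum() >= 1.0 - mass_tol:
            break
        length *= 2
    kernels = []
    for k in range(layout.K):
        col = ss.values[:, k]
        cum = np.cumsum(col)
        stop = int(np.searchsorted(cum, 1.0 - mass_tol)) + 1
        kernels.append(col[:stop].copy())
    return kernels


_D1 = np.array([-1.0, 1.0])
_D2 = np.array([1.0, -2.0, 1.0])


def difference_kernel(kernel, order: int) -> np.ndarray:
    """Temporal difference of a causal FIR kernel.

    Unlike signal columns, a kernel is known to vanish for t < 0, so the
    difference is well-defined from t = 0 on: convolve with the stencil
    [1, -1] (and [1, -2, 1] for pairs of orders)."""
    out = np.asarray(kernel, float)
    remaining = order
    while remaining >= 2:
        out = np.convolve(out, [1.0, -2.0, 1.0])
        remaining -= 2
    if remaining == 1:
        out = np.convolve(out, [1.0, -1.0])
    return out


def _apply_difference(values: np.ndarray, order: int) -> np.ndarray:
    """Backward-aligned temporal differences; composed from the first- and
    second-order stencils (-1,+1) and (1,-2,1) for higher orders."""
    out = values.astype(float)
    remaining = order
    while remaining >= 2:
        padded = np.full_like(out, np.nan)
        padded[2:] = out[2:] - 2.0 * out[1:-1] + out[:-2]
        out = padded
        remaining -= 2
    if remaining == 1:
        padded = np.full_like(out, np.nan)
        padded[1:] = out[1:] - out[:-1]
        out = padded
    return out


def temporal_derivative(ss: ScaleSpaceArray, order: int) -> ScaleSpaceArray:
    """Temporal difference derivative of a scale-space array.

    Differences are aligned to the later sample; the first ``order``
    samples of each column lack a full stencil and are NaN.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order == 0:
        return ScaleSpaceArray(
            values=ss.values.copy(),
            layout=ss.layout,
            derivative_order=ss.derivative_order,
            normalization=ss.normalization,
            gamma=ss.gamma,
        )
    vals = _apply_difference(ss.values, order)
    return ScaleSpaceArray(
        values=vals,
        layout=ss.layout,
        derivative_order=ss.derivative_order + order,
        normalization=ss.normalization,
        gamma=ss.gamma,
    )


def temporal_jet(ss: ScaleSpaceArray, N: int, gamma: float = 1.0) -> list[ScaleSpaceArray]:
    """Scale-normalized derivatives of orders 0..N (the temporal N-jet)."""
    from .norms import NormalizationSpec, normalize

    if N < 0:
        raise ValueError("N must be >= 0")
    jets = []
    for n in range(N + 1):
        deriv = temporal_derivative(ss, n)
        if n > 0:
            deriv = normalize(deriv, NormalizationSpec(scheme="variance", gamma=gamma, n=n))
        jets.append(deriv)
    return jets


def count_local_extrema(signal) -> int:
    """Number of local extrema, with runs of equal values collapsed.

    A plateau flanked by lower (or higher) values counts as one extremum;
    this makes the non-creation guarantee checkable on quantized data.
    """
    x = np.asarray(signal, float)
    if x.size < 3:
        return 0
    collapsed = x[np.concatenate(([True], np.diff(x) != 0.0))]
    if collapsed.size < 3:
        return 0
    s = np.sign(np.diff(collapsed))
    return int(np.sum(s[1:] != s[:-1]))
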