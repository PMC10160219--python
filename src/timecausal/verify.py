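"""Quick self-checks of the core invariants, used by the CLI ``verify``
command.  Each check returns (name, passed, detail)."""

from __future__ import annotations

import numpy as np

from . import cascade, fitting, kernels, layout, synth

__all__ = ["run_invariant_suite"]


def _check_variance_additivity():
    lay = layout.logarithmic_levels(16.0, 2.0, 3)
    mean, var = layout.cascade_moments(lay.mu_cont)
    ok = abs(var - lay.tau_max) < 1e-12
    return ok, f"sum mu^2 = {var:.12g} vs tau_max = {lay.tau_max}"


def _check_discrete_variances():
    lay = layout.logarithmic_levels(16.0, 2.0, 3)
    kernels_d = cascade.impulse_response(lay, mass_tol=1e-12)
    worst = 0.0
    for k, kern in enumerate(kernels_d):
        t = np.arange(kern.size)
        m = np.sum(t * kern)
        v = np.sum(t * t * kern) - m * m
        worst = max(worst, abs(v - lay.tau_levels[k]) / lay.tau_levels[k])
    return worst < 1e-6, f"max relative variance error {worst:.3g}"


def _check_non_creation():
    rng = np.random.default_rng(12345)
    for c in (np.sqrt(2.0), 2.0):
        for trial in range(10):
            n = int(rng.integers(64, 1024))
            x = synth.wiener_process(n, seed=int(rng.integers(2**31)))
            lay = layout.logarithmic_levels(256.0, c, 6)
            ss = cascade.filter_signal(x, lay)
            counts = [cascade.count_local_extrema(x)] + [
                cascade.count_local_extrema(ss.values[:, k]) for k in range(lay.K)
            ]
            if np.any(np.diff(counts) > 0):
                return False, f"extrema increased (c={c:.3g}, trial={trial})"
    return True, "extrema counts non-increasing on 20 random signals"


def _check_moment_map_roundtrip():
    p = kernels.LimitKernelParams(tau=9.0, c=2.0)
    mean = kernels.limit_kernel_mean(p)
    moments = fitting.MomentSet(M0=1.0, M1=mean, M2=p.tau + mean * mean)
    model = fitting.fit_limit_kernel(moments)
    ok = abs(model.tau - p.tau) < 1e-10 and abs(model.c - p.c) < 1e-10
    return ok, f"recovered tau={model.tau:.6g}, c={model.c:.6g}"


def run_invariant_suite() -> list[tuple[str, bool, str]]:
    checks = [
        ("variance additivity", _check_variance_additivity),
        ("discrete-continuous variance match", _check_discrete_variances),
        ("non-creation of structure", _check_non_creation),
        ("moment-map round trip", _check_moment_map_roundtrip),
    ]
    results = []
    for name, fn in checks:
        try:
            ok, detail = fn()
        except Exception as exc:  # pragma: no cover - defensive
            ok, detail = False, f"error: {exc}"
        results.append((name, ok, detail))
    return results
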