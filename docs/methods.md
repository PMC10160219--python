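# Methods

## Model

`timecausal` implements multi-scale smoothing of temporal signals under
two hard constraints: the filters may not look into the future
(*time-causality*), and the only admissible memory of the past is the
multi-scale representation itself (*time-recursivity*). Under the
additional requirement that smoothing must never increase the number of
local extrema (equivalently zero-crossings) of any input — the defining
scale-space property — the only causal smoothing primitive over
continuous time is the truncated exponential

    h(t; mu) = exp(-t/mu)/mu   for t >= 0,   0 otherwise,

a first-order integrator with time constant `mu`. All admissible causal
scale-space kernels are cascades of these. The composed kernel of K
stages has temporal mean `sum(mu_k)` (a delay measure) and variance
`tau = sum(mu_k**2)` (the temporal scale).

### Scale ladders

Two distributions of the intermediate scale levels are provided
(`timecausal.layout`):

* **logarithmic** — `tau_k = c**(2(k-K)) tau_max` with distribution
  parameter `c > 1`; adjacent levels are related by the constant factor
  `c**2`, i.e. uniform spacing in effective scale `log tau`;
* **uniform** — `tau_k = (k/K) tau_max`, all stages equal, whose composed
  kernel is the Gamma density `t**(K-1) e^{-t/mu} / (mu**K (K-1)!)`.

The logarithmic ladder is the interesting one: as K → ∞ it converges to
the **time-causal limit kernel** `Psi(t; tau, c)` with Fourier transform

    Psi_hat(omega; tau, c) = prod_{k=1..inf} 1 / (1 + i c^{-k} sqrt(c^2-1) sqrt(tau) omega),

which is scale-covariant: rescaling the input by any integer power of c
maps the representation onto itself with a shift along the scale
dimension. `Psi` has no compact time-domain form; `kernels` evaluates it
by two independent numerical routes (partial-fraction expansion into a
weighted sum of exponentials, and FFT inversion of the truncated Fourier
product) which are cross-validated against each other in the tests. Its
skewness and excess kurtosis are closed forms in c alone,
`gamma1 = 2(c+1)sqrt(c^2-1)/(c^2+c+1)` and `gamma2 = 6(c^2-1)/(c^2+1)`,
which the moment-fitting code exploits.

### Discrete implementation

On sampled data each continuous integrator becomes the normalized
first-order recursive filter

    y(t) - y(t-1) = (x(t) - y(t-1)) / (1 + mu_k),

the discrete scale-space kernel with variance `mu_k**2 + mu_k`. Stage
time constants are chosen by inverting that relation against the scale
increments, `mu_k = (sqrt(1 + 4 dtau_k) - 1)/2`, so the discrete
variances match the continuous scale levels *exactly* (the means differ
slightly; that is the price of discreteness). Derivatives are backward
differences `(-1, +1)` and `(1, -2, 1)` applied to the smoothed columns;
higher orders compose these.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `c` | ratio between adjacent scale levels (std.-dev. units is `c`, variance units `c**2`) | 2 (sqrt(2) also standard) | larger c → shorter delays; smaller c → denser scale sampling |
| `K` | cascade depth used to approximate the limit kernel | 8 | 4–8 stages suffice for the geometric tail (missing variance `tau * c**(-2K)`) |
| `tau` | temporal scale = kernel variance, squared sample units | — | converted from physical seconds only at the I/O boundary via `tau = (r sigma_t)**2` |
| `gamma` | scale-normalization power for derivatives | 1 | `gamma = 1` (p = 1) gives fully scale-invariant derivative magnitudes |
| `mass_tol` | truncation mass for materialized impulse responses | 1e-10 (1e-12 in variance checks) | tail mass bounds the variance error |

## Scale-normalized derivatives

Raw derivative amplitudes decay with smoothing. Two normalizations are
implemented (`norms`): variance-based, multiplying order-n derivatives by
`tau**(n*gamma/2)`; and Lp-based, scaling the discrete derivative kernel
to match the Lp norm of the *gamma-normalized* Gaussian derivative, with
`p = 1/(1 + n(1-gamma))`. The reference norm `G_{n,gamma}` is constant
over scales by construction (that is what gamma-normalization achieves),
so the Lp factor grows like `tau**(n*gamma/2)` times a shape constant and
the two schemes agree up to that constant. Closed forms are used for the
L1 norms of the first two Gaussian derivatives, quadrature otherwise,
with caching. For `p < 1` the quasi-norm `(sum |x|**p)**(1/p)` is used
without claiming the triangle inequality.

## Moment-based model fitting

The fitting module maps between four models of unimodal causal
responses by matching temporal moments over `t in [0, inf)`:

* **ex-Gaussian → limit kernel** (second order): with `delta = M1/M0`
  and `V = M2/M0 - delta**2`, the map is `b1 = M0`, `tau = V`,
  `c = (delta^2+V)/(delta^2-V)`, feasible iff `delta^2 > V`. The
  half-line restriction of the moments is essential: the ex-Gaussian
  carries Gaussian mass below t = 0, and full-line moments give visibly
  different (wrong) parameters whenever sigma is not small against m.
  The half-line moments are closed forms in erf/exp (half-line Gaussian
  moments plus integration by parts against the exponential), verified
  against adaptive quadrature at 1e-8 relative.
* **offset fit** (third order): `tau = V` and `b1 = M0` as before; c is
  recovered by root-finding the analytic skewness `gamma1(c)` (strictly
  monotone on (1, inf), range (0, 2)) against the sample skewness with
  bracketing on c in (1, 100]; the temporal offset is the residual mean
  shift `t0 = delta - sqrt(tau (c+1)/(c-1))`. Data whose skewness falls
  outside (0, 2) is reported as infeasible rather than clamped.
* **generic signals**: trapezoidal moments of non-negative sampled data
  feed the same maps; a relative L2 residual against the fitted kernel is
  returned as a diagnostic.
* **Koenderink scale-time ↔ limit kernel**: matching first and second
  moments gives `sigma = sqrt(log(2c/(c+1)))` (bounded by
  `sqrt(log 2) ≈ 0.832` as c → inf) and
  `delta = (c+1)^2 sqrt(tau) / (2 sqrt(2) sqrt((c-1) c^3))`; delta also
  serves as a (slightly over-estimating) predictor of the limit kernel's
  peak location. Note the scale-time kernel places its Gaussian in log
  time *without* a 1/t Jacobian, so its mode is exactly delta and its
  mean `delta e^{3 sigma^2/2}`.

## Wavelets and time-frequency analysis

Temporal derivatives of the limit kernel integrate to zero and have
finite L1 and L2 norms, so after normalization they are admissible
mother wavelets. Restricting dilations to `a = c**j` puts the whole
transform inside the cascade algebra: the bank's child wavelets are
materialized as order-n differences of the cascade's own per-level
impulse responses (with K-1 extra sub-scale stages below the finest
analysis scale so every level is a deep limit-kernel approximation), and
the transform itself is computed strictly time-recursively — one
recursive filter per extra scale plus a difference stencil. The
recursive and direct-convolution routes agree to ~1e-12.

The time-causal Gabor analogue is `chi(t, omega) = Psi(t) e^{i omega t}`;
the windowed transform `S(t, omega) = sum_u f(t-u) Psi_d(u) e^{i omega u}`
uses the mass-truncated discrete window. The time-recursive spectrogram
instead filters the demodulated signal `f(t) e^{-i omega t}` through the
real cascade (real and imaginary parts separately); by the demodulation
identity its output is `e^{-i omega t} S(t, omega)` exactly, so
magnitudes are preserved and phases are restored by a-posteriori
multiplication with `e^{+i omega t}`. The default omega grid is
logarithmic, matching the scale-covariance structure.

## Synthetic signals

The generator module (`synth`) reproduces the standard study inputs:
Wiener-process paths (cumulative Gaussian increments), the
frequency-varying sine `sin(exp((b-t)/a))` with defaults a = 200,
b = 1000, and a two-peak signal of unit-mass limit-kernel events at
tau = 16 and tau = 256 plus white Gaussian noise (default sd 1% of the
taller peak, delay 512 samples — the published description states only
"a small amount" of noise and "a certain" delay, so these are labelled
reconstructions and asserted through qualitative properties only).
Temporal rescaling for covariance experiments is realized by integer
subsampling, never interpolation (which is formally ill-defined on a
discrete grid). All generators are pure functions of (parameters, seed).

What the generators do *not* emulate: real measurement noise spectra,
non-uniform sampling, amplitude drift, or aliased content. On that last
point: the commutative-diagram checks only close for band-limited
signals, since subsampling an aliased segment cannot commute with
smoothing — with the published sine parameters the instantaneous
frequency exceeds pi rad/sample over the early segment, so the
covariance harness uses a band-limited parameterization of the same
family. Passing tests therefore demonstrate the discrete implementation's
fidelity to the continuous theory, not robustness to arbitrary real-world
recordings.

## Numerical choices

* Partial-fraction coefficients `A_k = prod_{i != k} 1/(1 - c**(k-i))`
  are accumulated smallest-factor-first; for `c < 1.2` the decomposition
  is ill-conditioned and evaluation silently falls back to the FFT route.
* Cascade state is initialized to the first sample by default, making
  constants exact fixed points; zero initialization is used for impulse
  responses, wavelets and spectrograms.
* The first `order` samples of a derivative stack are NaN (no full
  stencil) rather than zero-padded.
* Streaming (`step`) and batch (`filter_signal`) use identical floating-
  point arithmetic and agree bit-for-bit.
* Extrema counting collapses runs of equal values first, so plateaus
  count once and the non-creation guarantee is checkable on quantized
  data.
* Startup transients excluded from steady-state comparisons span the
  kernel delay plus five standard deviations; scale-covariance
  assertions use 3% tolerance at tau >= 64 squared samples (finite-K and
  sampling error), measured at ~0.1-0.3% in practice.
* Parallel-channel mode solves `mu**2 + mu = tau_k` per channel (the
  discrete variance), diverging deliberately from the continuous
  statement `mu = sqrt(tau_k)` for consistency with the cascade's
  discrete calibration.

## Problem sizes

The covariance and invariance checks run on signals of 8192–16384
samples at scales up to `tau = 4096` squared samples with K = 8 stages;
the non-creation sweep uses 102 random signals of 64–4096 samples; the
fitting recovery tests sample kernels on grids of 2e5 points. The full
suite completes in a few seconds on one core.

## Known limitations

* No automatic selection of K, c, or of scales from data (scale
  selection is out of scope).
* Non-uniform sampling and mid-stream layout changes are unsupported.
* The Lp-based normalization implements only the Gaussian-derivative
  reference norm.
* Reconstruction/inverse transforms for the wavelet and time-frequency
  representations are not provided.
* Fitting assumes noiseless or lightly-noised unimodal data; there is no
  likelihood machinery or uncertainty quantification.
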