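# timecausal

Time-causal, time-recursive multi-scale analysis of temporal signals.

Smoothing a signal for multi-scale analysis is easy offline — convolve
with Gaussians. In real-time settings (streaming sensor data, audio,
neural recordings, any model of a perceptual system) that is impossible:
the Gaussian looks into the future, and buffering the past contradicts
how physical and biological systems actually integrate information. The
only causal smoothing primitive that is guaranteed never to create new
structure — never to increase the number of local extrema of any input —
is the truncated exponential `h(t; mu) = e^{-t/mu}/mu`, a first-order
integrator. This package implements the full theory built on that fact,
for signal-processing practitioners and computational neuroscientists
modelling temporal receptive fields:

* **Recursive-filter cascades** (`timecausal.cascade`): strictly
  time-recursive scale-space computation `y_k(t) = y_k(t-1) +
  (in_k(t) - y_k(t-1))/(1 + mu_k)`, streaming or batch, with logarithmic
  or uniform scale ladders (`timecausal.layout`).
* **The time-causal limit kernel** `Psi(t; tau, c)`
  (`timecausal.kernels`): the infinite cascade with geometric time
  constants `mu_k = c^{-k} sqrt(c^2-1) sqrt(tau)`, the unique causal
  scale-space kernel that is also *scale-covariant* — rescaling the
  input by `c^j` shifts the representation j levels along the scale axis.
* **Scale-normalized derivatives** (`timecausal.norms`):
  `tau^{n gamma/2}`-weighted or Lp-norm-matched temporal derivatives;
  with `gamma = 1` derivative magnitudes are comparable, and invariant,
  across scales.
* **Moment-based model fitting** (`timecausal.fitting`): closed-form
  maps between the limit-kernel model `b0 + b1 Psi(t - t0; tau, c)`, the
  ex-Gaussian (exponentially modified Gaussian) model widely used for
  neural response functions, and Koenderink's scale-time kernel.
* **Time-causal wavelets and spectrograms** (`timecausal.timefreq`):
  zero-mean limit-kernel derivatives as mother wavelets computed inside
  the cascade algebra, and a time-recursive spectrogram with a-posteriori
  phase compensation — a causal analogue of the Gabor transform.
* **Synthetic test signals** (`timecausal.synth`): Wiener paths,
  frequency-varying sines, two-scale event trains, and the
  subsampling-based scale-covariance harness.

## Worked example

Fit the limit-kernel model to an ex-Gaussian response kernel with
exponential time constant mu = 4, Gaussian width sigma = 1/2 and
position m = 2 (amplitude 1), by matching half-line temporal moments:

```sh
$ timecausal fit-exgauss --mu 4 --sigma 0.5 --m 2 --a1 1
{"b0": 0.0, "b1": 5.0132521895947635, "t0": 0.0, "tau": 16.249981675782728, "c": 2.645560926858271}
```

The fitted temporal scale `tau ≈ 16.25` is the kernel's variance in
squared sample units, `c ≈ 2.65` is the ratio between adjacent scale
levels of the equivalent cascade (larger c = faster, less delayed
dynamics), and `b1 ≈ 5.01` is the amplitude `M0`, the kernel's total
mass. The same maps work on raw sampled data:

```sh
$ timecausal kernel --tau 4 -o k.tsv          # sample Psi(t; 4, 2) on a grid
$ timecausal fit-signal k.tsv
{"b0": 0.0, "b1": 0.9999995490789872, "t0": 0.0, "tau": 3.9997019739049495,
 "c": 1.999898290660962, "diagnostics": {"relative_l2_residual": 3.35956119969081e-05}}
```

which recovers the generating parameters (tau, c) = (4, 2) to four
digits. Library use mirrors the CLI:

```python
import numpy as np
from timecausal import logarithmic_levels, filter_signal, wiener_process

lay = logarithmic_levels(tau_max=256.0, c=2.0, K=8)
L = filter_signal(wiener_process(4096, seed=1), lay)   # 4096 x 8 matrix
```

Other subcommands: `scalespace`, `derivatives`, `jet`, `wavelet`,
`spectrogram`, `synth`, and `verify` (runs the invariant self-checks and
exits nonzero on failure). See `docs/methods.md` for the model, the
parameter conventions and the numerical choices.

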