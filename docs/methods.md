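# Methods

## Signal model

A dual-axis swallowing accelerometry recording is modelled per axis as
`g(n) = g_LF(n) + s(n) + w(n)`: a low-frequency head-motion component, a
swallowing-activity component, and additive white Gaussian noise. The
package estimates `g_LF` by least-squares spline approximation and removes
it; everything else (synthetic generation, baselines, scoring) exists to
quantify how well that works.

## B-spline machinery

`continuous_bspline` evaluates the centred B-spline of degree `n` by the
two-term recursion on degree, starting from the symmetric unit indicator
(value 1/2 at |x| = 1/2). This keeps arbitrary degrees available without a
piecewise-polynomial table. The discrete kernel `b^n_m` holds the samples
of the degree-`n` spline stretched by the integer factor `m`. When `m` and
`n` are both even no lattice point coincides with the kernel centre; the
samples are then taken on the half-shifted lattice `(i + 1/2)/m`, which is
exactly the convention under which the moving-average convolution identity
(the `(n+1)`-fold convolution of the width-`m` moving average with the
unit-lattice kernel, scaled by `m^-n`) reproduces the sampled kernel
tap-for-tap. Both construction routes are implemented and cross-checked;
analysis (correlation) and synthesis (convolution) use the same kernel, so
the half-sample phases cancel.

`direct_transform` computes interpolation coefficients by an exact banded
solve of the `b^n_1` Toeplitz system rather than the truncated recursive
filter, so the `m = 1` round trip is exact to solver precision.

### Boundary convention

All operations extend by whole-sample mirror reflection (zero-padding is
available). The reflection is applied to the *coefficient index* (period
`2M - 2`): the basis near an edge is symmetrised by folding in the mirrored
partners of each basis function, restricted to the signal domain. One
convention for analysis, the Gram operator and synthesis makes the
least-squares fit the exact orthogonal projection onto that space —
idempotent, energy-contracting, with residual orthogonal to every basis
function — and makes the filtering path agree with the explicit
normal-equations oracle at every knot, not only in the interior.
Constants are reproduced exactly up to the signal ends.

## Least-squares projection

Coefficient `k` is anchored at sample `k·m + m//2`, so degree 0 reduces to
exact block averaging (a hand-checkable special case used as an anchor for
the Gram normalisation). The Gram band is the *discrete* autocorrelation of
the kernel taps at knot lags — the exact normal-equations band — rather
than the continuous-domain `b^(2n+1)` samples it approximates; near edges
the band entries are corrected for the boundary symmetrisation. The system
is solved directly (`solveh_banded`), no iterative methods. When the
signal length is not a multiple of `m`, the final knot interval is partial
and handled by the same boundary convention in both the filtering path and
the oracle; `M = (N - 1)//m + 1` throughout.

Convolutions switch to FFT form above ~5·10^5 operations; small problems
keep direct convolution, so precision-critical tests are unaffected.

## Choosing the resampling frequency

`f_r` must exceed twice the head-motion band edge (band default 0-2 Hz,
giving the conservative default `f_r = 4` Hz) yet stay far below the
swallowing band. The Strang-Fix bound makes the approximation error of a
smooth trend decay like the fourth power of the knot spacing for cubic
splines, which the error-decay check measures directly (slope of log
interior RMS error against log `f_r`; boundary samples are excluded
because the mirror reflection introduces a derivative kink whose local
error does not follow the interior rate). Degree 3 is the default: higher
orders gain little accuracy and cost more.

The sweep experiment calibrates `f_r` empirically: per noise level and
realization it selects the grid frequency minimising trend MSE
(grid 0.5-10 Hz in 0.25 Hz steps). Downstream experiments use the per-axis
mean of these optima. A known property of this synthetic model is that the
optimum drifts upward as noise falls: it balances approximation bias
(falling steeply with `f_r`) against leakage of noise and swallowing energy
into the trend space (growing like `f_r/f_s`), and the balance point moves
when the noise power changes. At desk scale the per-SNR mean optimum rises
from about 5 Hz at 0 dB to about 8 Hz at 30 dB, and a Kruskal-Wallis test
across SNR groups detects this reliably; the effect persists at a 10 kHz
sampling rate. The sweep reports the test so the drift is visible rather
than hidden.

## Baseline detrenders

* **SPM** (smoothness priors): per-subinterval solve of
  `min ||y - z||^2 + lam^2 ||D2 z||^2` with the second-difference operator
  `D2`; pentadiagonal banded solve. `lam` maps to an equivalent -3 dB
  cutoff via `lam = 1/(2 sin(pi f_c / f_s))^2`; experiments set the cutoff
  to the spline's `f_r`. 1000 subintervals by default (whole-signal mode:
  `n_subintervals=1`).
* **PPF**: per-subinterval ordinary least-squares polynomials, degree 2,
  5000 subintervals, solved as one batched hat-matrix product. On 40 s
  recordings the 1000/5000 counts give 40 ms and 8 ms blocks at any
  sampling rate, matching the study protocol's block durations.
* **EMD**: in-package sifting — cubic-spline envelopes through maxima and
  minima with the two outermost extrema mirrored past each end; a mode is
  accepted when the normalised successive-difference criterion drops below
  0.05 or after 50 sifts; at most 12 modes. The trend is the residue plus
  every mode whose zero-crossing mean frequency falls below `f_r/2`.
  Monotone inputs yield trend = signal. Reconstruction (modes + residue =
  input) is exact by construction.

Every method returns trend and residual with `trend + residual = input` to
machine precision.

## Synthetic generator

The generator reproduces the *statistical* structure of recorded signals,
not their physiology: activity regions have higher variance than baseline.
Per axis:

* **Head motion**: 3 sinusoids, frequencies uniform on 0-2 Hz, phases
  uniform, amplitudes uniform on (0, 1) then rescaled to unit total
  (configurable: `amp_constraint="none"` keeps raw draws). The band,
  component count and amplitude scale are configuration, not constants.
* **Swallows**: baseline Gaussian noise (sd 0.1) with five disjoint
  events of duration uniform on 0.5-1.5 s; event content is white noise
  band-passed to 10-100 Hz (zero-phase fourth-order Butterworth) and scaled
  to a variance multiplier uniform on 5-20 times baseline. The event
  layout is drawn once per recording and shared by both axes.
* **Noise**: white Gaussian at a target SNR defined against the mean power
  of the noise-free composite (trend + swallows); the realized SNR is
  recorded in the output metadata.

Default duration 40 s at 1 kHz (the hardware profile, 10 kHz, is a config
field; all frequencies are absolute so results are rate-invariant except
for the leakage term noted above). One seeded generator drives each
recording; experiment drivers spawn per-realization generators from a
master seed, so every experiment is bit-reproducible.

What passing tests on this generator do *not* show: performance on real
swallows (whose spectra, non-stationarity and artifacts are richer), or on
head motions that are bursty rather than smoothly oscillatory.

## Evaluation

MSE is the mean squared difference between true and estimated trend; NMSE
divides by the mean power of the true trend, so the all-zero estimator
scores exactly 1. The comparison experiment runs two conditions: redraw
everything per realization, or freeze trend and swallows at the master
seed and redraw only noise. Rank tests (Mann-Whitney, Kruskal-Wallis) come
from scipy.stats with tie handling; degenerate inputs (identical pooled
samples) return p = 1. Desk-scale experiment profiles use 20-50
realizations and a coarse SNR grid; the full-scale protocol (1 dB grid,
100/500 realizations) sits behind the CLI's `--paper-scale` flag.

## Segmentation and DFA

The swallow segmenter thresholds a sliding-window variance track
(window 0.2 s) at `median + 6·MAD`, merges marked windows, and drops
events shorter than 0.3 s. It deliberately replaces the more elaborate
fuzzy-clustering segmenters of the literature: the before/after comparison
only needs one consistent detector applied to both versions of a signal.
Scoring assigns each detected interval to the true swallow it overlaps
most; a swallow is correct (CSS) when the union of its assigned detections
covers more than 90% of its duration, detections overlapping no swallow
are false positives, missed swallows false negatives. Whether fragments
may jointly cover one swallow was an open choice; the union rule is used.

DFA integrates the mean-removed signal, removes per-window linear fits at
20 log-spaced scales from 10 samples to N/4 (windows taken from both ends
of the profile), and fits the log-log slope of the RMS fluctuation. White
noise gives alpha ~ 0.5 and a random walk ~ 1.5, which the calibration
checks reproduce. Head-motion trends inflate alpha; removing them lowers
it. Note that detrending is a high-pass operation, so alpha also drops
slightly on trendless noise — segmentation scores, not alpha, are the
neutral quantity in the no-trend control.

The before/after study uses recordings with doubled trend amplitude
("strong trends"): at that amplitude steep trend slopes trigger spurious
variance detections away from true events, so head motions produce both
false positives and false negatives, and removal reduces both. At unit
amplitude the smooth trend produces only false negatives.

## Numerical choices and limitations

* Tolerances: kernel construction routes agree to 1e-10; filtering path vs
  oracle to 1e-8; projections idempotent to 1e-10; reconstruction
  identities to 1e-12.
* Degenerate inputs: monotone signals yield no EMD modes (trend = signal);
  blocks shorter than 3 samples pass through SPM unchanged; zero signals
  detrend to zero.
* The event packer rejects configurations whose total event duration
  cannot fit disjointly (bounded retries, then an error).
* The brute-force least-squares oracle is guarded to N <= 1e5, M <= 1e3.
* Rational (non-integer) resampling factors, fractional-delay splines and
  smoothing splines are out of scope; smoothing splines in particular keep
  one coefficient per sample, which defeats the purpose of the coarse-knot
  representation.
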