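# splinedetrend

Removal of low-frequency head-motion components from dual-axis swallowing
accelerometry signals by least-squares B-spline approximation, with the
surrounding simulation study: a synthetic signal generator with ground
truth, three baseline detrenders (smoothness priors, piecewise polynomials,
empirical mode decomposition), Monte-Carlo accuracy experiments, swallow
segmentation scoring and detrended fluctuation analysis.

## The problem

Swallowing accelerometry measures neck-surface vibrations on the
anterior-posterior (A-P) and superior-inferior (S-I) axes as a non-invasive
screen for dysphagia. A recorded signal decomposes as

    g(n) = g_LF(n) + s(n) + w(n)

where `g_LF` is a low-frequency component caused by head movements, `s` the
vibrations of swallowing activity and `w` additive white Gaussian noise.
Head motions distort signal amplitudes, degrade automatic swallow
segmentation and inflate the apparent statistical persistence of the
signal, so `g_LF` should be estimated and removed before any downstream
processing.

## The method

The head-motion component is approximated by the orthogonal projection of
the signal onto the space of cubic B-splines on a coarse, equally spaced
knot lattice. The knot rate — a resampling frequency `f_r` far below the
swallowing band but at least twice the head-motion band edge — fixes the
decimation factor `m = round(f_s / f_r)` and knot count
`M = (N - 1) // m + 1`. The projection is computed by a three-step
filtering procedure:

1. **prefilter**: correlate the signal with the expanded discrete B-spline
   `b^n_m` (samples of the degree-`n` B-spline stretched by `m`);
2. **decimate**: keep every `m`-th correlation value (the knot positions);
3. **postfilter**: solve the banded symmetric positive-definite Gram
   system — the sampled autocorrelation of `b^n_m` — for the expansion
   coefficients `c(k)`.

The trend estimate is the indirect spline transform of `c` (zero-insertion
upsampling followed by convolution with `b^n_m`), and the detrended signal
is `g − ĝ_LF`. By the Strang-Fix theory the approximation error of a smooth
trend decays like the (n+1)-th power of the knot spacing, so cubic
(fourth-order) splines give rapid convergence at modest cost.

## Worked example

```python
import numpy as np
import splinedetrend as sd

cfg = sd.SyntheticConfig(snr_db=10.0, seed=7)   # 40 s at 1 kHz
rec, truth = sd.gen_recording(cfg)

det = sd.spline_detrend(rec.ap, cfg.f_s, f_r=4.0)
print("knots:", det.params_used["M"])
print("trend NMSE:", round(sd.nmse(truth.trend["ap"], det.trend), 4))
print("reconstruction error:",
      float(np.abs(det.trend + det.residual - rec.ap).max()))

events = sd.segment_swallows(det.residual, cfg.f_s)
print(sd.score_segmentation(truth.events, events))
```

This prints:

```
knots: 160
trend NMSE: 0.0179
reconstruction error: 2.220446049250313e-16
SegmentationScore(tns=5, css=5, nfp=1, nfn=0)
```

i.e. the spline captures the simulated head motion to 1.8% normalised
error, the trend/residual decomposition is exact to machine precision, and
all five simulated swallows are correctly segmented from the detrended
axis (with one spurious detection at this noise level).

The same operations are available from the shell:

```sh
splinedetrend simulate --seed 7 --out rec.csv
splinedetrend process rec.csv --method spline --fr-ap 4 --fr-si 4 --out det.csv
splinedetrend experiment compare --seed 0 --out compare.csv
```

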