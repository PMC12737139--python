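# Methods

## Model and procedure

`aldtf` implements reference-free wavelet shrinkage for quasi-periodic
signals.  The pipeline is:

1. **Decompose** the noisy signal y_in(n) to depth J with a discrete wavelet
   transform.  Default wavelet: bior6.8 (symmetric, near-linear phase —
   preserves QRS/ST morphology); default boundary handling: symmetric
   half-point extension, recorded in the decomposition metadata so round
   trips are exact to ~1e-10.
2. **Threshold each detail layer** D_j with the tanh rule
   ŵ = sgn(w)·(|w|/2)·[tanh(α_j(|w|−λ_j)) + 1].  The rule is a continuous,
   odd, monotone shrinkage: the bracket (tanh+1)/2 ∈ [0,1].  α_j → ∞
   recovers hard thresholding away from |w| = λ_j; α_j = 0 halves every
   coefficient; at |w| = λ_j the output is w/2 for every α_j.  Note no α_j
   value reproduces soft thresholding exactly; "soft-like" here means
   strong shrinkage of small coefficients with a gradual transition.
3. **Tune per layer, finest to coarsest.**  For each layer, λ_j is set
   first (see below), then α_j is chosen by maximizing the NZOPP of the
   full reconstruction under the current rules of all layers — a
   one-dimensional coordinate step per layer.  Optional extra sweeps
   (`passes`) repeat the loop until the objective gains less than 1e-4.
4. **Reconstruct** with the approximation A_J passed through untouched.

### The periodicity objective

NACF(k) normalizes the lag-k autocorrelation by √(full energy)·√(tail
energy of the N−k overlapping samples).  This tail normalization (rather
than the textbook biased estimator) makes the profile exactly
scale-invariant and bounded by 1 at every lag, but it also caps the value of
an exactly periodic signal at √(1 − k/N); NZOPP values are therefore only
comparable between signals of the same length, which is how the optimizer
uses them.  NZOPP is the maximum of NACF over lags in
[round(min_period·fs), min(round(max_period·fs), ⌊N/2⌋)].  Defaults
min_period = 0.25 s and max_period = 2 s admit heart rates of 30–240 bpm;
the upper cap keeps slow periodic artifacts (residual baseline wander) from
claiming the peak on long records.

### The bracket search

`optimize_tuning_factor` evaluates the objective at the bracket ends, the
midpoint and the two quarter points.  If the best value sits at {start,
left} the bracket contracts to [start, mid]; at {right, end} to [mid, end];
at mid to [left, right].  For a unimodal objective the maximizer never
leaves the bracket, each step halves the width, and the loop stops at width
≤ tol (default 1e-6), returning the bracket midpoint.  Objective values are
cached by abscissa, so the endpoints shared between iterations cost
nothing; ties go to the earliest branch, making the search fully
deterministic.

### Threshold estimation

Two rules are provided for λ_j:

* `universal` (default): λ_j = σ_j √(2 ln N) with σ_j = median(|D_j|)/0.6745.
* `nzopp`: λ_j maximizes the same periodicity objective over [0, max|D_j|],
  with α_j held at its current value.

The universal rule is the default because, measured on the synthetic study
conditions, the per-layer NZOPP-maximizing threshold systematically drives
the coarsest layer's λ toward max|D_j|: deleting genuine QRS-band energy
*also* raises periodicity, and the reference-free objective cannot tell the
difference.  With the universal rule fixing λ_j and NZOPP tuning only the
function shape α_j, median ΔSNR on white noise at 5 dB input roughly
doubles (≈5.5 dB vs ≈2.8 dB).

### The α search interval

α has inverse-amplitude units.  The search interval is
[0, alpha_arg_span / max|D_j|] with span 25 by default, i.e. the tanh
argument at the layer's largest coefficient can reach 25 — comfortably into
the hard-threshold regime — regardless of the signal's scale.  A literal
interval [0, max|D_j|] (available via `alpha_arg_span=None`) caps the tanh
argument near max|D_j|² which, for peak-normalized signals, never exceeds
~1: the rule would then shrink even the largest coefficients by ≥12% and
could never approach hard thresholding.  The scale-invariant interval
measured equal or better on every tested condition.

## Defaults and units

| parameter | default | unit | why |
|---|---|---|---|
| wavelet | bior6.8 | — | symmetry / near-linear phase for morphology |
| levels J | 4 (ECG-rate); "auto" tries 3–5 | — | deeper layers trade noise removal for distortion; auto keeps the most periodic result |
| threshold_method | universal | — | see above |
| min_period_s | 0.25 | s | 240 bpm ceiling |
| max_period_s | 2.0 | s | 30 bpm floor; excludes slow artifacts |
| tolerance | 1e-6 | α units | bracket-width stopping rule |
| alpha_arg_span | 25 | — | tanh argument reach at the largest coefficient |
| passes | 1 | — | one finest-to-coarsest sweep suffices in practice |

## Synthetic data

The generators are pure functions of (parameters, seed) and define the
study conditions used by the tests and the acceptance script:

* **ECG**: sum of Gaussian bumps per beat (P, Q, R, S, T at fixed offsets
  −0.20, −0.028, 0, 0.03, 0.24 s; amplitudes 0.12, −0.12, 1, −0.22, 0.28;
  widths 25–60 ms), RR intervals with ±3% multiplicative jitter by default,
  peak normalized to 1.  Default 360 Hz, 10 s, 60–90 bpm in studies.
* **Noise**: BW = 2–3 sinusoids below 0.5 Hz plus a slow random walk
  (>90% of power below 1 Hz); EM = sparse ±transients convolved with an
  80 ms exponential decay; MA = white noise band-passed to 20–100 Hz;
  MIX = equal-power BW+EM+MA; WHITE = Gaussian.  All zero-mean, unit power.
* **Mixing** scales the noise so the input SNR is exact to <1e-9 dB; the
  stored noise vector is the realized difference y_in − x, so the pair
  decomposes bitwise.
* **Fiber cardiorespiratory**: dominant respiration sinusoid plus smaller
  30 ms cardiac pulses amplitude-modulated by respiration, 2048 Hz
  nominally; depth 5 is the recommended setting for these slower signals.

What the generators do **not** emulate: real PQRST morphology variation,
arrhythmia, the heavy-tailed and non-stationary structure of recorded
electrode-motion artifacts, or the broadband content of real
baseline-wander recordings.  Passing the synthetic efficacy bars therefore
shows the machinery works as designed, not that clinical performance is
matched on physical records.

## Evaluation metrics

SNR, RMSE and PRD are the standard reference-based definitions (and satisfy
SNR = −20·log10(PRD/100) identically).  SINAD = 10·log10(Ps/(Pn+Pd)) with
Ps = mean x², Pn = mean(y_out−x)², and Pd = mean(y_out−y_in)² — Pd is the
power of the *change the denoiser made*.  A consequence worth knowing: a
denoiser that removes most of the noise has Pd ≈ input-noise power, so
ΔSINAD (output minus input, the input side computed with y_out replaced by
y_in, making its Pd zero) is typically slightly negative even when ΔSNR is
strongly positive.  The reported ΔSINAD values follow this definition
as printed.  Exact estimates surface SNR = +inf as an explicit sentinel
(serialized `"inf"`) so batch reports never abort.

## Numerical choices

* NACF via FFT correlation (scipy `fftconvolve`); a direct-summation path
  is kept for cross-checks and agrees to <1e-10.
* Profile values are clipped to [−1, 1] against last-bit excursions.
* Degenerate layers (all-zero details) skip the search with α = 0 and an
  empty trace.
* Depth feasibility requires N ≥ 2^(J+1) (every approximation stage keeps
  at least two samples); reconstruction stays exact well past the
  conservative "no boundary effects" depth, which is deliberately allowed.
* `nzopp_out` in a result equals the best objective value recorded in the
  final layer's search trace; the realized output's own NZOPP differs from
  it only within the search tolerance.
* Everything is deterministic: identical signal + config give bit-identical
  results, and reports carry the rules needed to replay the output exactly.

## Known limitations

* **Baseline wander at the default depth.**  At 360 Hz and J = 4 the
  approximation band (0–11.25 Hz) passes through untouched, and nearly all
  BW power sits below 1 Hz.  No detail-layer shrinkage can remove it; the
  best achievable is the identity, and the periodicity objective prefers
  mild smoothing, so ΔSNR on the synthetic BW condition is slightly
  negative (≈ −0.7 dB median).  Removing BW requires either much deeper
  decomposition or an explicit detrending stage, both outside the current
  pipeline contract.
* The NZOPP objective is a proxy: it cannot distinguish "noise removed"
  from "sharp signal features smoothed" at coarse layers (hence the
  universal-threshold default).
* Single-channel, offline operation only; quasi-periodicity is assumed —
  signals without a periodic component give a flat, uninformative objective.

## Problem sizes

The test suite and acceptance script run synthetic studies at 360 Hz × 10 s
(N = 3600), 10–20 seeds per condition; one full adaptive denoise at these
sizes takes ~0.1 s, so the complete acceptance run finishes in well under a
minute.
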