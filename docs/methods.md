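# Methods

## Signal model and pipeline

The package treats an accelerometer recording as three equal-length sample
sequences at a fixed rate fₛ ≥ 30 Hz, in g or m/s².  Conversion between the
two units uses 9.8 m/s² per g: the pipeline's three printed constant pairs
(2.13 g = 20.874 m/s², 0.068 g = 0.6664 m/s², 0.001664 g = 0.0163072 m/s²)
are exact at 9.8 and inconsistent with 9.81, so 9.8 is the default
(`PipelineConfig.g_to_ms2`, configurable).

Quantification applies, per axis: band-pass filter → rectify → saturate
(2.13 g) → deadband (0.068 g) → scale (1 count = 0.001664 g) → gain →
1-s epoch aggregation (sum/fₛ), then the VM3 Euclidean norm across axes.
Choices that needed making:

* **Rectification** is not always listed among the steps of count
  algorithms, but the saturation/deadband thresholds act on magnitude and
  epoch sums must be nonnegative, so |·| is applied between filtering and
  saturation.  `PipelineConfig.rectify=False` disables it for
  experimentation (negative samples are then zeroed by the deadband).
* **Deadband convention**: samples strictly below the threshold are zeroed
  (not threshold-subtracted); a sample exactly at the threshold is kept.
* **Gain placement**: the calibration gain (0.93 fixed / 0.96 modifiable,
  least-squares calibrations against commercial output) multiplies the
  scaled counts before epoching; since epoching is a scaled sum, this is
  identical to scaling the epochs.
* **Quantization** (floor to whole counts at the scaling step) is off by
  default, preserving the continuous mean-count-per-second epochs; on, it
  mimics integer-count devices.
* **Epoching** drops a trailing window that does not fill a complete epoch;
  the CLI logs how many samples were dropped.
* **No resampling**: the pipeline's point is native operation at the
  recorded rate; fₛ < 30 Hz is rejected rather than upsampled.

## Filters

Both filter variants are continuous-time (analog) transfer functions, so
one design serves any sampling rate.

**Modifiable variant.**  `design_butterworth_bandpass(low, high, order)`
builds an analog Butterworth band-pass whose *total* denominator degree is
`order` (default 4, i.e., an order-2 low-pass prototype transformed to a
band-pass; some design tools would call this "order 2").  Its magnitude is
0 dB at the geometric band center and exactly half power (−3.0103 dB) at
the cutoffs, 0.305 and 1.615 Hz by default.  "−3 dB" is implemented as the
half-power level throughout, which is what Butterworth edges satisfy
exactly.

**Fixed variant.**  `fit_bandpass_to_reference` fits a stable analog
band-pass of even order n to a tabulated magnitude response
(freq_hz, magnitude_db; must cover 0.1–5 Hz with ≥ 50 points).  The model
is a cascade of n/2 second-order band-pass sections
g·Π (s·ωₖ/Qₖ)/(s² + s·ωₖ/Qₖ + ωₖ²), parameterized by log ωₖ, log Qₖ and
log g — every parameter choice is stable and strictly band-pass by
construction, so no stability-rejection step is ever needed.  The objective
is the mean squared dB-magnitude error at the reference frequencies.
Optimization is differential evolution (seeded, single-threaded, hence
bit-reproducible; population multiplier 20, ≤ 80 generations, Sobol
initialization) followed by a local least-squares polish started both from
the evolutionary optimum and from a deterministic Butterworth-shaped seed
derived from the reference's interpolated half-power band; the better
polished candidate wins.  Fitting a response that is itself generated by a
member of the cascade family recovers it essentially exactly (objective
below 1e−13 dB² in the shipped-default regeneration).

The packaged reference table
(`data/synthetic_count_filter_response.csv`) is a *synthetic* stand-in for
a measured commercial count-filter characterization: a cascade of two
analog Butterworth band-passes (0.29–1.66 Hz and 0.25–2.5 Hz, total order
8), peak-normalized, sampled on 200 log-spaced points over 0.05–5 Hz.  It
reproduces the qualitative shape of published count filters (passband
≈ 0.3–1.6 Hz, steep skirts) but is not a measurement of any device.  The
shipped fixed filter (`data/fixed_bandpass.json`) is the order-8 fit of
that table (seed 20201126); `actcounts fitfilter` regenerates it or fits a
user-supplied table.

**Discretization.**  `discretize` maps an analog filter to a given fₛ with
the bilinear transform.  Plain bilinear compresses frequency by
tan(πf/fₛ)/(πf/fₛ), which at fₛ = 30 Hz shifts the 1.615 Hz edge by ~1%
and costs ~0.12 dB there.  The transform constant is therefore chosen so
that the residual warp factors at the two band edges are reciprocal
(geometric balancing): max passband error is then 0.059 dB at 30 Hz and
0.005 dB at 100 Hz.  Outside the passband, warping still grows toward
Nyquist (~0.5 dB at 3 Hz for fₛ = 30); at fₛ = 100 the agreement is within
0.1 dB across 0.05–3 Hz.  fₛ below 10× the upper band edge is rejected.

**Application** is causal direct-form filtering with zero initial
conditions, matching a streaming count device.  Consequences: a gravity or
DC step at recording onset produces a decaying transient (counts in the
first few seconds of an otherwise still recording), and steady-state
sinusoid gain matches the computed frequency response to < 0.5%.

## Classification

Cut-point scales are ordered (name, lower-bound cpm) lists forming
half-open intervals [lower, next lower), the last unbounded; the integer
Freedson Adult VM3 bounds ship as the default and any scale loads from
JSON.  Boundary values classify upward (2960 cpm is Moderate; 6167 is
Vigorous).

The discrete method partitions the 1-s VM3 series into back-to-back 60-s
blocks from index 0; each block's cpm is its 60-count sum; a trailing
partial minute is dropped; series shorter than 60 s give an empty profile
with a warning rather than an error.  The continuous method forms, for each
second i, the half-open window [i−30, i+30) — exactly 60 s, resolving the
ambiguity between a 60-s and a 61-s reading of "30 preceding and 30
following" in favor of a window that is exactly one minute.  Windows are
clipped at the series boundaries and rescaled by 60/length to stay in cpm —
the only convention that yields one window per recorded second (180 windows
for a 180-s series); zero-padding would instead dilute boundary windows.

## Agreement statistics

`agreement(a, b, epoch_s)` re-aggregates 1-s series to 1/10/30/60-s epochs
(block sums, trailing remainder dropped) and reports: Pearson r, Spearman ρ
(average ranks on ties), mean difference and SD of differences (ddof = 1),
limits of agreement at mean ± 1.96 SD with the count and percentage of
points outside, relative difference of totals 100·(ΣB − ΣA)/ΣA, and OLS of
|b − a| on (a + b)/2.  Differences are comparator minus reference.
Zero-variance inputs and zero reference totals yield NaN for the affected
statistics plus an explanatory flag instead of an exception.  On
independent Gaussian differences the 1.96·SD construction leaves ≈ 5% of
points outside the limits; the suite checks 5 ± 2 percentage points at
n = 10 000.

## Synthetic signals

The generator emulates the ingredients of wrist-worn recordings: a 1 g
gravity DC placed on z (the band-pass removes DC, so placement is
arbitrary and fixed for reproducibility), sinusoidal movement carriers in
the voluntary band (default 1 Hz), white Gaussian noise (no colored-noise
model is claimed), optional out-of-band tremor overlays (4–6 Hz), and
piecewise-constant activity profiles built from segments with per-axis
weights.  All output is clipped to ±8 g, the range of common research
accelerometers, and all randomness flows through one seeded generator, so
profiles are bit-reproducible.  These signals contain no biomechanical
structure, orientation changes, or non-wear periods: passing tests
demonstrate numerical correctness of the pipeline, not validity on human
data.

Default demonstration profile (CLI `simulate`): three 60-s segments at a
1 Hz carrier with amplitudes 0.05, 0.3 and 0.8 g and 0.01 g noise — a
ramp spanning the Light-to-very-vigorous range at 30 or 100 Hz.

## Problem sizes and tolerances

The test suite runs filter fits at orders 4 and 8 on 200-point reference
grids, pipeline oracle comparisons on 8–10 s signals at 30 Hz (checked to
1e−9 against a per-sample loop reference), classification on 3–7 min
series, and Bland–Altman coverage at n = 10 000 pairs; the whole suite
completes in well under a minute.  Numerical tolerances: half-power
crossings are located to machine precision by Brent root finding on a
4000-point log scan; steady-state gain checks use the second half of a
120-s signal (transient fully decayed); fit determinism is asserted
bit-for-bit for a fixed seed.

## Known limitations

* The shipped fixed filter encodes the shape of the packaged synthetic
  reference, not a measured commercial filter; users wanting fidelity to a
  specific device should supply their own measured response table to
  `fitfilter`.
* Counts from recordings with different sensor ranges (±2 g vs ±8 g) can
  differ through early saturation; the pipeline assumes the signal was not
  clipped below its own 2.13 g saturation.
* No non-wear detection, MET/energy-expenditure conversion, or step
  counting.
* Causal filtering means the first seconds of every recording carry a
  start-up transient; analyses of very short recordings should discard a
  settling prefix (≈ 10 s is ample at the default band).
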