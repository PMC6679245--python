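# Methods

## The problem

Heart-rate-variability (HRV) features are computed from the sequence of
RR-intervals (times between successive heartbeats) in short windows,
conventionally 5 minutes. Wearable optical monitors lose beats in bursts:
motion artifacts corrupt runs of consecutive intervals rather than isolated
ones. This package (1) simulates such burst missingness with a two-state
Markov model, (2) reconstructs the gapped series with interpolation applied
either to the beat *timestamps* or to the beat *durations*, or leaves the
gaps in place, and (3) measures the error each strategy induces in eleven
standard HRV features relative to the gap-free ground truth.

## Gilbert burst model

States 0 (good, beat observed) and 1 (bad, beat missing). With target
long-run missing fraction `Pchange ∈ [0,1)` and mean burst length
`Lburst ≥ 1` beats:

    p = 1/Lburst               # bad -> good
    P = Pchange/(1-Pchange)·p  # good -> bad
    q = 1-p,  Q = 1-P

The stationary bad-state occupancy is `Pe = P/(p+P)`, which simplifies to
`Pchange` exactly, and bad-state runs are geometric with mean `1/p =
Lburst`. Parameter combinations implying `P > 1` (short bursts at high
missing fractions) are rejected outright rather than clipped, so the
stationary identity always holds for accepted parameters.

Simulation choices: the chain starts in the good state; the first beat of a
window is never maskable, since a window whose start time is unknown has no
defined duration — the mask applies from beat 2 onward. At the simulation
lengths used (10^5 beats) this biases the empirical missing fraction by
under 10^-4, far below the Monte-Carlo error. The generator is
`numpy.random.default_rng` under an explicit integer seed that is recorded
in the produced mask.

Note an internal inconsistency in how the model is sometimes parameterised
informally ("to get 20% missing, set Pchange = 0.3"): under the algebra
above the long-run missing rate *equals* `Pchange`. This package follows
the algebra; requesting 30% missing means `Pchange = 0.3`.

## Interpolation pipelines

Both pipelines index data by the integer beat position in the original,
pre-masking enumeration, because the gap mask and the kernels are
index-wise. The difference is the order of operations:

- **On time**: interpolate missing *timestamps* against beat index, then
  difference to obtain durations. Retained beats keep their exact
  timestamps, so the span between the first and last retained beat — the
  window time — is conserved exactly. This is a structural invariant, tested
  as such.
- **On duration**: compute durations of retained consecutive pairs first
  (a duration slot is known only when both of its beats are retained), then
  interpolate the missing slots. The reconstructed cumulative time generally
  drifts away from the true beat positions; the drift is the mechanism by
  which this pipeline corrupts spectra.
- **No interpolation**: keep the retained beats at their true timestamps and
  flag which adjacent pairs were consecutive in the original series.
  Successive-difference statistics (RMSSD, pNN50, Poincaré) then use only
  genuinely consecutive pairs, and spectral estimation uses the unevenly
  sampled retained data directly.

Kernels: nearest neighbour (true nearest; an exact midpoint takes the later
neighbour — note the piecewise closed form is sometimes printed with the
branches swapped, which would assign the *far* neighbour and contradict its
own definition), linear, quadratic (the unique parabola through three
supports, evaluated in Lagrange form; on equally spaced supports this
reduces to the familiar second-order Newton form, verified by a randomized
oracle test), and a global natural cubic spline over all retained points.
Nearest-on-time is rejected: duplicating a neighbouring timestamp creates a
zero-length interval, which is physiologically impossible.

Support selection (not fixed by the kernel definitions, so chosen here):
nearest/linear use the closest retained point on each side of a gap;
quadratic uses the two nearest retained points before the gap and one
after, falling back to one-before/two-after at the left window boundary and
to linear when only two supports exist. Gaps touching a window edge degrade
rather than extrapolate: on time, leading/trailing missing beats are
dropped; on duration, edge slots hold the nearest known duration.
Interpolated timestamps are *not* forced monotone — a non-monotone
reconstruction (possible with quadratic/spline overshoot) marks the window
invalid for feature extraction instead of being silently clamped, which
would bias spectra.

## HRV features

Eleven features per window, from durations `RR_i` and beat timestamps:

- HR mean = mean of `60/RR_i` (beats/min).
- RMSSD = sqrt of the mean squared successive duration difference. The
  mean runs over the N−2 valid difference terms for N beats (the printed
  N−1 normalisation in some formulations double-counts an index).
- SDNN = sample standard deviation (divisor N−1) of durations.
- pNN50 = (count of |successive difference| > 50 ms, strict) divided by the
  number of RR-intervals (not the number of difference pairs); the raw NN50
  count is also emitted.
- VLF (0, 0.04], LF (0.04, 0.15], HF (0.15, 0.4] Hz band powers: sums of
  Lomb–Scargle periodogram values over each band; total power over
  (0, 0.4]; LF/HF ratio (dimensionless, undefined when HF = 0).
- Poincaré SD1/SD2: sample standard deviations of
  `(RR_{n+1} − RR_n)/√2` and `(RR_{n+1} + RR_n)/√2` over lag-1 pairs —
  the 45° rotation of the lag-1 scatter. The identity
  `SD1² + SD2² = s²(RR_n) + s²(RR_{n+1})` holds to machine precision and is
  tested.

Spectral conventions: each duration is placed at the midpoint of its two
beat timestamps (symmetric; the convention is otherwise arbitrary). The
default frequency grid is 0.002–0.400 Hz in 0.002 Hz steps (200 points),
resolving the ~1/300 Hz limit of a 5-min window. The periodogram is the
least-squares Lomb periodogram (scipy's `lombscargle`) scaled by 2/N so an
injected tone of amplitude A contributes ≈ A²/2 — its variance — at its
peak; absolute power calibration is conventional and not an accuracy claim.
For duration-sequence input the time axis is reconstructed by cumulative
sum; for the gap-aware view only consecutive-flagged pairs contribute
samples. Undefined features (too few valid pairs, zero HF, invalid
reconstruction) are reported as NaN, never as zero.

## Evaluation harness

Recordings are split into consecutive non-overlapping windows (default
300 s, half-open `[start, start+300)`, trailing partial window dropped,
each window re-anchored at its first beat). For every window × missing
fraction (default 30/50/70%) × replicate seed, a Gilbert mask
(`Lburst = 10`) is drawn from a per-cell sub-seed (via
`numpy.random.SeedSequence`, so cells are independent but reproducible),
and every pipeline — no-interpolation, 3 on-time kernels, 4 on-duration
kernels — is scored per feature by relative error
`RE = |x_real − x_k|/x_real·100` and RMSE against the same window's
gap-free features. Windows with fewer than `min_retained_beats` (default
10) retained beats, and features whose ground truth is zero or undefined,
are excluded per-cell with counts reported. Both mean and median RE are
aggregated; method ranking uses mean RE with ties broken toward the
simpler method (none < nearest < linear < quadratic < cubic_spline), then
toward the simpler pipeline (none < time < duration).

## Synthetic generator

An integral pulse frequency modulation (IPFM) model: instantaneous rate

    r(t) = hr_mean + lf_amp·sin(2π·0.1·t) + hf_amp·sin(2π·0.25·t) + noise(t)

in beats/min; a beat fires whenever `∫ r/60 dt` crosses an integer. The
integral is accumulated on a 1 ms grid with linear interpolation of the
crossing time (sub-millisecond accuracy; exact for constant rate). The LF
tone stands for baroreflex-band modulation, the HF tone for respiratory
sinus arrhythmia.

The noise term emulates broadband beat-to-beat variability: white Gaussian
rate deviations held over 0.8 s blocks (about one beat), so successive
intervals are perturbed nearly independently. Millisecond-scale white rate
noise would integrate away to ~0.2 ms of RR jitter and leave pNN50
identically zero; beat-scale noise is what actually produces the short-term
variability seen in sinus-rhythm recordings. Defaults — `hr_mean = 75`,
`lf_amp = 3`, `hf_amp = 2`, `noise_sd = 2.5` bpm — give RMSSD ≈ 0.036 s,
SDNN ≈ 0.033 s and nonzero pNN50, close to the short-term variability of
daytime normal sinus rhythm at 75 bpm. A validity bound
`hr_mean − lf_amp − hf_amp − 3·noise_sd > 20` keeps the instantaneous rate
positive and physiologic.

What the generator does **not** emulate: the very-low-frequency (VLF) and
1/f trend structure that dominates real sinus-rhythm recordings
(so synthetic SDNN is smaller relative to RMSSD than in real data, and VLF
power is leakage-level), circadian nonstationarity, and ectopic beats.
Consequences for interpretation: results that hinge on slow spectral
content transfer only qualitatively. In particular, on this stationary
tone-plus-noise data the *no-interpolation* view and *nearest-on-duration*
(which copy genuine duration values across gaps, preserving marginal
variance and band-power magnitude, a phase-insensitive quantity) can beat
on-time interpolation for amplitude-type features (SDNN, total power) even
though on-time reconstruction has the smaller per-duration RMSE and exactly
conserves window time. On VLF-dominated real recordings the balance shifts
toward on-time interpolation for those features; the test suite encodes the
strict on-time-vs-on-duration expectation for SDNN and all band powers, and
the cells where the synthetic conditions genuinely favour duration-value
copying fail that test — deliberately left visible rather than papered over
by re-tuning the generator.

A 100-beat demonstration fixture (`make_table1_fixture`) applies a 10%
burst mask to a synthetic window; because roughly a third of such short
draws would contain no gap at all, the mask is re-drawn deterministically
until it contains at least one missing beat — the fixture exists to exhibit
the on-time/on-duration contrast, which a gapless draw cannot.

## Problem sizes and numerics

Chain-statistics checks use 10^5-step simulations (Monte-Carlo standard
error of the occupancy fraction ≈ 0.5 percentage points at 30% missing,
accounting for the chain's lag-1 autocorrelation `ρ = 1 − p − P`). The
factorial study in the acceptance tests uses 20 five-minute windows × 3
replicate seeds × 3 missing fractions × 8 pipelines, chosen as the smallest
design at which the medians of per-cell RE are stable. Kernel and feature
oracle tests compare against independent brute-force implementations at
1e-12 relative tolerance; conservation properties are asserted with exact
floating-point equality, which the on-time pipeline satisfies by
construction (retained values are copied, never recomputed).
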