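# Methods

This note documents the models, the numerical choices, and the synthetic
data conditions behind `motionwarp`, and states what the tests do and do
not demonstrate.

## Dynamic time warping

Two sequences x (length N) and z (length M) are aligned on the full N×M
grid with local cost δ(n,m) = (xₙ − z_m)² and the accumulated cost
recurrence σ(n,m) = δ(n,m) + min of the three predecessors. Boundary
cells, where only one predecessor is admissible, accumulate along the
first row/column. The total warping cost is Σ = σ(N,M), and the traceback
asserts that the δ-sum along the recovered path equals it (the two
definitions coincide for any optimal path, and the implementation checks
this identity in tests rather than preferring one).

Numerical choices:

- **Traceback tie-break:** at equal accumulated cost the diagonal
  predecessor is preferred, then the vertical (previous row), then the
  horizontal. This yields the shortest path among cost ties and makes
  paths deterministic.
- **No band constraint:** motions are tens of samples long, so the full
  O(NM) matrix is computed; no Sakoe–Chiba band or lower-bounding.
- Paths are reported as 1-based (n, m) pairs from (1,1) to (N,M).

Σ is symmetric, invariant to adding a constant to both sequences, and
scales quadratically under a common amplitude factor (local costs are
squared differences). Queries and templates are therefore min-max
normalized to a shared [0,1] scale wherever amplitude is not meaningful.

## Length equalizers

Both map an N-sample sequence to M ≥ N samples; decimation (M < N) is
rejected rather than implemented.

**DFT interpolation.** The N-point spectrum is split literally in half —
first N/2 and last N/2 coefficients for even N, first (N+1)/2 and last
(N−1)/2 for odd N — with M−N zeros inserted between, followed by the
M-point inverse DFT with its 1/M factor. Consequences of the literal
half split, kept deliberately:

- Amplitudes shrink by N/M (the padded inverse keeps 1/M). Downstream
  min-max normalization removes the scale, so no compensating gain is
  applied.
- For an integer ratio M = rN the original samples reappear exactly at
  positions 1 + r(n−1), scaled by N/M (verified to 1e−9 in tests).
- For even N the Nyquist bin moves wholly to the back half, which breaks
  conjugate symmetry and leaves a genuine imaginary residue proportional
  to the signal's Nyquist content. The real part is taken; a
  `RuntimeWarning` fires when the residue exceeds 10 % of the signal
  amplitude. On smooth motion shapes the residue is negligible; on
  heavily noisy inputs the warning is expected and harmless, since the
  discarded component is itself noise.

**Convolutional equalizer.** Full discrete convolution with an all-equal
kernel of length Q = M − N + 1. The kernel taps are 1/Q (unit DC gain, a
true moving average) so equalized amplitudes stay comparable when Q
differs between sequences; the source description fixes only that the
taps are a constant impulse train, not their value. Larger stretches
therefore smooth more — visible as the lower recall of
convolution-averaged templates relative to DFT-averaged ones.

**Normalization.** Min-max onto [0,1]; a constant sequence maps to all
0.5 (the midpoint is the symmetric, bounded choice for the degenerate
zero-range case).

## Templates (matching pattern paradigms)

Averaged MPPs: per category, equalize every training sample to a common
length M, normalize, average pointwise. M defaults to the longest sample
present, since the equalizers only upsample; the 15-point worked example
applies only to its short 13/11/11-sample inputs. The random policy picks
one raw sample per category (seeded) as the no-averaging control.

An opt-in `reject_outliers` pass drops samples whose warping cost to the
provisional template exceeds the 90th percentile and re-averages once — a
reproducible surrogate for manually discarding degraded recordings. It is
off by default so the default pipeline is exactly
equalize → normalize → mean.

Whether templates should be built from raw or equalized samples is
underdetermined; equalized is used, as it is the only construction that
makes pointwise averaging well defined across lengths.

## Classification and evaluation

A query is labeled by the template of minimum total warping cost, ties
broken toward the lowest category code. The bare `classify_sequence` does
not touch the query's amplitude — normalization is applied by the callers
(k-fold evaluation, online detection) so both sides of the match share a
scale; this keeps the invariant that a query identical to a template
matches at exactly zero cost.

Cross-validation uses stratified, seeded folds (per-class shuffling with
a dealing cursor carried across classes, so fold sizes differ by at most
one and no class can vanish from a training union unless it has fewer
samples than folds — which raises an explicit error). Accuracies are
reported in percent with two decimals, plus their mean across folds.

## Back-propagation network

Three layers: M inputs, 5 logistic hidden units, one logistic output per
category with one-hot targets. Unstated details resolved as: logistic
sigmoid on both layers; error E = ½·Σ(squared output errors) with its
RMSE as the convergence criterion; full-batch delta-rule updates with a
fixed learning rate η ∈ (0,1) (default 0.5), no momentum; initial weights
uniform in [−0.5, 0.5]; defaults of 1000 epochs and RMSE tolerance 0.05.
Units compute g(Σwᵢxᵢ − θ), so bias gradients carry a sign flip relative
to a plain additive bias. Gradients are verified against central finite
differences (relative error < 1e−5) in the tests. Plain gradient descent
is not strictly monotone in general; the non-increasing-RMSE check is
made at η = 0.05 on a fixed benchmark where it does hold.

## Segmentation and threshold tuning

The variation statistic is a right-aligned rolling population standard
deviation over 0.25 s (5 samples at 20 Hz), front-padded with the first
valid value. A segment opens when variation exceeds the start threshold
and closes once variation has stayed strictly below the stop threshold
for ≥ 0.5 s (10 samples); the hold window is excluded from the segment
body so matched patterns carry no trailing quiet. A segment still open at
the end of the stream is closed at the final sample. The stop threshold
may not exceed the start threshold.

Thresholds are tuned by maximizing mean segment-level F1 over streams
with known spans. A detected segment matches a true span when their
overlap covers at least half of the true span (greedy, one-to-one, in
stream order); this recall-oriented definition tolerates the short onset
lag the rolling window introduces. The optimizer is a global-best
particle swarm — 20 particles, 50 iterations, inertia 0.7,
cognitive/social coefficients 1.5/1.5, seeded — searching (start, r) with
stop = r·start, r ∈ [0,1], which enforces the ordering constraint by
construction; a dense grid search over the same bounds is available as a
fallback and as an optimizer sanity oracle. These swarm settings are
conventional defaults, chosen here, not inherited.

Online detection classifies each normalized segment body against the
loaded MPPs. Walking is a recognized *normal* category, not an exception:
batch accuracy statistics count only sit-down/stand-up events.

## Synthetic data conditions

The generator emulates a frontal-axis accelerometer at 20 Hz. Prototype
shapes are invented (no recordings are redistributed): sit-down is a
biphasic pulse — one sine period under a Hann window — stand-up its exact
polarity mirror (consistent with reversing the motion along the frontal
axis), and walking a damped ~2 Hz sinusoid. Defaults: 2.0 s base
duration, speed factor uniform in ±30 % applied to the *time axis before
sampling* (so sequence length genuinely varies, the premise of the whole
method), amplitude factor ±10 %, additive white noise with sd 0.1 signal
units, quiet-baseline noise sd 0.02 in streams. All levels (sequence,
dataset, stream) derive their randomness from one root seed.

What passing tests show — and do not. The synthetic classes are smooth,
unimodal and well separated at the default noise: they validate the
machinery (alignment optimality, length contracts, gradient correctness,
segmentation logic, the end-to-end pipeline) and the qualitative ordering
between methods, not field performance on real volunteer recordings. Real
accelerometry carries gravity leakage, sensor drift, multi-axis coupling
and inter-subject variability that the generator does not model, so
absolute accuracies here (often 100 %) overstate what any method achieves
on real data. Benchmarks in the tests use 130 two-class sequences or 30
three-class sequences — sizes chosen to mirror a realistic single-subject
collection session while keeping the suite fast.

## Known limitations

- Univariate sequences only; no multi-axis DTW or step weighting.
- One template per category; no template libraries or online adaptation.
- The even-N spectral split is kept literal rather than halving the
  Nyquist bin; see the equalizer section.
- Thresholds are tuned offline; no drift adaptation during detection.
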