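# Methods

This note documents the models, parameters and numerical choices behind
`mimicrank`, and what the synthetic benchmark does and does not show.

## The matching task

A mimicked call is treated as a query against a library of candidate
calls; the analysis asks at what rank the putative model call appears when
candidates are sorted by feature-space distance. Two designs are
implemented. In the *full-library analysis* every mimic is compared with
every other file, and rank-1/2/3 correct-match counts are tabulated per
feature × index. In the *trial design* each mimic is tested in five
independent sets of eleven spectrogram slots — the query plus its model
and nine distractors (three other mimics, three conspecific calls, three
other-species calls, drawn without replacement within a set, independently
across sets) — mirroring how human raters are typically tested, so the
automated and human arms are directly comparable. Accuracy is scored per
trial (rank 1; rank 1+2) and per call (correct in all five trials; correct
in at least four of five, the "80 % threshold").

Feature and index selection follows the matching counts: the feature with
the most first-ranked correct matches, and the two indices with the most
first-ranked matches summed across features, ties broken by lower rank
variance and then by a fixed index order (Jaccard, correlation, cosine,
city-block, Euclidean). Rank variance is the sample variance (n − 1) of
the rank list expanded from the rank-1/2/3 counts; a flag optionally
appends incorrect matches scored as rank 4 — both conventions appear in
published tables, and the two reproduce different published cells, so both
are kept.

## Feature front ends

All extractors share a 25 ms (1200-sample) Hamming frame with a 720-sample
hop at 48 kHz; a signal of N samples yields ⌊(N − 1200)/720⌋ + 1 frames
(tail frames are dropped, never padded). Display spectrograms use a
256-point Hann window at 50 % overlap (187.5 Hz × 2.67 ms cells). The DFT
length equals the window length; spectra are one-sided; energies are
clamped at 10⁻¹⁰ before any logarithm so silent frames stay finite.

**MFCC.** 32 triangular unit-peak mel filters span 0–24 kHz on
mel(f) = 2595 log₁₀(1 + f/700). The 13 static coefficients include c₀ (an
`include_c0` flag drops it); velocity is a 5-point (±2 frame) linear
regression slope with edge replication, acceleration the same operator
applied twice: 39 dimensions.

**LSF.** Biased autocorrelation (Wiener–Khinchin via FFT), order-12
Levinson–Durbin, then the palindromic/anti-palindromic split of A(z). Root
angles are found with the companion-matrix eigensolver; trivial roots at
angles 0 and π are discarded; residence on the unit circle is enforced to
10⁻⁶ and instability raises rather than returning spurious frequencies.
Frames whose LP fit is degenerate (e.g. zero energy) are excluded from
pooling and counted.

**RASTA-PLPCC.** Critical-band integration uses masking-curve filters
centred on integer Bark values 0..26 (Ω(f) = 6 asinh(f/600); flat over
±0.5 Bark, +10 dB/Bark lower skirt, −25 dB/Bark upper skirt). Band
log-energy trajectories are filtered by
H(z) = 0.1 z⁴(2 + z⁻¹ − z⁻³ − 2z⁻⁴)/(1 − 0.98 z⁻¹) with the canonical
warm-up initialisation: the FIR state is primed on the first four frames
(whose outputs are zeroed) before the pole engages, which makes the DC
rejection exact — a constant offset (e.g. a global gain change) produces
identically zero response, the property that gives the representation its
channel robustness. A plain zero-state mode (`init="zero"`) is available;
its impulse response is the filter's own. After exponentiation, 40-phon
equal-loudness weighting and cube-root intensity-loudness compression, the
edge bands are duplicated from their neighbours (standard stabilisation),
the auditory spectrum is inverse-DFT'd to an autocorrelation, an order-12
all-pole model is fitted, and cepstra c₁..c₁₂ are computed by the standard
recursion and lifted by n^0.6. c₀ (log gain) is excluded by default; both
the order and the lifter exponent are parameters.

Open conventions resolved here: the 13 MFCC coefficients include c₀, the
12 PLP coefficients do not; the equal-loudness curve is the 40-phon
rational approximation; LP order is 12 throughout.

## Pooling and similarity

Variable-length frame sequences are reduced by an element-wise mean
(median available) — the simplest fixed-length contract for whole-call
comparison; how the original analyses reduced frame sequences is not
documented, and any experiment here can be re-run under either pooling.
Jaccard's distance on continuous features uses the Ruzicka generalization
on magnitudes (a binary set mode exists for indicator vectors); it is a
true metric, verified by property tests. Similarities are converted to
distances (1 − r for correlation; the angle itself for the cosine metric)
so that every index ranks by ascending distance, with ties broken
lexicographically by candidate id for determinism.

## The synthetic data generator

The generator emulates the statistical structure of a field-recorded
mimicry study: libraries with the study's role composition (21/21/20/20
subset; 63-mimic/84-heterospecific/210-conspecific full library), calls of
five spectral-signature classes between 500 Hz and 8 kHz, and mimics
derived from their models by controlled degradation.

Class shapes: FM is a linear sweep; Trill repeats a short FM element with
10 ms silent gaps; NB-Trill is sinusoidal FM (deviation ≤ 200 Hz) around a
carrier; HR is a harmonic stack with seeded per-harmonic amplitudes and
5 % vibrato at 4–8 Hz (harmonic bird calls are strongly modulated, never
flat tones); BB is spectrally masked band-limited noise with smooth
raised-cosine bursts. Every call carries a slow random amplitude envelope
(depth 0.3, 2–6 Hz), 5 ms raised-cosine edge fades, peak normalisation to
0.9, and an ambient white-noise floor 25 dB below the call — field
recordings are never noise-free, and a common floor is what makes the
clean-model/perturbed-mimic comparison realistic rather than a
clean-vs-noisy artifact. Call durations are 0.5–1.2 s. Distinct
heterospecific "species" are stratified over each class's frequency range
(real species occupy separated acoustic niches; i.i.d. draws produce
implausibly many near-duplicate species). ≥ 90 % of each call's spectral
power lies within its nominal band ± 100 Hz, verified by DFT.

Mimic perturbation: frequency jitter is a polyphase resampling (all
frequencies scaled by 1 + j, duration by 1/(1 + j), as in a transposed
re-recording — a flat-passband resampler is used so the noise floor keeps
its character); an explicit time stretch is applied pitch-free with a
phase vocoder (reflect-padded so window-overlap normalisation is uniform);
white noise is then injected at exactly the requested SNR, and an optional
slow amplitude modulation models level instability. The identity
perturbation returns a bit-identical copy. How real mimics deviate
acoustically from their models is not characterised in the literature this
emulates; this perturbation model is a stand-in, and its parameters are
exposed rather than asserted.

What passing the synthetic benchmark shows: that the full pipeline —
synthesis, feature extraction, pooling, ranking, scoring — recovers
planted mimic/model relationships well above chance at realistic noise
levels, degrades monotonically with noise, and sits at the 1/10 chance
floor when mimics are unrelated to their assigned models (in the chance
control all clips are drawn i.i.d., making the ten candidates of a trial
exchangeable). What it does not show: performance on real recordings.
Synthetic calls lack reverberation and habitat transmission effects,
overlapping background fauna, recording-chain nonlinearity, and the
within-species variability of real repertoires; published accuracies on
real drongo recordings are therefore not comparable quantities and are not
asserted anywhere in the test suite.

## Statistics

The two-arm comparison uses the 2 × 2 chi-square test with Yates'
continuity correction, χ² = N·(max(|ad − bc| − N/2, 0))²/(r₁r₂c₁c₂), with
a two-sided p-value from the 1-df upper tail (erfc(√(x/2))). The
correction term is clamped at zero so the statistic cannot go negative;
degenerate margins raise. The implementation agrees exactly with R's
`prop.test` and scipy's `chi2_contingency(correction=True)`, and with a
conditional (hypergeometric) Monte-Carlo oracle to ±0.02.

## Problem sizes and determinism

Every stochastic component (synthesis, library construction, trial-set
draws) is driven by explicit integer seeds through `numpy`'s Generator;
identical specs give bit-identical audio. The parameter-recovery benchmark
uses 82-file libraries with five seeds per condition (525 trials) and ten
seeds for the chance control (1050 trials) — enough that the binomial 95 %
band around the chance floor is ±1.8 percentage points. Property suites
use 1000 random stable LP models (poles drawn inside the unit circle) and
1000 random vector triples for the metric axioms.

## Known limitations

- Plain log-domain RASTA cancels convolutional (channel) effects exactly
  but is not additive-noise invariant; at low SNR the noise floor
  compresses log-domain modulation depth and accuracy falls — visible in
  the benchmark's SNR ladder, and consistent with the representation's
  known behaviour.
- LSF extraction excludes frames with degenerate LP fits rather than
  repairing them; heavily silent recordings can lose frames.
- The trial design requires at least four mimics and three distractors of
  each role; smaller libraries raise informative errors rather than
  degrading the design.
- The human-assessment arm is ingested from CSV as trial outcomes; no
  perceptual model is provided or implied.
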