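# Methods

`vocalsig` quantifies how individual identity is encoded in an animal's call
repertoire, from two complementary angles: an acoustic one (can a classifier
tell two vocalizers apart from their calls, and do the cues transfer across
call types?) and a behavioral one (does a subject in a go/no-go operant task
interrupt the nonrewarded vocalizer preferentially?). Because the package is
exercised end to end on synthetic data, this note describes both the analysis
machinery and the generative model it is validated against, and is explicit
about what the synthetic validation does and does not establish.

## Synthetic repertoire model

Each call type is a template: a fundamental-frequency contour (flat, up- or
down-sweep; `base_f0 = 0` marks unvoiced, noise-like types), three resonance
("formant") centers, a mean duration with a duration CV, a harmonicity weight
in [0, 1] mixing a harmonic stack against resonance-shaped noise, and a
smooth unimodal amplitude envelope `x^a (1-x)^b` whose shape parameter skews
the energy forward or backward. Rendering band-limits everything to
0.25–12 kHz and peak-normalizes to −3 dBFS, written as 16-bit PCM WAV at
44.1 kHz.

Individual identity is a six-component additive offset vector applied to
(log f0, log F1..F3, log duration, envelope shape). Working on log scales
makes the spread parameters unit-free: `sigma_between = 1` corresponds to a
6% sd on f0, 4% on formants, 8% on duration (per-component base scales in
`synth._OFFSET_SCALE`). Rendition-to-rendition jitter reuses the same
component scales at `sigma_within`, so the ratio
`sigma_between / sigma_within` is the effective signature strength.

The key dial is `rho_voice`: an individual's offset for call type *t* is
`sqrt(rho) * v_i + sqrt(1 - rho) * s_it` with `v_i` shared across types
("voice", a cue carried by vocal-apparatus morphology) and `s_it` independent
per type ("signature", a cue that must be memorized per call type). The
square-root mixing keeps the marginal between-individual variance constant in
`rho`, so cross-regime comparisons of classification performance are not
confounded by overall cue strength.

A rendering subtlety: the noise component is seeded from a hash of the
synthesis parameters rather than from the caller's RNG, so identical
parameters (e.g. `sigma_within = 0`) reproduce bit-identical waveforms while
jittered renditions still get fresh noise. All dataset-level generation is
deterministic given the config seed.

Default study conditions (used by the tests and the acceptance script):
10 individuals, 30 renditions per (individual, type),
`sigma_between/sigma_within = 4/1`, five voiced call types for the transfer
analyses. The defaults are chosen so that within-type discrimination is
nearly saturated while cross-type transfer cleanly separates the two `rho`
regimes; the within- vs. between-individual acoustic variance of real zebra
finch calls is not quantified in the literature this mirrors, so these are
testability choices, not fitted values.

What the generator does *not* emulate: source–filter interaction,
articulation or motor variability structure, amplitude cues (deliberately
removed by peak normalization), recording-channel effects, or overlapping /
unsegmented vocalizations. Passing tests therefore demonstrate that the
analysis machinery recovers known structure of this family of signals — not
that real calls carry that structure.

## Acoustic features

Eighteen predefined acoustic features per rendition, in three groups.

* **Spectral (8).** Welch power spectral density (Hann, segments of up to
  1024 samples) restricted to 0.25–12 kHz and normalized to a probability
  distribution over frequency: mean, sd, skewness, kurtosis (plain
  `m4/m2^2`), entropy normalized by `log(n_bins)` so it lies in [0, 1], and
  the 25/50/75% quantiles. Quantiles invert a piecewise-linear CDF that
  spreads each bin's mass over its width, accurate to half a bin for a point
  mass and nearly exact for flat spectra.
* **Temporal (5).** The waveform is rectified and low-pass filtered at 50 Hz
  (4th-order Butterworth, zero phase), normalized to a distribution over time
  from call onset: mean, sd, skewness, kurtosis, normalized entropy.
* **Fundamental (5).** Frame-wise f0 (20 ms frames, 5 ms hop) from the
  highest normalized autocorrelation peak in the 300–6000 Hz lag band. Peaks
  are picked on the *biased* autocorrelation — its linear lag taper makes the
  true period beat its own multiples, avoiding octave-down errors — refined
  parabolically, and scored by a lag-bias-corrected saliency in [0, 1].
  Frames with saliency below the voicing threshold (default 0.5) are
  unvoiced. Features: mean/min/max/CV of f0 over voiced frames plus mean
  saliency over all frames; the fifth feature can be switched to the voiced
  fraction via `fifth_feature="voiced_fraction"` since either is a defensible
  voicing summary.

All 18 features are invariant to waveform amplitude scaling (normalized
distributions; normalized autocorrelation). Unvoiced calls yield missing f0
statistics, carried as NaN / empty CSV fields; imputation is deferred to the
classifier so extraction stays lossless.

## Identity classification

The discrimination design is pairwise: for each unordered pair of vocalizers,
stratified cross-validation (10-fold when the smaller class has ≥ 10
renditions, else 5-fold) yields a pooled (correct, tested) count, reported as
percent correct classification (PCC; 50% is chance) with a two-sided exact
binomial test against 0.5. A (vocalizer, call type) cell needs at least five
renditions to enter any analysis. Multiclass tasks (chance `100/k`%) are
provided for illustration-style analyses.

Per fold, preprocessing uses training statistics only: missing f0 features
are imputed with the training-fold class-unconditional mean and a binary
missingness indicator column is appended (so an unvoiced-vs-voiced contrast
remains learnable); features are then z-scored. Classifiers:

* **reg-LDA** — shrinkage LDA with analytic Ledoit–Wolf intensity
  (`solver="lsqr", shrinkage="auto"`); parameter-free and never singular.
* **QDA** — per-class Ledoit–Wolf-shrunk covariances with a diagonal
  fallback if a class covariance is still singular.
* **RF** — 200 trees, seeded; ties in vote fractions resolve to the
  lexicographically smaller vocalizer id for determinism.

Spectrogram-space classification flattens Gaussian-window log spectrograms
(2 ms sd, 5 ms step, ≤ 12 kHz, decimated frequency axis), center-crops or
pads each call to its type's median frame count, and projects each training
fold onto principal components retaining 95% variance before the classifier.

Cross-type generalization trains on one set of call types and tests on
another: *Same* is within-type cross-validation; *Other* trains on the pooled
renditions of the other call types (at least five when the repertoire offers
them, otherwise all available, logged) and tests on every rendition of the
held-out type; a train-type × test-type matrix holds single-type transfer
with the Same condition on its diagonal. Feature-subspace comparison repeats
the pairwise identity analysis on the All/Spect/Temp/Fund spaces and, for the
call-type objective, classifies per-vocalizer mean feature vectors by call
type.

## Behavioral odds ratio

For a trial log with rewarded (Re, 20% of trials) and nonrewarded (NoRe)
playbacks, performance is

    OR = log2( [p_NoRe / (1 - p_NoRe)] / [p_Re / (1 - p_Re)] ),

with `p_role = interrupted / total`. Zero cells get the Haldane–Anscombe
+0.5 correction on all four counts (applied only when needed, flagged on the
result). Significance uses the two-sided conditional exact
(Fisher/hypergeometric) test, with the matching exact conditional confidence
interval; both are isolated behind single functions so a different exact
construction can be substituted. Running OR uses windows of 30 trials
(step 1) — trial counts, not wall-clock, for stable per-window sample size —
while the session analysis bins by elapsed time into three consecutive
30-minute sessions (left-closed/right-open). The random-interruption null
band permutes interruption outcomes across trials, preserving the role
schedule and the total interruption count, and reports 5–95% (optionally
1–99%) quantiles. First-exposure analysis keeps each trial only while its
rendition has been heard at most twice; per-trial exposure ranks (VocRank =
prior trials of the same role and call type, RendRank = prior trials of the
same rendition) are exported for external mixed-model analysis rather than
modeled here.

## Numerical choices and degenerate inputs

Silence yields an all-floor spectrogram (floor 80 dB below peak) and
NaN-flagged spectral/temporal features; calls shorter than one analysis
window are padded with a warning; f0 or formant targets pushed outside the
valid band by offsets are clamped with a warning; a single-role trial log is
rejected for the whole-test OR and skipped for windows; degenerate 2×2
margins give p = 1. Stratified folds, forest seeds and permutation draws are
all deterministic given the configured seeds.

## Problem sizes

Test and acceptance runs are sized for a single CPU: chance-level
calibration uses 11 vocalizers × 10 renditions (multiclass) and 21
vocalizers × 12 renditions → 210 pairs (pairwise); signature-recovery uses 4
individuals × 50 renditions per point of the strength grid; the transfer
dial uses the default study conditions above (1,500 calls per regime);
odds-ratio calibration uses 500 replicate logs of 500 trials. The full
default pipeline completes in about two minutes.

## Known limitations

* The exact binomial test on pooled cross-validated counts is mildly
  anticonservative: fold predictions share training data, so null rejection
  rates run above the nominal 5% (roughly 5–14% across population draws in
  the null calibration). Moreover, when many pairs are drawn from one shared
  population, pair outcomes are correlated (every vocalizer appears in many
  pairs), so the across-replicate spread of the mean null PCC and of the
  rejection rate is several times the nominal binomial scale. Both are
  properties of the cross-validation + exact-test design itself, which the
  package reproduces deliberately; for strictly calibrated inference, use
  label permutation instead.
* With 10 individuals, the cross-type transfer PCC of a single population
  draw scatters around its expectation with an sd of roughly 3 percentage
  points; spurious cross-type offset correlations in one small population
  sample can move the `rho_voice = 0` transfer a few points off 50%.
* Fisher's conditional test is conservative at small margins; its type-I
  rate approaches 5% only for the trial counts used here (hundreds of
  trials).
* The exact construction of the behavioral "exact test" and of the null band
  (per-trial vs. per-stimulus permutation) admits variants; both live behind
  single functions (`behavior.exact_or_test`, `behavior.null_band`) precisely
  so they can be swapped.
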