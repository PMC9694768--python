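# Methods

## Signal model and what the synthetic generator emulates

The generator produces phenomenological EGG: per channel,

x(t) = A·sin(2π ∫ f(τ) dτ) + D·sin(2π f_d t + φ) + w(t) + artifacts,

with instantaneous frequency f(t) = f₀ + j(t), where j is a discrete
AR(1) process (coefficient 0.99) whose stationary SD is the configured
jitter. The baseline state uses f₀ = 3 cpm, A = 100 µV, jitter SD
0.15 cpm; the nausea state f₀ = 6 cpm, A = 150 µV, jitter SD 0.6 cpm —
a frequency shift, amplitude increase and loss of regularity, which is
the canonical dysrhythmic signature. Baseline wander is a 0.3 cpm,
200 µV sinusoid with random phase; w is white Gaussian noise (SD 10 µV);
artifacts are Poisson-placed (0.5/min) biphasic single-cycle spikes of
1000 µV peak and 1.5 s width, with the ground-truth mask kept. Sampling
is 2 Hz; segments last 420 s (~7 min drive scenes); a session is four
segments (baseline, highway, countryside, rest). Nausea labels are
assigned to round(prevalence·4·n_subjects) segments (prevalence 0.176 →
12 of 68 for 17 subjects), preferentially off-baseline since baseline
precedes sickness induction; each positive segment receives one
button-press event.

The AR(1) jitter model is a choice, not an identified model: it yields
narrowband spectra at baseline and visibly broadened spectra under
nausea. The amplitude scale is order-of-magnitude only (µV range); the
real amplitude distribution of cutaneous EGG is not characterised here,
and channels are independent — no gastric conduction or inter-channel
coupling is modelled. Consequently, passing tests demonstrate that the
pipeline recovers planted structure under controlled noise; they do not
certify performance on real recordings, whose between-segment
heterogeneity is far larger (see "Known limitations").

## Noise injection and the two SNR conventions

White Gaussian noise is scaled against the *raw* segment so that
10·log₁₀(ms(signal)/ms(noise)) equals the target exactly (ms = mean
square); the sum is then bandpassed, which colours the noise to the
1–10 cpm band. One independent realisation per (segment, channel),
seeded from (cohort seed, subject, segment, target), so any stage can
be reproduced in isolation. Because the filter removes most wideband
noise power but only part of the signal is in band, the achieved
in-band SNR — filtered signal power over filtered noise power, both
passed through the identical filter — differs from the target; with the
default generator it sits 1–2 dB above it. The averaging domain is
ambiguous in general, so both conventions are computed: the mean of
per-record dB values and the pooled power ratio.

## Preprocessing

The bandpass is a 6th-order Butterworth applied forward and backward
(zero phase; effective magnitude order 12). "Order" is read as the
design order; a `halve_order` switch gives the 3rd-order-design/6th
-effective reading. Artifact handling replaces expert visual deletion
with a deterministic detector: the robust z-score (median/MAD) of the
*first difference* of the signal, threshold 5, with flagged samples
dilated into runs capped at 3 s. Scoring the derivative keeps the
slowly-varying gastric component and baseline wander out of the scale
estimate, so spikes are detected regardless of wave amplitude; a
constant signal (MAD = 0) returns an all-false mask. User-supplied
masks are honoured throughout. Detection operates on the raw signal and
excision happens after filtering, by concatenating clean runs (no
interpolation); the excised fraction is recorded per segment. The
channel with the fewest masked samples is selected (ties → lowest
index). Segment labelling uses half-open intervals [start, end); a
segment is nausea-positive iff at least one button press falls inside.

## The feature battery — numerical conventions

- PSD: full-segment Hamming periodogram of the mean-removed signal
  (density scaling, µV²/Hz). An 840-sample segment resolves 0.143 cpm,
  needed to localise DF; Welch (N/4 segments, 50 % overlap) is a config
  option. All band-limited features use the 1–10 cpm sub-band.
- Median frequency: first in-band bin whose cumulative power reaches
  half the in-band total. DF: in-band argmax (ties → lowest frequency);
  MagDF is the PSD value there, reported in µV²/Hz.
- Crest factor: in-band peak over RMS of the PSD values (peak/mean via
  config); flat spectrum → 1. SDV: percentage of in-band bins whose PSD
  exceeds 25 % of MagDF ("25 % of DF" is read as 25 % of the magnitude
  at DF; a fraction of the frequency value would be dimensionless
  nonsense).
- Sample entropy: Chebyshev distance, overlapping templates,
  self-matches excluded, both A (m+1) and B (m) counted over the N−m
  template start positions; SampEn = −ln(A/B). When A·B = 0 the
  Richman–Moorman bound −ln(2/((N−m−1)(N−m))) is substituted (≈12.8 at
  N = 840, m = 2), which is what makes the categorical low/high split
  at 10 meaningful for degenerate segments. The tolerance is
  r = 0.15·SD of the noiseless reference: for original data the
  segment's own SD, for noisy twins the SD of their clean original (and
  for SampEntP, of its in-band PSD sequence) — noisy and clean twins
  are measured with the same yardstick. Segments are used as filtered
  (already mean-free).
- Spectral entropy: Shannon entropy of the normalised in-band PSD,
  divided by ln(bin count) by default (0 = one-hot, 1 = flat).
- Autocorrelation zero-crossing: biased mean-removed estimator,
  r(0) = 1; first lag with r ≤ 0, no interpolation between lags;
  (N−1)/fs when no crossing exists.
- Poincaré: SD1² = Var(diff)/2, SD2² = max(0, 2·Var − SD1²),
  SDEGG² = (SD1²+SD2²)/2 (n−1 variances). This SDEGG definition is the
  one that reduces to the sample SD of the segment, which is its stated
  meaning.

## Statistics

Noise robustness is a paired design over the 68 segments: Shapiro–Wilk
(α = 0.05) on the paired differences gates a paired t (Cohen's d =
mean/SD of differences) against a Wilcoxon signed-rank (statistic V =
sum of positive-difference ranks, zeros discarded) with Cliff's delta.
A constant nonzero difference vector routes to the rank branch
(normality and d are undefined there); an all-zero one returns a
degenerate p = 1. The nausea effect is unpaired: per-group Shapiro–Wilk
gates Welch's t (fractional df, pooled-SD d) against Mann–Whitney U
(W = pairs with group0 > group1, +½ per tie) with delta; group 0 is the
non-nausea segments, so negative delta means larger values under
nausea. The categorical entropy split (low/high at 10) is tested by
Pearson chi-square with a Monte-Carlo p under fixed margins (Patefield
sampling, (1+exceedances)/(n_sim+1)). Effect magnitudes use |d| ≥
0.2/0.5/0.8 and |δ| ≥ 0.147/0.33/0.474 (a "paper-style" mode applies
the d cut-points to δ as well); boundaries are inclusive upward. No
multiple-testing correction is applied by default (a Holm option
exists). The 68 segments are treated as exchangeable — within-subject
correlation is ignored by design, a known caveat of the protocol.

## Classifier protocol

Labels are the two-level factor {no_nausea, nausea}; the *positive*
class is no_nausea (the majority level): with 17 test rows the
reference confusion TP=14, FP=2, FN=0, TN=1 jointly reproduces
accuracy 0.882, kappa 0.452, sensitivity 1.000, specificity 0.333,
precision 0.875 and the exact binomial CI (0.636, 0.985), which no
other orientation does. Reports carry both orientations since prose
and tables in the field often disagree on it. The split is stratified
(per class, round(0.75·n) to training → 51/17 with 9/3 positives);
mtry is tuned by leave-one-out CV over {2, 9, 17} (accuracy argmax,
ties → smallest); the forest is a seeded (seed 100) 500-tree bagged
ensemble with mtry candidate features per split. Training AUC comes
from the LOO-CV vote fractions (a convention — resubstitution is the
alternative; which one produced the published constant is unknowable),
test AUC from the held-out vote fractions. Importance is the
per-feature count of split usages summed over all trees. Variant 1
re-runs the full protocol per noisy table; variant 2 evaluates the
original-table model on the noisy twins of the same held-out rows, with
identical split indices everywhere.

## Problem sizes

The bundled demonstration uses 17 subjects × 4 × 420 s segments at
2 Hz, five SNR targets, and a 128–200-tree forest in the scripted runs
(the library default stays 500); leave-one-out tuning over three grid
points on 51 rows is the dominant cost. Property suites use ≥ 200
random instances of length ≤ 50 against exhaustive brute-force oracles.

## Known limitations

- Synthetic segments are far more homogeneous than real EGG, so paired
  tests at n = 68 detect even tiny systematic feature shifts; robustness
  orderings measured here can differ from those on real cohorts. In
  particular, MagDF's response to injected noise is dominated by the
  signal–noise cross term of the single-taper periodogram, whose sign is
  random per segment — MagDF therefore looks *robust* at mild SNRs on
  this cohort, while the entropy of the PSD sequence picks up the
  raised noise floor consistently. A smoothed PSD estimator (Welch)
  shifts both behaviours.
- No 1/f or powerline noise, no coupling between channels, no
  physiological conduction model.
- Achieved SNRs depend on the in-band power fraction of the clean
  signal, so values measured on synthetic cohorts do not transfer to
  any particular real dataset.
- The external-validation path exercises schema mapping and the full
  protocol, but published external metric values can only be compared
  when the corresponding shared feature tables are supplied by the
  user.
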