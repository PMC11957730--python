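# Methods

This note documents the models, algorithms and numerical choices behind
`erpmvpa`, and what the synthetic-data tests do and do not establish about
real recordings.

## Scientific setting

The package implements the analysis chain used to look for neural
signatures of near-human ("uncanny") visual stimuli: participants judge
images as human or non-human while EEG is recorded. Three questions drive
the analysis. How well do observers discriminate each category from real
faces (signal detection)? Do event-related potentials (ERPs) at posterior
electrodes differ between conditions (mass-univariate Bayes factors)? And
does the multichannel scalp pattern carry condition information even where
the pooled ERP does not (timepoint-wise multivariate decoding)?

## Behavioural model: asymmetric d′

Hit and false-alarm rates are condition-specific. For the human condition,
hit = P(judged human | human image) and fa = P(judged human | any non-human
image, pooled). For each non-human condition, hit = P(judged non-human |
that condition) and fa = P(judged non-human | human image); all non-human
conditions in a table therefore share one false-alarm rate, which the tests
assert. Sensitivity is

    d′ = Φ⁻¹(hit) − Φ⁻¹(fa),

clipped to ±5. The cap is applied to any |d′| > 5, not only to infinities:
a perfect hit rate with non-zero false alarms still diverges otherwise, and
the symmetric rule preserves the antisymmetry d′(h, f) = −d′(f, h). When
hit = fa (including 0/0 and 1/1) d′ is defined as exactly 0. No log-linear
(Hautus) correction is applied: the cap is the stated convention, and both
conventions cannot hold at once. A consequence worth knowing: for true
d′ ≈ 4 and fewer than ~100 trials per condition, perfect observed hit rates
are common and the capped group estimate is biased upward; the acceptance
test for reproduction mode accounts for this.

Per-participant d′ is computed first and then group-averaged (matching
per-participant dots in the standard figures); a pooled-rates alternative
is not provided because averaging capped participant values is what the
cap-at-5 convention implies. Reaction times are log-transformed before any
averaging; summaries are back-transformed geometric means in ms. Error
trials are included in RT averages by default (`correct_rts_only` switches
this), since the exclusion rule is not specified by the judgement task.

## JZS Bayes factors

The default Bayesian t-test places a Cauchy(0, r) prior on the
standardised effect size — equivalently δ | g ~ N(0, g) with
g ~ InverseGamma(1/2, r²/2) — and a Jeffreys prior on the variance. For a
one-sample/paired t with n observations (ν = n − 1),

    BF₁₀ = ∫₀^∞ (1+ng)^(-1/2) (1 + t²/((1+ng)ν))^(-(ν+1)/2) π(g) dg
           / (1 + t²/ν)^(-(ν+1)/2).

The scale defaults to r = √2/2 ≈ 0.707, the common default of standard
Bayes-factor software; it is config-exposed and recorded in the run
manifest. Integration substitutes g = u/(1−u) and runs adaptive quadrature
on (0, 1); the integrand is evaluated in log space with a grid-located
shift, so t statistics in the hundreds neither overflow nor lose the peak.
Agreement is verified two independent ways: against pingouin's
implementation (1e-6 relative) and against a 10⁶-draw stratified
Monte-Carlo evaluation of the same integral (0.1%).

Timecourses apply the test at each timepoint with no multiple-comparison
correction, matching the raw-BF presentation convention; Bayes factors are
empirically conservative here (null simulations show < 5% of timepoints
with BF₁₀ > 3 at n = 24). Zero-variance timepoints are flagged, not fatal.
Evidence categories: BF₁₀ < 1 null-leaning, 1–3 anecdotal, > 3 some, > 10
strong, > 30 very strong.

## Preprocessing

- **Filter**: 0.5–30 Hz zero-phase FIR. Hamming-window designs with 0.5 Hz
  transition at the low edge and 7.5 Hz at the high edge (cutoffs placed
  half a transition outside the passband) are convolved into one kernel and
  applied forward-backward in the frequency domain (|H(f)|² response,
  zero-padded FFT). Verified gains: within ±1 dB over 1–25 Hz, > 30 dB down
  at 0.05 Hz and 50 Hz. Epochs shorter than the kernel are filtered with
  the same response but carry edge transients — unavoidable for any offline
  filter; the filter-then-epoch order (`bandpass_array` on continuous data)
  avoids this and is the default pipeline order.
- **Epoching** cuts −200…+1000 ms (default) around event onsets; events too
  close to a recording edge are reported and skipped, never silently
  dropped.
- **Baseline**: per trial and channel, the mean over [−200, 0) ms is
  subtracted (half-open, so the onset sample is excluded). Idempotent, and
  commutes with electrode pooling.
- **Exclusion**: a participant is dropped when more than 20% of trials
  contain any sample beyond ±100 µV. EEG reports often exclude noisy
  participants without stating a quantitative rule; this operationalisation
  makes the rule explicit, and both numbers are config-exposed.
  Behavioural data are never affected by EEG exclusions.
- **Pooling**: unweighted mean over P6, P8, PO6, PO8 (face-sensitive
  posterior sites) by default.
- **Grand means** carry 95% percentile-bootstrap bands over participants
  (default 2000 resamples). Percentile bootstrap undercovers slightly at
  small n (~90% at n = 12, ~94–95% by n ≈ 30–60); the coverage test runs at
  n = 60.

## Decoding scheme

At one timepoint, features are the raw voltages of all channels, unscaled.
Per permutation and per class, `n_exemplars` = 4 disjoint subsets of
round(0.2 · n) trials are drawn and averaged into training exemplars; the
test set is the remainder, disjoint from training by construction.
Disjoint draws are the default reading because independent 20% draws could
leave no guaranteed held-out trials; an overlapping variant (test =
complement of the union) is available via `disjoint=False`.

The classifier is a linear soft-margin SVM with C = 1. The dual problem
(8 training points at the defaults) is solved by a compact SMO routine with
maximal-violating-pair selection, jit-compiled; it reproduces libsvm
solutions (sklearn's `SVC`) to ~1e-5 in weights and intercept, which the
test suite checks on random problems, while running ~400× faster per fit —
the difference between hours and minutes for a cohort × timepoints ×
permutations analysis. Ties at decision value exactly 0 go to the first
class in sorted label order, so runs are exactly reproducible. If both
classes present identical exemplar sets the fit is flagged degenerate and
scores at chance.

Accuracy is the mean of the two per-class accuracies ("balanced"). With
balanced designs this equals raw accuracy; with a 2:1 imbalance it
preserves the 50% chance anchor that raw accuracy would lose. A config
flag restores raw accuracy. Default 1000 permutations; 1000 vs 4000
permutations differ by < 1 percentage point on fixture data.

RNG streams are derived per (seed, participant index, timepoint index), so
the accuracy matrix is independent of execution order and identical across
machines. `time_decim` decodes every k-th sample to trade resolution for
runtime. Group-level evidence versus chance is the one-sample JZS test on
accuracy − 0.5 at each decoded timepoint.

Not implemented by design: temporal generalisation matrices, channel
searchlights, cross-participant decoding, and per-pattern normalisation
before classification (default none; raw voltages are the field-standard
feature choice for this scheme).

## Synthetic cohorts

`simulate_epochs` builds each trial as

    Σ_k a_k (1 + ε) G(t; λ_k + η, w_k) u_k  +  effect terms  +  noise,

with Gaussian temporal kernels G (the components are only named with
latencies in the literature, so a smooth analytic shape is chosen): P100
(+5 µV, 100 ms, 15 ms SD, medial occipital topography), N170 (−6 µV,
170 ms, 20 ms SD, lateral posterior), P200 (+4 µV, 220 ms, 30 ms SD,
broader). ε is multiplicative amplitude jitter (SD 0.1) and η latency
jitter (SD 5 ms), per trial. Noise is 1/f^α pink noise (α = 1, SD 8 µV,
frequency-domain synthesis with analytic SD normalisation; the log-log
periodogram slope test recovers −α) plus white noise (SD 2 µV).

Condition effects add amplitude × pattern × Hann(window) to the second
condition of a pair only. Effect patterns are drawn orthogonal to the
component topographies (QR projection), so pooled-electrode univariate
tests can legitimately miss effects that the multivariate decoder finds —
the key contrast the method is designed to expose. The default effect
amplitude is 10 µV along a unit-norm 32-channel pattern (~1.8 µV per
channel), which puts synthetic group decoding peaks in the low-60s
percent — the regime reported for human-vs-android and human-vs-silicone-
mask comparisons; amplitude is a free config axis.

Defaults are a desk-scale cohort: 20 participants, 30 trials/condition,
32 channels at 250 Hz, epochs −200…+1000 ms. This preserves the structure
of a 64-channel 1 kHz recording at a fraction of the cost; the full scale
is reachable through config. Default two-window effects sit at 100–200 ms
and 580–620 ms.

Behaviour: trial evidence ("humanness") is N(µ_c, 1); the human condition
sits at +d̄/2 (d̄ = mean configured sensitivity over non-human conditions
present) and each non-human condition at µ_human − d′_c, so every
human/non-human pair is separated by exactly its configured d′ and the
non-human d′ estimates are criterion-free. Responses threshold evidence at
the criterion (0 = neutral); RTs are log-normal per condition (defaults
match geometric means near 700–800 ms with σ_log = 0.25). Ratings are
discretised clipped normals around per-condition means.

What the generator does *not* emulate: eye-blink/muscle artifacts, channel
covariance of real noise (noise is independent across channels),
inter-participant topography variability, overlapping responses from fast
presentation, or any image-computable stimulus structure. Passing the
recovery tests therefore shows the *estimators* are unbiased and sensitive
under the assumed model, not that real uncanny-valley effects have any
particular size.

## Problem sizes used in the automated checks

Chance calibration and two-window recovery run at 20 participants ×
30 trials/condition × 301 timepoints with 200 permutations; behavioural
recovery at 20 × 180 trials; the Monte-Carlo oracle at 10⁶ draws per
(t, n) cell. These sizes give Monte-Carlo error comfortably inside each
test's tolerance while keeping a full run in minutes.

## Known limitations

- The epoch container is deliberately minimal (float64 + JSON sidecar);
  EEGLAB/BrainVision import bridges are not implemented — convert upstream.
- ICA cleanup, channel interpolation and re-referencing are out of scope;
  inputs are assumed referenced (e.g. whole-head average) already.
- Repeated-measures ANOVA Bayes factors are not provided; all reported
  comparisons are covered by the pairwise tests.
- The percentile bootstrap undercovers mildly below ~20 participants.
- With `subset_fraction` and class sizes such that round(0.2·n) < 1 or no
  test trial remains, decoding raises a named infeasibility error rather
  than silently degrading.
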