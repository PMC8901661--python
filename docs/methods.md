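# Methods notes

This note documents the models, defaults and design choices behind
`vocalence`, in the spirit of a package's statistical documentation: what
each stage assumes, which knobs matter, and what the synthetic data do and
do not establish about real recordings.

## Synthetic call model

Recorded pig calls are not available to this package's test suite, so
every stage is exercised on synthetic calls.  A call is

    w(t) = [ sqrt(q) * H(t) + sqrt(1-q) * N(t) ] * A(t) * M(t) + floor(t)

* `H(t)`: a harmonic stack — fundamental `f0` (LF: ~140 Hz; HF: about a
  third of the target center) plus integer partials, each weighted by a
  Gaussian in frequency centred on the target spectral center of gravity
  with a per-call-type half-width (LF 220 Hz, HF 900 Hz).  Random phases
  per partial.
* `N(t)`: Gaussian noise spectrally shaped to a Gaussian band around the
  same center but twice as wide.  The width factor matters: Wiener
  entropy is largely an occupancy measure, so the noisy component must
  occupy visibly more spectrum than the partials for the tonality
  contrast to appear in the extracted features.
* `q`: tonal-to-noise energy ratio (both components normalized to unit
  RMS first).
* `A(t)`: 15 ms raised-cosine attack and decay.
* `M(t) = (1 + m sin(2 pi f_am t - pi/2)) / (1+m)` with `m` chosen so the
  intensity contour swings by the drawn AM extent in dB peak-to-trough:
  `extent = 20 log10((1+m)/(1-m))`.
* `floor(t)`: white noise 60 dB below the call RMS, the ever-present
  recording floor of a real microphone chain.  Without it the spectrum is
  exactly zero outside the call band and spectral flatness degenerates.

Pigs are allocated round-robin to recording teams.  Each team carries a
random offset on log-duration (sd 0.05) and log-center (sd 0.03), and
each pig an additional offset (sd 0.12 and 0.06).  These offsets are what
the pDFA's control factor and the mixed models' nested random effects
exist to absorb.  Each pig keeps one age class (class 1: 1–25 d, class 2:
32–43 d, class 3: >= 85 d); age scales the spectral center by 1.1 / 1.0 /
0.9, echoing that piglets call higher.

### Default study conditions

Per-cell parameter means (sd in parentheses):

| cell | Dur s | AM rate Hz | AM extent dB | center Hz | tonal q |
|------|-------|------------|--------------|-----------|---------|
| LF negative | 0.50 (0.12) | 12 (2) | 10 (0.5) | 450 (60) | 0.70 |
| LF positive | 0.35 (0.12) | 7 (2)  | 10 (0.5) | 620 (60) | 0.94 |
| HF negative | 0.80 (0.16) | 12 (2) | 10 (0.5) | 3300 (200) | 0.94 |
| HF positive | 0.55 (0.16) | 7 (2)  | 10 (0.5) | 2700 (180) | 0.60 |

These encode the four reported valence contrasts: shorter calls and fewer
amplitude modulations in positive contexts for both types; Q50 up
(positive) for LF and down for HF; Wiener entropy down (more tonal) for
positive LF and up for positive HF.  Durations were spread so that the
mixed-model marginal R² for duration lands in the 0.2–0.4 band
characteristic of a "large" valence effect on call length.  The AM extent
is deliberately valence-neutral and nearly constant: its measured values
then share variance with the AM rate through the contour rather than
forming an independent axis, which is what lets the PCA screen identify
AmpModRate as the informative amplitude-modulation parameter.

Nineteen context labels map to a fixed valence each (11 negative, 8
positive) with strongly imbalanced sampling weights (Isolation dominates;
Surprise is rare), HF calls are drawn with probability 0.33 in negative
and 0.10 in positive contexts, and age-class probabilities are
0.4/0.3/0.3.  The per-context weights are illustrative: the real
per-context counts are not published in a machine-readable form, only
their extremes.

What the generator does **not** emulate: vocal-tract filtering and real
pig timbre, arousal as a separate dimension, background noise and
reverberation beyond the flat floor, age-dependent duration, context
effects beyond their valence, or serial correlation within recording
bouts.  Tests passing on this material show the *pipeline* behaves as
specified, not that real calls are this separable.

## Feature extraction

* Intensity contour: 10 ms frames advanced by 1 ms, RMS in dB re full
  scale, floored at −70 dB.  This resolves amplitude modulation up to
  ~50 Hz.
* The contour is zero-phase low-pass filtered (4th-order Butterworth,
  50 Hz) before the AM measures: frame-RMS ripple at the fundamental
  (an LF grunt's f0 period is comparable to the frame length) is not
  amplitude modulation.  Contours with fewer than ~22 frames, or sampled
  too coarsely for the filter, are used raw — this keeps tiny hand-built
  contours exactly as written.
* An AM cycle is a smoothed-contour peak with >= 2 dB prominence; its
  extent is the peak minus the mean of the adjacent minima; no qualifying
  peak means AmpModRate/AmpModExtent are missing, not zero — mirroring
  the real datasets where AM could not be measured for some calls.
* Average spectrum: Welch mean of Hann-windowed 2048-point frames (whole
  call if shorter).  Quartiles are the smallest frequencies reaching
  25/50/75 % of cumulative power; Wiener entropy uses the natural log
  with a relative power floor of 1e-12 so it is finite; it is clamped at
  0 from above.  Log base only rescales the measure.
* Harmonicity: maximum of the lag-unbiased normalized autocorrelation
  over lags corresponding to 60–2000 Hz, mapped by `10 log10(r/(1-r))`
  and clamped to [−10, 40] dB.  The unbiased correction matters: the raw
  (biased) estimate caps a pure tone at ~20 dB.
* Call typing: HF iff Q50 strictly exceeds the age-class cutoff
  (2414/2153/896 Hz); a value exactly at the cutoff is LF.  The tie rule
  is arbitrary but fixed and tested.

## PCA screen and mixed models

The PCA runs per call type on z-scored complete cases (correlation
matrix), retains components with eigenvalue > 1 (falling back to the
first component if none qualifies), and selects within each of the four
parameter categories the parameter with the largest absolute loading
(eigenvector scaled by sqrt(eigenvalue)) on any retained component; ties
break alphabetically.  The retention and selection rules are explicit
choices; other conventions (covariance PCA, scree cutoffs) would be
defensible but are not what this package implements.

Mixed models are Gaussian with identity link: fixed factor of interest
(valence or context) plus age class, random intercepts for team and for
pig nested in team, fitted by maximum likelihood so the factor can be
tested by a likelihood-ratio chi-square against the model without it.
Marginal R² is var(fixed linear predictor) divided by the sum of that
variance and all random-effect and residual variances.  Degenerate
designs degrade gracefully: a constant outcome yields zero components and
p = 1 with a warning; a single team pins the team component at 0.

## Permuted DFA

Classification operates on the four selected parameters (configurable).
From every (pig × level) cell with at least `min_calls_per_cell` (default
2) complete-case calls, exactly that many calls are drawn into the
balanced derivation set; all remaining complete-case calls are the
holdout.  Linear discriminant functions use the pooled within-class
covariance and **equal priors** — priors must not re-encode the class
imbalance that the permutation chance level is there to measure.  A
singular pooled covariance is ridge-regularized by `1e-6 * trace/dim`
with a warning.

The null permutes test-factor labels within each pig; pigs observed at a
single level keep their labels (conservative, and the only scheme that
respects the control factor in an incomplete crossed design).  Chance
levels are permutation means.  Reported percentages average
`n_selection_reps` (default 100) balanced re-draws, but the p-value
compares a *single* draw with true labels against single-draw
permutations, `p = (#{perm >= obs} + 1) / (n_perm + 1)`.  Averaging the
observed statistic over many draws while permuted statistics use one draw
would give the observed value systematically less selection noise than
its reference distribution and de-calibrate the test; with the
like-for-like comparison the p-value is exact under exchangeability,
which the 500-run calibration in the acceptance checks verifies
empirically (rejection rate at alpha = 0.05 close to nominal, two-level
chance level at 50 %).

The balanced-selection rule (all sufficiently large cells contribute
equally) is one reasonable instantiation; the exact subset rule behind
the published per-analysis "calls selected" counts is not derivable from
public material, so those counts are not reproduction targets.

## Spectrogram classifier

Spectrograms follow the published recipe: central zero-padding to 3.595 s
(split equally, to the sample), 3 ms Hann window, hop of 1 % of the
window length, 512-point DFT, log magnitude, bilinear resize to the
network input (48 × 48), per-image min–max normalization.  The window
length is `round(0.003 * sample_rate)` samples and is zero-padded to the
DFT length; the recipe is stated in time units because the source
protocol names no sample rate.  Desk-scale runs (tests, acceptance) use
8 kHz audio and a 25 % hop to keep the short-time transform tractable;
the hop is a configuration field, not a code path change.

The bundled backbone is a three-block numpy CNN (8/16/32 3×3 filters,
ReLU, 2×2 max-pool, 64-unit penultimate fully connected layer, softmax),
trained with minibatch SGD + momentum 0.9, initial lr 0.001, drop factor
10^-0.5 every 10 epochs (the drop period is not published; 10 epochs is
this package's default), batch 32, stratified 70/30 split per trial, and
the best-validation-accuracy checkpoint kept.  Metrics per trial:
accuracy, precision, recall, F1 — binary with the positive-valence class
as positive for the valence task, support-weighted across classes for the
context task; the cross-trial uncertainty is the standard error of the
mean, consistent in magnitude with published ±0.003-scale uncertainties.
A large pretrained transfer backbone is deliberately not bundled;
requesting one raises an informative error.  Published full-scale
accuracies (91.5 % valence, 81.5 % context) belong to the real
7414-call dataset and pretrained weights and are outside what synthetic
desk-scale runs can or should reproduce.

## t-SNE maps

Activations are taken from the penultimate fully connected layer, one
vector per spectrogram.  t-SNE uses perplexity 50 for valence maps and 20
for context maps by default (scaled down automatically when n is small),
PCA initialization and a fixed seed, so embeddings are reproducible.
Negative calls plot as triangles, positive as circles.

## Aggregation and reporting

LF and HF analyses are combined as weighted averages with complete-case
call counts as weights — this is the weighting that reproduces every
published dataset-level percentage from the published per-type cells
(weighting by derivation-subset sizes does not).  Relative
cross-classification is cross-classified percent over its chance level.
Rounding (1 decimal for percentages, 2 for ratios) happens only at
presentation.

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen as
sensible desk-scale conditions: 200 calls per (type × valence) cell for
direction recovery; 500 simulated null datasets (16 pigs × 40 calls, so
the holdout accuracy grid is fine enough that permutation ties are
negligible) × 100 permutations for calibration; 240 two-band calls,
48 × 48 images, 4 epochs, 2 trials for the CNN checks; 44.1 kHz audio
everywhere except the CNN fixtures (8 kHz).

## Known limitations

* The synthesizer's controllability is its purpose; none of its
  parameters were fitted to real audio.
* Wiener entropy here, as in real data, conflates tonality with
  bandwidth occupancy; the generator holds bandwidth fixed per call type
  so the tonality contrast is identifiable.
* The LMM uses a chi-square reference for the likelihood ratio; with few
  teams the team variance component is weakly identified (it is retained
  as a nuisance, not interpreted).
* pDFA p-values are exact only under within-pig exchangeability of
  labels, which excludes e.g. time trends within a pig's recordings.
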