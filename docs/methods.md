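# Methods

This note documents the models, defaults, and numerical choices behind
`saveseq`, and what the synthetic-data tests do and do not establish about
real recordings.

## Task model

A session is a series of *saving sequences*: runs of save choices ending in
one spend choice. Reward grows geometrically, `x_n = b Σ_{i=0}^{n-1} q^i`;
for `q ≠ 1` the closed form `b(q^n − 1)/(q − 1)` is evaluated in
`expm1`/`log1p` form so it stays accurate as `q → 1`. Display rounding of
reward magnitudes is three decimals, half-up.

Subjective values are empirical: per interest rate, `P_i` is the raw
relative frequency of sequences of length *i* (no smoothing; unobserved
lengths get probability 0, pooled across sessions per interest rate),
`SVspend_i = P_i x_i`, `SVsave_n` is the unweighted mean of future spend
values, and a sequence's own value (`SeqSV`) is the spend value realized at
its final length. At the maximal observed length there is no future,
so `SVsave` is set to 0 there for regression purposes.

## Synthetic experiments

The generator produces the statistical structure the analyses assume, not a
biophysical simulation. Its defaults are the package's study conditions:

- **Behavior.** One interest rate (q = 1.5, base rate 0.11 ml) with a
  length distribution over 2–7 trials peaked at 3–4 (mean ≈ 4), 200
  sequences per session, and per-trial error probability 0.10 (at most
  three consecutive errors). These reproduce the qualitative features real
  animals show: mid-length preferences, hazard-shaped spend probability,
  errors that freeze sequence progress while retaining accumulated reward.
  An imperative session replays the free-choice sequence lengths so
  save/spend statistics are matched between tasks.
- **Reaction times.** Key-release latency follows a linear model with a
  negative progress slope (−10 ms/step), a negative progress × (1/length)
  adaptation interaction (−50 ms at full normalized progress), a spend-trial
  speedup (−30 ms), Gaussian noise (SD 50 ms) and a 50 ms floor; saccade
  latency has a small positive progress slope. Magnitudes are in the range
  reported for overtrained macaques.
- **Trial timing.** Fixation spot at 1.0 s (the preceding second is the
  control period), cues 2.0 s later, a 1.5 s post-choice delay, then the
  reinforcer; analysis windows are the five fixed periods (pre-fixation
  1000 ms; fixation 1775 ms from +25 ms; cue 300 ms from +20 ms; delay
  1500 ms from +25 ms; outcome 500 ms from +50 ms), half-open
  `[start, start+duration)`. Inter-trial timing variability (the truncated
  exponential fixation requirement of real sessions) is emulated only as a
  fixed mean; the schedule is configurable.
- **Spikes.** Inhomogeneous Poisson with piecewise-constant rate: baseline
  plus `gain × drive` inside the neuron's target periods, clipped at zero
  (clipping is logged; it biases strongly negative gains, which is why
  default gains keep `baseline + gain ≥ 0` only loosely). Each drive is
  normalized to a session maximum of 1 so `gain` is the rate increment in
  Hz at full drive, comparable across tuning models. Phasic modulation is a
  constant increment across the whole target period rather than a shaped
  kernel — the simplest form consistent with fixed-window counting.
  The reward-expectation control neuron ramps within each trial (increment
  scaled by the period's fractional time to outcome) but identically across
  steps: gradual within trials, non-adaptive across them. Default roster:
  baseline 3–8 Hz, |gain| 8–16 Hz, 72% positive gains, about half of tuned
  neurons free-choice-specific, progress neurons attenuated to 0.3 on error
  trials, ~55/45 basolateral/centromedial labels.
- **Reproducibility.** One global seed; per-neuron substreams derive from
  `(seed, crc32(neuron_id))`, so editing the roster does not perturb other
  neurons' spike trains. Identical configs write byte-identical files.

What passing tests therefore show: the analysis chain is *correct and
calibrated* under its own assumptions (Poisson noise, constant-rate
periods, i.i.d. sequences, no cross-neuron correlations). They do not show
that real amygdala data satisfy those assumptions, and pseudo-populations
deliberately ignore cross-correlation structure.

## Single-neuron statistics

Task-relatedness uses the paired Wilcoxon signed-rank test of each period
against pre-fixation with the strict criterion p < 0.0083 (the published
Bonferroni-corrected threshold, used verbatim). Model fits are OLS with
two-sided t-tests (significance p < 0.05); standardized coefficients are
`x_i s_i/s_y`. The step-indicator model omits the intercept (the indicators
span it); its R² is computed centered and its model-level p-value from the
F-test against the mean, so it is comparable with the other models.

Model contests are pairwise over matched responses (a *response* is one
neuron × task-related period). Win counts use R² within the paired scope;
exact ties count for neither model. The dependent-samples statistic on
discordant significance is `z = (n_A−n_B)/√(n_A+n_B)`. Where a single
*best-fitting* model must be named (model-recovery confusion), selection is
by BIC: models of equal size are then ranked exactly by R², while the
`ln n` parsimony penalty resolves nested contests — with raw or even
adjusted R², the step-indicator model, which nests every tuning that
depends on step alone, would win a coin flip against the true model no
matter how much data is available. Recovery is demonstrated for the five
classes with a one-to-one model counterpart (adaptive, non-adaptive, reward
magnitude, elapsed time, step tuning); the partial-adaptation and
reward-expectation phenotypes are supersets/degenerates of these and are
assessed by their own analyses instead.

Stepwise regression uses forward selection at p-to-enter 0.05 with backward
elimination at p-to-remove 0.10 (classic defaults; the method is named in
the source analyses without thresholds), plus a forced simultaneous mode.
Perfectly collinear columns are dropped in entry order and logged.

The sliding-window regression tiles 200 ms windows at 25 ms steps over
event-aligned segments (fixation −1.000→+1.825 s, cue −0.200→+0.520 s,
choice 0→+1.550 s, outcome −0.100→+0.650 s) stitched in task order — trials
have variable durations, so a single continuous clock would misalign
events. The run-length criterion is bootstrapped by permuting the regressor
across trials and finding the smallest L with P(max run > L) < 0.05; with
the default geometry on the default sessions this calibrates to L = 8.
Windows with zero count variance record p = 1.

## Population analyses

Activity is z-scored against the pre-fixation control period (mean/SD over
correct trials; zero-SD neurons are excluded and logged), optionally
sign-corrected by flipping responses with negative progress slopes.
Population progress slopes are fit on pooled trial-level activity; a
per-neuron averaging variant exists because the pooled/per-neuron choice is
genuinely open. Per-length fits include spend trials by default (option to
exclude). Consecutive sequences are adjacent sequence ids within one
session, task and interest-rate block. Error-trial coding compares pooled
and per-neuron progress slopes on pre-error, error, and post-error trials
(dependent-samples t-tests); the on/pre slope ratio estimates the error
attenuation of the underlying gain.

## Decoding

Per neuron, trials split into progress terciles by empirical quantiles with
boundary values assigned to the lower group (deterministic); quartiles are
available. Neurons need ≥5 trials per group; the per-group trial count is
equalized to the minimum across neurons by random subsampling within each
of 150 matchings (the matching procedure leaves this open; subsampling is
the least-assumption choice). Leave-one-out nearest-neighbor decoding uses
Euclidean distance with first-index tie-breaking under the documented
stacking order; the max-margin alternative is a linear-kernel SVM (kernels
beyond linear add nothing here). Per matching, accuracy is the fold-average
percentage correct; matchings are then averaged. Shuffle nulls permute the
label vector without replacement, 500 iterations by default (1500–5000 at
full scale), compared with real accuracies by a two-sided rank-sum test.
With unequal group sizes the nearest-neighbor null sits at Σ(s_g/Σs)²
rather than exactly 1/n_groups; chance-level checks use balanced groups.

## Problem sizes

Default analyses use 200-sequence sessions (~800 correct trials) and
rosters of 60 neurons. The heavier validation suites use 300 null neurons
for run-length calibration, 200 neurons per class for model recovery, 500
neurons × 4 periods (2000 responses) for type-I calibration, and 100
neurons for error-attenuation recovery — sizes chosen so each property is
measured with comfortable statistical margin on a single CPU.

## Known limitations

- Constant-rate phasic modulation; no shaped response kernels or latency
  jitter.
- No cross-neuron correlations, so decoding results are a lower bound of
  the simultaneous-recording case by construction.
- Error trials carry schedule marker times but no choice/reaction-time
  fields; analyses treat them only through the step-freezing and
  attenuation mechanisms.
- Negative-gain neurons can hit the zero-rate floor, making their effective
  tuning sublinear; sign-correction and rectified-slope covariates absorb
  most of this in population analyses.
- Real-data headline quantities (fractions of significant neurons, absolute
  decoding accuracies) depend on the recorded population and are not
  reproduction targets; the package validates calibration and recovery, not
  those numbers.
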