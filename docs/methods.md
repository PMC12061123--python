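# Methods

`affpriming` analyses a two-experiment affective-priming study — a
classical *forward* priming task (prime word → target image) and a
Bem-style *backward* task (target → response → prime) — at three levels:
behavioural reaction times, event-related potentials (ERPs), and
single-trial decoding. Because the original recordings are not publicly
deposited, the package ships a synthetic-data generator that emulates
the experiment's statistical structure; every analysis stage is
validated against data whose ground truth is known.

## Trial schedules

Each experiment has 400 trials in blocks of 36 (11 full blocks plus a
remainder block of 4). Target valences are exactly balanced (200
positive, 200 negative, order permuted by seed); prime valences are an
independent fair coin per trial. Congruency — prime and target sharing
valence — is therefore random around 50%, not forced, and the *expected*
congruent fraction of 0.5 is a property the generator must reproduce,
not a constraint it imposes. Forward and backward schedules built from
the same seed share identical valence sequences and differ only in
event order (forward: fixation 1200 ms → prime 500 ms → ISI 300 ms →
target ≤ 2000 ms → blank 1000 ms; backward presents the target first and
the prime after the response).

## Reaction-time model

Per trial, RT = (base + δ/2·c)·exp(σZ) with c = +1 for congruent and
−1 for incongruent trials, Z standard normal. The multiplicative
lognormal factor has median 1, so the per-condition *median* RT — the
statistic the analysis uses — is exactly base ± δ/2. Defaults: base
735.5 ms and δ = −31 ms, so condition medians sit at 720 / 751 ms;
σ = 0.25 (a realistic RT coefficient of variation); response errors at
5%; RTs above the 2000 ms deadline are flagged as timeouts. Cohorts add
between-participant variation: baseline sd 80 ms and effect sd 45 ms.
The effect sd is chosen so a 31-participant cohort yields paired-t
values near −3.5, the scale of the reported behavioural effect; note
the distribution family itself is a modelling choice — only the medians
and the cohort-level test behaviour are constrained.

Validity filtering keeps correctly-classified trials with RT in
[250, 2000] ms, inclusive at both bounds. Statistics on the cohort of
median differences: one-sided Wilcoxon signed-rank (congruent faster;
exact null for n ≤ 25 after discarding zero differences, else normal
approximation with continuity correction), one-sided paired t, Cohen's
d = mean/sd of differences, and a JZS Bayes factor with Cauchy scale
0.707 computed by numerical integration of the noncentral-t likelihood
against the (half-)Cauchy prior — the directional variant reproduces
the two-sided value of the reference implementation split by posterior
direction. Multiple tests are Holm-corrected. Pearson and Spearman
correlations are always reported together; their disagreement on
skewed data is diagnostic, not noise.

## EEG simulation

Continuous 32-channel recordings (extended 10–20 montage, default
250 Hz for tractability; 1000 Hz available and all analysis code is
rate-agnostic) are built from four parts:

1. a stereotyped evoked template at every target onset (Gaussian
   components at ~100, ~170 and ~450 ms with plausible scalp
   weightings) — identical across conditions, since absolute ERP shapes
   are unconstrained;
2. the congruency contrast, a boxcar over an electrode/time window
   added at +half its amplitude to congruent and −half to incongruent
   trials, leaving the grand average untouched. Defaults are the
   published condition differences: −1.14 µV at P8 over 586–889 ms
   (forward; 0.18 − 1.32 µV) and +0.32 µV at CP5 over 207–290 ms
   (backward; 0.91 − 0.59 µV). Windows are resolved to integer sample
   indices with one shared helper, so noiseless recovery of the
   injected amplitude is exact to float precision;
3. 1/f-shaped Gaussian background noise, sd 8 µV per channel, exponent
   1.0 — a standard EEG background model at a realistic amplitude. At
   the study's own scale (≈200 trials per condition) this puts the
   per-participant, per-timepoint noise of the difference ERP near
   0.8 µV, i.e. cohort-level running-t values of ≈4–5 against the
   1.14 µV forward effect at n = 12 — strong but not trivial recovery;
4. eye blinks at Poisson times (default 0.1/s, 150 µV), a 100 ms
   Gaussian transient projected through a frontal topography maximal at
   Fp1.

A fast epoch-level path (`simulate_epochs`) draws template + contrast +
noise directly per trial, skipping the continuous round trip; it is
used for replicate-heavy studies (window-recovery and type-I
calibration), while the continuous path exercises markers, filtering,
ICA and epoching. What the generator does **not** emulate: between-
participant ERP topography/latency variability, image-category
differences (faces vs scenes), alpha rhythms or other structured
oscillations, electrode drift and line noise. Passing tests therefore
show the *analysis machinery* is correct and calibrated, not that real
recordings would yield these effect sizes.

## Preprocessing

Canonical order: zero-phase FIR band-pass 0.1–30 Hz → common-average
reference → ICA blink removal → target-locked epoching (−100…+1000 ms)
→ baseline correction (mean over −60…+40 ms) → peak-to-peak rejection.
Each container records the applied chain.

The ICA is a FastICA decomposition with component count equal to the
channel rank (31 after average referencing), seed-controlled;
components whose |Pearson r| with the (filtered) Fp1 trace exceeds 0.5
are flagged as blinks and projected out. Absolute correlation is used —
component sign is arbitrary. Removal adds back the subspace the
decomposition never captured, so removing nothing is the identity.

"±100 µV peak-to-peak" is read as the signal leaving a ±100 µV band:
the default budget is max−min > 200 µV, with the stricter reading (100)
selectable. Epochs run to +1000 ms regardless of response time, since
the ERP analysis window is 0–1000 ms. Events whose epoch would leave
the recording are dropped and logged, never truncated.

## ERP analysis

Per participant, trials are averaged per condition over 0–1000 ms;
differences are congruent − incongruent; cohort summaries are grand
means ± SEM (sd/√n). The exploratory procedure: a paired t-test at
every electrode × timepoint (two-sided — the contrasts carry no stated
direction), deliberately uncorrected for multiplicity (it generates
hypotheses); the electrode with the longest contiguous run of p < 0.05
is selected, with run length measured in milliseconds so the selection
is sampling-rate-invariant. Ties break to the earlier onset, then
montage order; the tie-break is recorded. Points with zero-variance
differences and nonzero mean are undefined (NaN, breaking runs); all-
zero differences are a genuine null (t = 0, p = 1). The topographic
summary takes, per electrode, the *median* p over ±10 ms (inclusive)
around the selected window's minimum-p time — the same time for every
electrode — capped at 0.05; the mean is available as an option (the
name "median p-value" fixes the default). Windowed amplitudes average
each participant's difference trace over a half-open [start, end)
window using the same sample-index convention as the simulator's
injection.

## Single-trial decoding

Per participant: epochs are cut to the half-open 400–700 ms window, the
majority class is randomly subsampled to balance congruent/incongruent,
and a 4-fold × 3-seed cross-validation is run (per class, counts are
truncated to a multiple of 4, the remainder dropped seeded and logged;
every train and test split is exactly 50/50). Each of the 12 held-out
accuracies comes from a freshly initialized network; the summary is
their mean (the per-seed fold means and the median are also reported,
since "average" and "median" are both defensible readings of the
protocol). The three seed values are arbitrary defaults (11, 22, 33)
and config-exposed.

The network is two convolutions and a dense sigmoid: a spatial kernel
spanning all channels at one timepoint (collapsing the montage into
n_filters spatial filters), then a 1×25 temporal kernel (valid padding,
stride 1), dropout 0.5 after each, classification threshold 0.5. It is
implemented directly in NumPy with analytic gradients (verified against
central differences in the test suite), Glorot-uniform initialization,
and Keras-convention activations (relu, softmax-along-time, softplus,
tanh, selu, elu), losses (binary cross-entropy, Poisson, KL divergence)
and optimizers (adam, sgd, rmsprop; ε = 1e-7). Inputs are standardized
per channel with training-fold statistics only. Hyperparameters come
from a 10-draw uniform random search scored by the same CV protocol;
this scores on the folds it selects on — optimistically biased by
construction — so the protocol is kept as specified and a nested
variant is left to the caller. Default training: 80 epochs, batch 32.

## Problem sizes and numerical choices

Replicate-based checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted band: congruency balance over 1000
schedules (±3 binomial SE), window recovery over 50 cohorts of 12
participants × 400 trials, type-I calibration over 4 such null cohorts
(per-cohort sd of the flagged fraction ≈ 0.005), and null decoding over
8 participants × 200 trials with 20 training epochs — training length
does not affect the chance-level outcome, only how fast the net
overfits its training folds. Losses clip probabilities to
[1e-7, 1−1e-7]; the Wilcoxon falls back from the exact to the
approximate null if the exact distribution is unavailable (ties); 1/f
noise zeroes the DC bin and rescales each series to the target sd.

## Known limitations

- The RT distribution family and the absolute ERP template are
  modelling choices; only the published contrasts constrain defaults.
- The KL-divergence loss provides no gradient on negative-class trials
  (0·log 0 = 0); it is implemented as listed but is a poor objective
  here, and the random search will typically discard it.
- The one-participant-average blink count and a shared template across
  participants understate real between-subject variability; recovery
  rates on real data would be lower at the same nominal SNR.
- BrainVision is the only write dialect (readers cover BrainVision and
  EDF); epoch containers are .npz + JSON sidecar, not a standard epochs
  format.
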