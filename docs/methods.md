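# Methods

This note records the modelling choices behind `b2t`: what each stage
assumes, which knobs matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Signal model and preprocessing

The pipeline assumes the task-relevant signal is *broadband gamma*
(70–170 Hz) power: a non-oscillatory marker of local cortical activity
whose log-energy is approximately Gaussian per condition.  Processing
order is fixed as detrend → downsample → line-noise channel rejection →
common-average reference → band filtering → framing.  Channel rejection
operates on the 600 Hz signal so the 58–62 Hz estimate is cheap and
consistent with the rest of the chain.

Filters are elliptic IIR in second-order sections: high-pass at 70 Hz
and low-pass at 170 Hz (order 8 each), and a 118–122 Hz band-stop of
order 13 for the first line-noise harmonic.  Band edges and the notch
order are fixed by the design; passband ripple (0.5 dB) and stopband
attenuation (40 dB) are conventional values, exposed in
`PipelineConfig`.  Filtering is causal (forward-only) by default so the
identical chain could run online; `zero_phase=True` switches to
forward–backward filtering for offline analyses.  The causal group
delay (a fraction of one 25 ms hop at mid-band) slightly blurs the
feature/label alignment; the ±4-frame context stack largely absorbs it.

Framing uses 50 ms windows every 25 ms, `E = log(mean square)` per
window and channel, floored at `log(1e-12)` so silent channels cannot
produce −∞.  Context stacking replicates the first/last frame at the
edges, keeping exactly one feature row per frame (and per label).
Frame labels use maximum temporal overlap against the phone tier, ties
to the earlier segment, silence where no phone overlaps.

## Discriminability scores

Feature quality is measured per stacked column by the mean KL divergence
between per-phone univariate Gaussians, averaged over ordered pairs
(this equals the mean of symmetrized divergences).  Two closed forms are
implemented:

- `eq1_verbatim` (default): the determinant term uses a base-2
  logarithm while trace and Mahalanobis terms stay natural.  This mixed
  expression reads in "bits" but is **not** guaranteed non-negative when
  variance ratios stray far from 1; it is retained as the primary score
  for fidelity to the published form.
- `natural`: the standard divergence (all natural logs), non-negative,
  used wherever non-negativity is asserted and validated against
  Monte-Carlo estimates in the tests.

Scores are normalized by their mean (an O(1) scale on which the
selection threshold −0.05 is meaningful; sum-normalization is available
in config).  Selection keeps the top of the descending ranking up to
the *last* drop steeper than 0.05; if the ranking never drops that
steeply the top 5 % (at least one feature) is kept and a warning logged.

The chance level for KL maps comes from recomputing the scores after
rotating the feature rows circularly by half the sequence length with
labels fixed.  The reported threshold is the 99th percentile of the
*pooled* null scores (all features and shifts together): with the
default single shift a per-feature percentile would be a single draw,
whereas the pooled threshold has the intended "exceeds 99 % of
randomized scores" reading.  Per-feature null scores are also returned.

LDA reduces the selected columns to at most (#classes − 1) dimensions
with the eigendecomposition solver; scalar (Ledoit–Wolf) shrinkage of
the within-class covariance switches on automatically when there are
fewer than three frames per input dimension.

## Phone models and the speech-activity screen

Each grouped phone and silence is one diagonal Gaussian fitted by
sample moments, variances floored at 1e−6 (features are O(1) after
LDA).  Phones with fewer than 5 training frames are dropped; lexicon
words containing a dropped phone become undecodable in that fold and a
warning is logged.  A silence model is mandatory.

The screen that gates whole sessions fits two diagonal Gaussians
(speech vs non-speech frames), classifies held-out phrases by higher
likelihood under leave-one-phrase-out, and compares against the same
classifier trained on half-rotated features with a two-sided paired
t-test; a session passes at p ≤ 0.05 with the real accuracy on top.
Diagonal covariance is used for robustness at the frame counts involved.

## Decoding

The search graph is a determinized phone-prefix tree: pronunciations
share common prefixes, so at most one advance arc exists per
(state, phone); homophones share their terminal state.  Cross-word
suffix merging is not performed — at these lexicon sizes (tens of
words) the prefix tree is already small, and keeping word identity on
states simplifies exact traceback.

Each phone is a single emitting state with a self-loop; the self-loop
probability is `p = 1 − 1/m` with `m` the mean duration in frames of
that phone in the training alignment (geometric duration model),
clipped to [0.05, 0.999].  An optional two-frame minimum duration per
phone is available (`min_phone_duration_frames`).

Silence is a decodable unit allowed at phrase edges and between words
(default on).  Silence units cannot be adjacent: after a silence unit
the path must enter a word.  Without this rule the silence state could
exit and re-enter the graph root every frame, bypassing its own
duration model; forbidding adjacency makes the path semantics exactly
"words optionally separated by silence runs", which is also what the
exhaustive-enumeration oracle in the tests scores.

The Viterbi search is an exact max-sum dynamic program over
(graph state, previous word) pairs — the previous word is part of the
state so bigram terms are exact, not approximated at word boundaries.
No beam pruning is applied by default (phrases are short); scores
decompose exactly into emission + transition + LM + insertion terms,
and the tests verify score and argmax against exhaustive enumeration.
Tie-breaking is deterministic: staying in a state beats advancing beats
entering a new word, and the vocabulary is scanned in lexicographic
order.  The LM weight (default 1.0) and word insertion penalty
(default 0.0) follow the plain Bayes decision rule; both are exposed
because real deployments tune them.

The bigram language model uses interpolated Witten–Bell smoothing with
a uniform-base smoothed unigram, so every vocabulary word — including
dictionary distractors unseen in the training transcripts — has
positive probability, and probabilities sum to one exactly for every
history.  ARPA text export/import round-trips to 1e−6.

## Evaluation protocol

Leave-one-phrase-out: for each phrase, feature selection, LDA, phone
models and the LM are fitted only on the other phrases.  The
randomized baseline repeats *all* of those steps on features circularly
rotated by half the training length (labels fixed): rotation preserves
every marginal statistic of the features and the label priors, so the
baseline measures exactly what the dictionary and LM alone can do.  The
shift point differs across folds because fold lengths differ.

Per-phrase dictionaries contain the spoken words plus distractors drawn
uniformly without replacement from the session word pool, identically
in the real and randomized arms (the draw depends only on seed, phrase
and size).  The LM is re-estimated restricted to each dictionary
(out-of-vocabulary tokens are dropped from the training sentences).
Significance: two-sided paired t-test across folds for frame accuracy,
one-sided paired for WER.  Phone true-positive rates exclude silence
frames from the per-phone average (silence dominates the frame count
and would inflate the mean).

WER uses a unit-cost minimum edit alignment; on equal cost the
backtrace prefers match/substitution over deletion over insertion, so
the (S, D, I) split is deterministic even though only their sum is
canonical.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes,
not cortical biophysics.  Per session it draws a pattern matrix
`z[phone, channel] ~ N(0,1)` over the informative channels; during a
phone, an informative channel's 70–170 Hz noise carrier is scaled by
`exp(effect · z)`, so the log-energy feature is linear in the planted
pattern with known per-phone means.  All channels carry broadband
background noise and a 60 Hz sine plus 120 Hz harmonic whose amplitude
varies channel to channel (×0.5–1.5), as on a real electrode grid —
this heterogeneity is what makes the interquartile range of the line
band meaningful; designated bad channels get 20× pickup.  Phone
durations are lognormal (mean 80 ms, sd 30 ms) floored at one analysis
window (50 ms) so every phone covers at least one full frame; pauses
between phrases are lognormal around 0.9 s.  Transcripts sample words
uniformly from a built-in ~90-word lexicon of mid-19th-century
oratory, so bigram statistics are deliberately weak and decoding
performance reflects the neural features rather than the LM.

Defaults (40 phrases of 4–6 words, 32 channels, 8 informative, 2 bad,
effect size 0.6, 9600 Hz) give a session of a few minutes comparable in
scale to a single reading session, which the full pipeline processes in
well under a minute.  What passing tests on this generator shows: the
pipeline recovers planted phone structure, its chance baseline is
calibrated, and the decoder is exact.  What it does not show: robustness
to 1/f background spectra, spatial correlation between channels,
movement or epileptiform artifacts, session drift, or imperfect forced
alignments — real recordings have all of these and the generator has
none.

## Problem sizes used in checks

The end-to-end checks run the default 40-phrase session; calibration of
the real-vs-random significance test uses 50 independent zero-effect
sessions of 8 phrases × 8 channels — the size of a calibration session
does not change the level of a paired t-test, and the small sessions
keep the 50-replicate design practical.  The Viterbi/oracle comparison
uses instances of up to 4 words and up to 8 frames, where exhaustive
enumeration is feasible; the Monte-Carlo KL check uses 10⁶ samples per
pair.

## Known limitations

- The mixed-base default KL score can be negative for extreme variance
  ratios; use `kl_mode="natural"` when a true divergence is required.
- One Gaussian per phone, context-independent: no coarticulation
  modelling, no mixture components.
- The geometric duration model is crude; phone durations are not
  geometric in real speech.
- The decoder's exact (state × previous-word) search is quadratic in
  vocabulary at word boundaries; it is meant for the small-vocabulary
  regime studied here, not large-vocabulary recognition.
- Labels are consumed as given; alignment errors propagate into both
  training and scoring.
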