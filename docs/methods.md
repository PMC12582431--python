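# Methods

`writetrace` analyses keyboard writing sessions recorded as timestamped
editor events plus an eye-movement fixation stream.  This note documents the
models and conventions the package implements, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish.

## Document replay and fixation anchoring

Text produced in an editor changes continuously, so fixations cannot be
located with static areas of interest.  The keystroke log is replayed into a
time-indexed document model: after every event the full text, the cursor,
and the *point of inscription* (the index of the last-typed character) are
recorded, and any query time resolves to the state at the latest event not
after it.  Conventions: 0-based character indices; half-open delete ranges;
sentences end at a run of `.?!` followed by whitespace (abbreviations are
not handled — synthetic texts contain none); words are maximal
non-whitespace runs.

The *current sentence* at an insertion point is defined by the number of
completed terminator-plus-whitespace boundaries at or before the point of
inscription.  A writer who has just typed the space after a terminator is
therefore already "in" the next, still-empty sentence, which makes the
minimum sentence distance of any fixation from a before-sentence transition
equal to 1 — the convention the depth-of-lookback analysis relies on.

Fixations are mapped to text through a fixed-grid monospace layout model
(configurable characters per line, pixels per character and line, and a
prompt band at the top of the screen).  A real editor's rendering is
proportional and scrolled; the grid is a documented stand-in that is exactly
invertible, so the screen-coordinate and text-anchored input paths agree and
both are exercised.  Distances behind the point of inscription are measured
to the fixated word's *nearest edge* (its last character when the word lies
fully behind); word distance counts word boundaries between the fixated word
and the word containing the point of inscription.

## Transition taxonomy

Transitions are consecutive event pairs.  Writing transitions are classified
by the characters around them (within-word, post-word, pre-word,
pre-sentence); editing transitions (second event a deletion or cursor move)
by their *preceding* keypresses only, since whether a pre-edit letter was
word-final is indeterminate.  For the same reason post-word is always
reported merged into within-word.  Two timing rules: shift-plus-character
capitals are timed to the shift keypress, and a run of cursor moves that
returns exactly to its origin with no intervening edit, followed by typing,
is folded into a single non-editing transition (cursor movement used to
support lookback, e.g. as a scrolling strategy, is not editing).  Word-forming
characters are anything non-whitespace: digits and non-terminator
punctuation are treated as letters, which maximises retained transitions.

Filtering removes durations <= 50 ms (key-overlap artefacts) and >= 30 s
(off-task activity); cells of participant x language x location x mode with
more than 200 observations are reduced to exactly 200 by seeded sampling
without replacement.  The cell seed is derived from the cell key, so
subsampling a cell in isolation reproduces the cell's rows from a full-table
run.  The cap is applied to the interval modelling input only; lookback
detection sees all writing transitions.

## Lookback detection

The candidate sequence for a writing transition is the maximal run of
fixations whose onsets fall strictly inside the transition window (no
sub-sequence search; this is the simplest reading of a sequence of fixations
"between the two keyboard events").  It is a lookback when (a) the medians of
word distance and character distance over its in-text fixations are at least
1 word *and* 5 characters (computed separately; character distance uses
linear-text characters, not screen columns), (b) more than 80% of all its
fixations are behind the point of inscription, (c) it does not start on the
writing prompt, and (d) fewer than 50% of its fixations are on the prompt.
Prompt fixations count in the denominators of (b) and (d) but carry no text
distance.  Editing transitions are excluded: looking back while editing is
trivially expected.

Metrics: duration is the sum of all member fixation durations; words fixated
counts word *entries* (consecutive same-word fixations collapse, re-entries
count again; prompt fixations are transparent); depth is the sentence
distance of the uniquely most-fixated sentence, with ties excluded from the
depth analysis.

## Text measures

Word count, mean word length, sentence count, mean sentence length, the
ratio of open- to closed-class words, and MTLD.  Tokens are case-folded with
surrounding punctuation stripped.  The package ships small English/Spanish
closed-class inventories (~120 entries each) as overridable defaults; the
ratio is |tokens outside the lexicon| / |tokens inside|.  MTLD walks the
token sequence accumulating a type-token ratio; each time the TTR falls to
the threshold (default 0.72) a factor completes and counters reset, the
remainder contributing a partial factor (1 - TTR)/(1 - threshold); the
statistic is the mean of N/factors over the forward and reverse passes, and
is flagged undefined when no factor completes in either pass.

## Inter-keystroke interval mixture

Writing IKIs are modelled as a two-component lognormal mixture.  The fluent
component (finger-movement-limited output) has a log-location shared across
language and text location but varying by participant; the hesitation
component adds a strictly positive, cell-specific shift `delta` on the log
scale; the mixing proportion has a cell-level logit intercept plus a
by-participant offset.  Priors: `mu_f ~ N(log 150 ms, 0.5)`;
`log delta ~ N(0, 0.5)`; cell logits `~ N(0, 2.5)`; half-normal(0.5) and
half-normal(1) on the random-effect SDs; half-normal(1) on both component
scales.  The log-scale prior on the shift serves two purposes: positivity
prevents label switching, and the repulsion from zero removes the degenerate
ridge in which a zero-separation "hesitation" component absorbs fluent
observations (with a shift prior allowed near zero that ridge is a genuine
second mode and the mixing proportion is unidentified).  Its 95% prior range
for the shift factor, roughly e^-1 to e, covers all plausible hesitation
magnitudes.

Configured and reported millisecond quantities are component geometric means
`exp(mu)`; mixing proportions are reported at a zero participant offset (a
typical participant).  Language effects are the L1 - L2 differences of the
cell shifts (log scale) and cell logits, so a larger L2 value prints as a
negative effect.

Sampling is by Gibbs: exact conjugate updates for the component indicators,
the fluent location and the participant offsets; univariate slice sampling
(stepping-out/shrinkage) for the shifts (on the log scale), the scales and
the logit-scale parameters; plus two exact "translation" moves that shift
mass between each intercept and its random-effect block (the likelihood
depends only on their sum, so the shift has a closed-form Gaussian
conditional).  Without the translation moves the intercepts mix an order of
magnitude more slowly.  Defaults: 4 chains x 1,000 post-warmup draws after
1,000 warmup sweeps; fits check split-R-hat < 1.01 and bulk ESS >= 100 on
the reported parameters and raise a diagnostic error otherwise.

## Mixed-effects models for rates, durations and counts

Editing and lookback probabilities (binomial), lookback durations
(lognormal), and words fixated / lookback depth (negative binomial, with a
Poisson family available for dispersion-limit checks) share one engine.
Fixed effects: language (sum-coded L1 = +1/2, L2 = -1/2) and two location
contrasts — pre-sentence vs pre-word, and within-word vs
before-word-or-sentence — with language interactions; random participant
intercepts and by-participant language slopes.  Depth is modelled separately
for before-sentence (minimum distance 1) and before/within-word transitions
(minimum 0), the latter with a single within-vs-before-word contrast.
Priors: N(0, 1) on effects, N(0, 10) on the intercept, half-normal(1) on
random-effect SDs and the lognormal residual scale, N(2, 2) on the log of
the negative-binomial dispersion.

When every language x location cell is observed, the fixed-effect design is
square and the sampler re-parameterizes to the cell means, whose likelihood
contributions are disjoint; the effect priors transform to a Gaussian with
cross-terms.  This removes the strong posterior correlations between
contrasts and interactions that make coordinate-wise sampling of unbalanced
designs slow (pre-sentence cells carry far fewer trials than within-word
cells).  Draws are stored on the effect scale.  Cell summaries are posterior
draws of the inverse-link-transformed linear predictor at zero random
effects: probabilities for binomial, geometric means for lognormal, mean
counts for negative binomial.

The text measures are analysed as per-measure normal models on log-scaled,
z-scored values with participant random intercepts (one text per participant
and language, so a by-participant language slope is not identifiable); the
language coefficient is then a standardized effect.

## Savage-Dickey Bayes factors

`BF10` for a point null is the prior density at zero divided by the
posterior density at zero.  The posterior density is a Gaussian KDE (Scott
bandwidth) over the effect draws; the prior density is analytic for normal
effect priors and a KDE over prior draws for derived contrasts (mixture cell
differences).  When no draw lies within five bandwidths of zero the ratio is
reported as a bound (infinite BF10); printed tables cap values at 100.
Savage-Dickey ratios are prior-sensitive, so the prior SD is part of any
reported result.

## Synthetic data

The generator writes multi-sentence texts from synthetic lexicons: a finite
pool of random content words per language (distinct letter inventories with
accented Spanish characters, configurable lengths, 150 words by default)
mixed with ~35% closed-class function words from the shipped inventories, so
lexical diversity and the open/closed ratio are well defined; content words
need lengths and boundaries, not semantics.  Every
keypress interval is drawn from the configured cell mixture; editing
episodes (wrong character + backspace within words; deletion and retyping of
the just-typed space at word/sentence boundaries) occur with per-cell
probability; capitals are typed as shift + character; occasional
cursor-away-and-return excursions exercise the non-editing cursor rule.
Lookback sequences are planted inside sufficiently long transition windows
to satisfy criteria (a)-(d) exactly, with a configured total duration,
word-entry count and unique modal sentence; negative windows receive
fixations on the word under production, or prompt-initial pairs, which
violate the criteria.  Participant heterogeneity enters as normal random
effects on log-duration and logit-probability scales.  Default cell
parameters describe realistic adult L1/L2 composition: a ~153 ms fluent
component everywhere; hesitation medians rising from ~270-370 ms within
words to ~1.4-1.9 s before sentences; hesitation shares from .08-.20 within
words to .78-.94 before sentences; editing probabilities .05-.24; lookback
probabilities from under .01 within words to ~.34-.40 before sentences, with
matching duration, words-fixated and depth targets.

What the generator does *not* emulate: real linguistic content and its
semantics, spelling-error structure, proportional fonts, scrolling and line
wrapping, raw 60 Hz gaze samples, fixation-detection noise, and calibration
drift.  Green tests therefore show that the pipeline implements its
definitions exactly and that the models recover parameters from data that
match the modelling assumptions — not that the assumptions hold for any
particular real dataset.

## Problem sizes and numerical choices

Recovery tests simulate at the scale of a two-condition study with up to 39
participants: the mixture check uses 30 participants x 200 before-word
intervals per language; the rate/duration/count checks use 39 participants
with per-cell trial counts matching observed keystroke frequencies (tens for
before-sentence, thousands for within-word) and 12 events per cell for
durations and counts.  The end-to-end reporting script generates 10
participants x 2 languages x 10 sentences and fits the mixture and the
binomial/lognormal models with 4 chains; it relaxes its convergence gate to
R-hat < 1.05 so a single marginal tail parameter does not abort the whole
report, while library defaults keep the strict 1.01 gate.  Degenerate inputs
are rejected with informative errors: non-positive IKIs or durations,
constant responses, improper priors, unanchored fixations, subsample caps
below 1, and malformed or time-reversed event logs (with line numbers).
Ties in the depth metric are excluded rather than broken arbitrarily.

## Known limitations

The grid layout model ignores proportional rendering and scrolling, so
anchored distances on real editor data would need the editor's own layout
feed.  The candidate-sequence rule considers only the maximal fixation run
per transition; a qualifying sub-sequence inside a non-qualifying run is not
searched for.  Whether distance-to-word is measured to the nearest edge or
the word onset changes criterion (a) marginally (sensitivity can be probed
with the CLI threshold overrides).  The mixture assumes a single fluent
component across locations and languages; violations (e.g. digraph-specific
motor timing) would inflate the fluent scale rather than bias the shifts.
Savage-Dickey estimates degrade when the posterior places almost no mass
near zero; such cases are reported as bounds rather than numbers.
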