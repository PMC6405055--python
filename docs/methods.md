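# Methods

## Session model

An improvisation is a session record: metadata (participant, task,
gender, age, proficiency), a time-ordered list of raw key events
(seconds from session start, on/off, MIDI note 0–127, velocity 0–127),
and bounds `[t0, t_end]`. Unless a source encodes explicit bounds,
`t0 = 0` (recording start) and `t_end` is the last event time; bounds
can be overridden per session, which affects the %start and %idle
denominators and is logged.

Raw events are paired into note intervals per note number with FIFO
discipline: if the same key is re-pressed while already sounding, the
first off closes the first on. A dangling note-on is closed at `t_end`
with a warning (preserving its playing-time mass rather than discarding
it); an unmatched note-off is dropped with a warning. Intervals are
half-open `[onset, offset)`, so an offset coinciding with another onset
never produces a one-sample spike in the held-key count.

The held-key timeline is the piecewise-constant count of simultaneously
sounding keys; it changes only at onsets/offsets, its integral equals
the summed interval durations, and the measure of its positive support
equals the net playing time (both identities are tested against a 1-ms
brute-force grid). The Idle/Playing state trace is derived from it
(Playing iff count ≥ 1) together with running extrema of intensity
level, octave and cluster size; an instrument-selection state is
unnecessary with a single instrument and is omitted.

## Keyboard semantics

Black keys are the five sharp pitch classes {C#, D#, F#, G#, A#};
octaves follow the scientific convention `floor(note/12) − 1` (middle
C = C4), which places the default 76-key board (E1 = MIDI 28 to
G7 = MIDI 103; 31 black + 45 white keys) on octaves 1–7. Velocity is
categorised onto ten dynamics levels *pppp*(1) … *ffff*(10) by
equal-width binning, `level = 1 + floor(v·10/128)`; published alternative
categorisations use non-uniform boundaries, so the boundaries are a
`DynamicsScale` parameter and any monotone 9-boundary mapping can be
swapped in. Values that depend on the binning (intensity averages,
extremes, modal levels) shift accordingly; values that do not (times,
concurrency, colors, octaves) are binning-invariant.

## Parameter conventions

* Intensity and octave **averages** are press-weighted means of per-press
  values: the press count is the natural denominator for a per-press
  attribute.
* **Most used** octave/level are duration-weighted modes, consistent with
  histograms expressed as percentage of playing time; a press-weighted
  variant is available (`duration_weighted_mode=False`). Ties break to
  the lower bin, deterministically.
* Histogram denominators are summed note-sounding seconds (a two-note
  chord contributes its duration to each member's bin), so each
  histogram sums to 100 independent of concurrency.
* A **cluster instance** is a maximal constant-count positive segment of
  the timeline; counts above 10 are reported as-is.
* **Tempo transitions** compare consecutive inter-onset intervals;
  equal IOIs count as ritardando so the two shares always sum to 100
  (there is no "same tempo" category). Velocity/color transitions use
  consecutive presses ordered by (onset, note). Transitions run on the
  ungrouped press sequence by default for reproducibility; a chord
  window (default suggestion 30 ms, the spread of a humanly "simultaneous"
  chord) can group near-simultaneous presses first, in which case a
  chord contributes its loudest velocity and its lowest note's color.
* `total_session_min` is the session span `t_end − t0` in minutes (not
  net playing time); both interpretations are computable, this one is
  the reported default.
* Session-duration categories ("long", "extremely short") are labels
  from cohort-level quintiles of session length; they are reported only
  and never enter statistics.
* A parameter a session cannot define (start time with no presses,
  transition shares with fewer than 2 presses / 3 onsets) is NaN and is
  excluded pairwise from aggregation and tests.

## Statistics

Two-sample comparisons use the independent t-test in both the pooled
(df = n1+n2−2) and Welch (Satterthwaite df) variants — reported dfs in
the literature this package serves are not consistent with a single
choice, so the CLI reports both — with Cohen's d standardised by the
pooled SD. A fully degenerate comparison (zero variance in both groups,
equal means) is defined as t = 0, p = 1, d = 0.

The repeated-measures ANOVA is the one-way within-subject decomposition
SS_total = SS_subject + SS_condition + SS_error on an n×k matrix,
F = MS_condition/MS_error with df (k−1, (n−1)(k−1)), and effect size
partial η² = SS_condition/(SS_condition+SS_error) — the per-effect
bounded choice for within-subject designs. Missing cells are handled by
complete-case analysis by default (dropped subjects are counted and
logged); an alternative `missing="impute"` fills a cell with the
additive expectation (subject mean + condition mean − grand mean) and
removes one error df per imputed cell. Pairwise condition contrasts are
paired t-tests with Bonferroni adjustment `min(1, p·n_pairs)`. With
k = 2 the F statistic equals the squared paired-t statistic, which the
tests verify, along with agreement with an independent library
implementation and a Monte-Carlo type-I error check (2,000 null
replicates at n = 50, k = 4).

## Synthetic sessions

The generator emulates a keyboard improvisation as a marked point
process: chord onsets separated by truncated-normal IOIs, occasional
idle gaps (rate × truncated-normal length), truncated-normal session
duration and start delay, truncated-normal velocity and octave placement,
key color black with probability `p_black`, and a categorical
cluster-size distribution. A cluster event emits its member onsets
within 10 ms at the nearest same-color keys above the sampled base note
— same-color stacking keeps the configured black-key probability exact
for every press. Note durations are truncated-normal, or every chord can
be sustained to the next onset (`hold_to_next`), in which case a fixed
cluster size c yields concurrency ≈ 100·c % by construction. Truncated
normals were chosen for boundedness with two interpretable parameters;
the distribution hook is swappable.

Defaults approximate a mid-register, moderately loud, mostly single-note
style (~52 s sessions, 0.5 s mean IOI, octave center 3.5, velocity
center 76, 16 % black keys). The two presets encode only qualitative
directions — the harsh preset is lower (octave center 2.5), louder
(velocity 95), cluster-heavy (sizes 1–6), black-leaning (p = 0.3) and
slower to start; the gentle preset the opposite — because published
cohort studies report group summaries, not generative parameters, so
only directions, not magnitudes, are meaningful to encode. What the generator does **not** emulate: melody/harmony
(notes are style-conditioned but musically unstructured), expressive
micro-timing correlations, pedal effects, or velocity–duration coupling.
Passing tests therefore demonstrate correctness of the measurement and
inference pipeline under controlled statistical structure, not musical
realism of any particular cohort.

## Numerical and scale choices

All times are float seconds; interval algebra is exact sweep-line
arithmetic, with the 1-ms grid oracle used only in tests (random
fixtures are drawn on the millisecond lattice so oracle agreement is
exact rather than within a step). Test problem sizes — 1,000 interval
sets for the oracle sweep, 1,000 seeded sessions for the invariant
suite, 2,000 ANOVA null replicates, 50 sessions/group for effect-
direction recovery, 200 sessions for parameter recovery — were chosen as
the smallest sizes at which the checked quantities are statistically
stable; all are fixed-seed.

## Known limitations

* The deposited-dataset reader infers its dialect (delimiter, column
  aliases) and reports what it detected; layouts without recognisable
  session identifiers are rejected rather than guessed.
* Re-pressing a sounding key is interpreted as a second overlapping
  interval (FIFO pairing), not as restarting or extending the first.
* Dynamics-dependent parameters are only comparable across datasets that
  share the same velocity categorisation boundaries.
* No melodic/harmonic analysis (key detection, chord labeling) and no
  audio transcription; input must be symbolic MIDI-style events.
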