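# Methods

This note documents the models, conventions, and numerical choices behind
`aslkit`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic-data tests do and do not
establish.

## Language design and the design-TP metric

A language is built from a 16-syllable syllabary split (under the seed)
into 12 *high-TP* syllables — four trisyllabic words in which every
syllable occurs in exactly one word at one position — and 4 *low-TP*
syllables arranged as a 4×3 Latin rectangle: four words, each syllable
appearing once per position and never twice within a word (implemented as
cyclic shifts with seeded offsets). Because all words are repeated equally
often (60 times in the nominal stream), each low-TP syllable is heard three
times as often as each high-TP syllable (180 vs 60 tokens).

The *design TP* of an ordered syllable pair is defined as the number of
word-internal occurrences of that bigram across the nominal 60-repetition
stream divided by the total number of tokens of its first syllable. This
order-free counting metric yields exactly 1.00 for high-TP word bigrams,
1/3 for low-TP word bigrams, and 0 for foil bigrams — the three design
levels the paradigm manipulates — and is verified in the tests against a
brute-force enumeration of the full token list.

Foils are found by seeded backtracking over the per-position syllable
slots of each predictability class, under four constraints: positions
preserved, per-stream token frequencies preserved (the foil set uses
exactly the source words' slots), three distinct syllables per foil, and no
adjacent pair that is a word-internal bigram of any word. An infeasible
constraint set raises an error rather than silently relaxing a constraint.
Foil TP = 0 is guaranteed at the design level; whether foil bigrams also
never arise across word boundaries in the realized stream is not
constrained (the empirical-TP diagnostic exposes such boundary
coincidences).

## Stream composition

Streams are composed per block by sequential seeded sampling from the
remaining word counts, excluding candidates that repeat the previous word
or whose initial syllable equals the previous token's final syllable. Dead
ends trigger a block restart (cap 1000); the boundary constraint is applied
across block joins because the blocks are contiguous audio. The chirp
scheduler places `round(rate × 60) = 18` chirps per word, balanced exactly
across the two within-word inter-syllable intervals (9/9); a three-position
variant (including word onset) is available via the `intervals` argument.
Rates whose per-word count does not divide over the interval set are
rejected with the list of feasible rates.

Timing: 300-ms syllables, no pauses, so a word token every 900 ms, 72 s per
80-token block, and 432 s for the default stream — the arithmetic-consistent
timing for gapless concatenation. Audio is placeholder synthesis (a
distinct harmonic tone per syllable with a raised envelope, so the stream
has no silent gaps), since recorded natural syllables are not a reproducible
computation; the chirp is the specified 0.1-s sawtooth sweep added at the
scheduled boundary instant.

## Learner models

The TP tracker accumulates unigram and bigram counts over the raw syllable
sequence (boundaries included — a naive listener hears none) and scores a
trisyllabic item by the mean of its two forward conditional probabilities;
unseen bigrams score 0 (no smoothing; word items always have full support).
The frequency tracker scores items by mean relative unigram frequency.
Aggregation by arithmetic mean is the default; the choice rule is
Luce/softmax on the score difference with temperature T (chance as T→∞,
argmax as T→0). These models are explicit operationalizations of
discussion-level hypotheses, not fitted cognitive models.

## ERP pipeline conventions

Processing order: mastoid re-reference → bandpass → epoch → baseline →
threshold rejection. Re-referencing first matches an acquisition chain in
which the recording reference is arbitrary; the subtraction is applied to
all channels, making the operation idempotent once the mastoids are zeroed.
The bandpass is a Butterworth of one-pass order 2 applied
forward–backward (`sosfiltfilt`), i.e. an effective 4th-order zero-phase
response; at 60 Hz the amplitude attenuation exceeds 25 dB. Epochs span
−300…1200 ms (768 samples at 512 Hz); window endpoints, including the
baseline, are closed intervals on sample times with 0-based indexing, which
puts 21 samples in the 80–120 ms N100 window and 51 in the 350–450 ms N400
window at 512 Hz. Halves are assigned from stream blocks: the first half of
the block range → half 1.

Rejection flags an epoch when any scalp channel (default; ROI-only as an
option) exceeds ±100 µV after baseline correction. Ocular-artifact
decomposition (ICA) is deliberately out of scope — component selection is
not reproducible from a written description — so blink handling is the
threshold path, which the synthetic blinks are sized to exercise
(~10–25% of epochs rejected at defaults). Cohort-level subject exclusion is
a configurable minimum retained-epoch fraction per condition cell
(default 50%).

## Statistics

The mixed ANOVA uses the univariate split-plot decomposition in
orthogonal-contrast form: for each within-subject effect (all factors
two-level) the per-subject contrast score is tested against zero with Type
III (unweighted group means) conventions, its interaction with group is the
one-way ANOVA on the same scores, and the between-subjects effect is the
one-way ANOVA on subject means. This reproduces R `car::Anova(type=3)`
with sum-to-zero contrasts exactly, balanced or not, and pingouin's mixed
ANOVA in the balanced case. Within factors with more than two levels are
not supported (`NotImplementedError`); with single-df contrasts sphericity
is vacuous, so the Greenhouse–Geisser ε is exactly 1 — it is still reported
and applied to the dfs for interface generality. Note that permuting group
labels changes the within-stratum error partition, so within-effect F
values are not exactly invariant to relabeling; the structure (dfs,
effects) is.

Conventions that matter for reproducing printed statistics: the 2×2 χ² is
Pearson without continuity correction; the independent t is the
pooled-variance Student t with df = n₁+n₂−2; partial η² = F·df₁/(F·df₁+df₂);
observed power is the noncentral-F tail above the central critical value
with ncp = F·df₁ (equal to α at F = 0). Bonferroni adjustment is
min(1, m·p) with the family m being all returned contrasts.

## Synthetic data

Component templates are Hanning bumps (N100: peak 100 ms, width 80 ms;
N400: peak 400 ms, width 300 ms) whose support lies within 0–600 ms so no
template leaks into the next epoch's baseline; spatial topographies are
Gaussians over an idealized planar 10–20 layout, centred on the component's
ROI centroid (mastoids weight 0). Each template is scaled so that the
pipeline's own window/ROI averaging returns the target amplitude exactly —
hence noiseless forward–inverse recovery is exact by construction, which is
the point of the calibration: it isolates placement/extraction errors from
noise. Background noise is FFT-shaped 1/f^β Gaussian noise (defaults
10 µV RMS, β = 1) plus 2 µV white sensor noise; blinks are 400-ms frontal
Hanning bumps at 120 µV, 6/min. Between-subject variability is a per-subject
Gaussian amplitude offset per component (SD 1 µV). All randomness fans out
from a master seed via `SeedSequence`.

Default cohort size is 15 per group — 30 analyzed subjects, matching the
error df of 28 in the published-size 2×2×2×2 design. Behavioral defaults
are the paradigm's observed group accuracies (all cells near 0.5) over 8
trials per task × predictability cell, and click-detection hit rates near
0.9.

What the simulations do *not* emulate: volume conduction and realistic head
geometry, developmental EEG spectra, non-stationary artifacts, reaction
times, or any learning dynamics within the recording (amplitudes are
stationary within a condition cell). Passing tests therefore establish the
correctness and calibration of the *analysis chain* under its own
assumptions, not the realism of the generator.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks run at reduced scale, chosen once: the behavioral
chance-level calibration uses 1000 replicates of 14 subjects × 16
Bernoulli(0.5) trials (acceptance band 3–7% around the nominal 5%); the
ANOVA type-I calibration uses 200 zero-effect cohorts of 6 subjects per
group on a 2-block × 3-repetition stream with the ROI-only montage, pooling
the 15 effect tests per cohort (band 3.5–6.5%); the detection-power
consistency check uses 40 cohorts of 8 per group with a 1.5 µV injected
task effect, compared against the analytic noncentral-F power within ±10
points. Composition constraints are scanned over 100 seeds at full stream
size. Exactness claims (design TPs, brute-force amplitude oracle, noiseless
recovery) are asserted at machine precision or 1e-10 µV.
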