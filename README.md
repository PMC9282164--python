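# aslkit

Auditory statistical-learning (SL) experiments test whether listeners can
segment a continuous stream of synthesized speech into word-like units using
nothing but the transitional probabilities (TPs) between syllables — the
paradigm used to compare implicit and explicit learning in preschool
children with developmental language disorder (DLD) against typically
developing (TLD) peers, with event-related potentials (ERPs) as the neural
readout. `aslkit` implements the computational side of such an experiment as
a reusable, tested Python library:

- **Language design** — 16-syllable syllabaries; four *high-TP* trisyllabic
  words (each syllable exclusive to one word/position, internal
  TP = 1.00), four *low-TP* words (a 4×3 Latin rectangle over 4 shared
  syllables, TP = 0.33), and 2-AFC foils that reuse the exposed syllables at
  their exposed positions and frequencies but contain only unseen bigrams
  (TP = 0). The design TP of a bigram *ab* is
  `#(word-internal ab tokens) / #(a tokens)` over the nominal 60-repetition
  stream.
- **Stream composition** — 6 blocks × 10 repetitions per word (480 tokens,
  300-ms syllables, 432 s), seeded constrained shuffling (no immediate word
  repeats, no identical boundary syllables), a 0.1-s sawtooth chirp
  (450→1450 Hz) on 30% of each word's tokens as the click-detection cover
  task, BIDS-style events TSV and WAV output.
- **Learner models** — TP-tracking vs syllable-frequency-tracking learners
  with a Luce/softmax 2-AFC choice rule, operationalizing the two candidate
  segmentation strategies.
- **ERP pipeline** — mastoid re-reference, 0.1–30 Hz zero-phase Butterworth
  bandpass, −300…1200 ms word-locked epochs with −300…0 ms baseline,
  ±100 µV artifact rejection, and mean amplitudes for the N100 (80–120 ms,
  frontocentral ROI) and N400 (350–450 ms, central ROI).
- **Statistics** — one-sample/pooled t tests, uncorrected Pearson χ², the
  2(group) × 2(task) × 2(predictability) × 2(half) mixed ANOVA (Type III,
  split-plot decomposition, validated against R `car::Anova` and pingouin),
  Greenhouse–Geisser ε, partial η² = F·df₁/(F·df₁+df₂), observed power from
  the noncentral F with ncp = F·df₁, and Bonferroni pairwise contrasts.
- **Synthetic data** — a forward model generating 64-channel 512-Hz EEG
  with condition-dependent N100/N400 templates, 1/f noise and blink
  artifacts, plus Bernoulli 2-AFC and click-detection behavior, so the whole
  chain is testable without any recorded data.

## Worked example

```python
import aslkit as ak

design = ak.build_language(ak.default_syllabary("A"), seed=3)
tokens = ak.compose_stream(design, seed=1)
events = ak.emit_events(tokens, ak.schedule_chirps(tokens, seed=2))

w = design.high_words[0]
print(w.label, ak.design_tp(design, (w.syllables[0], w.syllables[1])))
print(ak.observed_power(5.80, 1, 28))
```

prints

```
vitiso 1.0
0.6425180671464786
```

— the first high-TP word of the generated language with its internal design
TP of 1.0 (a perfectly predictive syllable pair), and the post hoc power of
an F(1, 28) = 5.80 main effect at α = .05 (0.64: a 64% chance of detecting
an effect of that size with 30 subjects). `examples/` contains one short
script per capability: language construction, stream composition and audio,
learner strategies, single-subject ERP extraction, and the full
cohort-level factorial analysis; each prints the quantities it computes and
a line on how to read them.

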