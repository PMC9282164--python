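"""Build an artificial language and inspect its transitional-probability design.

Constructs the 8-word inventory from the built-in 16-syllable syllabary A:
four high-predictability words (each syllable exclusive to one word and
position, within-word TP = 1.0), four low-predictability words (a 4-syllable
Latin rectangle, within-word TP = 0.33), and eight 2-AFC foils whose
adjacent pairs never occur inside any word (TP = 0).
"""

import aslkit as ak

design = ak.build_language(ak.default_syllabary("A"), seed=3)

print("high-TP words:", ", ".join(w.label for w in design.high_words))
print("low-TP words: ", ", ".join(w.label for w in design.low_words))
print("foils:        ", ", ".join(f.label for f in design.foils))

for name, items in (("high-TP word", design.high_words),
                    ("low-TP word", design.low_words),
                    ("foil", design.foils)):
    w = items[0]
    tps = [ak.design_tp(design, (w.syllables[p], w.syllables[p + 1]))
           for p in range(2)]
    print(f"design TP inside first {name} ({w.label}): "
          + ", ".join(f"{tp:.2f}" for tp in tps))

trials = ak.build_2afc_trials(design, seed=5)
first = trials.trials[0]
print(f"2-AFC: {len(trials.trials)} trials in 2 blocks; first trial pairs "
      f"{first.word.label} with {first.foil.label} ({first.presentation_order})")
# The three TP levels (1.00 / 0.33 / 0.00) are the segmentation cue the
# exposure streams manipulate; foils differ from words only in syllable order.
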