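"""Compose an exposure stream, schedule the chirp cover task, render audio.

The default stream is 6 blocks x 10 repetitions of each of the 8 words
(480 tokens, 432 s of gapless 300-ms syllables). 30% of each word's tokens
carry a 0.1-s sawtooth chirp (450->1450 Hz) between syllables, the signal
for the attention-keeping click-detection task.
"""

from pathlib import Path

import aslkit as ak

design = ak.build_language(ak.default_syllabary("A"), seed=3)
tokens = ak.compose_stream(design, seed=1)
chirps = ak.schedule_chirps(tokens, rate=0.30, seed=2)
events = ak.emit_events(tokens, chirps)

print(f"{len(tokens)} word tokens; 60 per word; "
      f"{len(chirps.entries)} chirps ({len(chirps.entries) / len(tokens):.0%})")

tp = ak.empirical_tp(events)
w = design.high_words[0]
pair = (w.syllables[0].label, w.syllables[1].label)
print(f"empirical TP of {pair[0]}->{pair[1]} (inside {w.label}): {tp[pair]:.3f}")
low = design.low_words[0]
pair = (low.syllables[0].label, low.syllables[1].label)
print(f"empirical TP of {pair[0]}->{pair[1]} (inside {low.label}): {tp[pair]:.3f}")

out = Path("scratch")
out.mkdir(exist_ok=True)
ak.write_events_tsv(events, out / "stream_events.tsv")
sr, wave = ak.render_audio(events, out_path=out / "stream.wav")
print(f"rendered {len(wave) / sr:.0f} s of audio at {sr} Hz -> scratch/stream.wav")
# Empirical TPs include word-boundary transitions, so low-TP bigrams sit at
# or slightly above their design floor of 1/3 while high-TP bigrams stay 1.0.
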