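"""Exposure-stream composition, chirp scheduling, event tables, and audio.

The exposure phase of each task is a continuous speech stream: 60
repetitions of each of the 8 words, distributed over 6 blocks of 10
repetitions, with 300-ms syllables and no pauses (one word token every
900 ms, 80 tokens per 72-s block, 432 s in total). Composition is a seeded
constrained shuffle: the same word never occurs twice in a row and the
final syllable of a token never equals the initial syllable of the next
token, including across block joins. A 0.1-s sawtooth chirp (450->1450 Hz)
is superimposed between syllables on 30% of each word's tokens,
counterbalanced over interval positions, as an attention (click-detection)
cover task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .language import DesignError, LanguageDesign, WordSpec

__all__ = [
    "StreamPlan", "ChirpSchedule", "compose_stream", "schedule_chirps",
    "emit_events", "empirical_tp", "render_audio", "chirp_waveform",
    "write_events_tsv", "read_events_tsv",
]


@dataclass(frozen=True)
class StreamPlan:
    """Block structure and timing of one exposure stream."""

    blocks: int = 6
    reps_per_block: int = 10
    syllable_duration_ms: float = 300.0

    @property
    def reps_total(self) -> int:
        return self.blocks * self.reps_per_block

    @property
    def word_duration_ms(self) -> float:
        return 3 * self.syllable_duration_ms


def compose_stream(design: LanguageDesign, plan: StreamPlan = StreamPlan(),
                   seed: int = 0, max_restarts: int = 1000) -> list[WordSpec]:
    """Compose the token sequence of one exposure stream.

    Per block every word appears exactly ``plan.reps_per_block`` times; no
    token is immediately followed by the same word, and the boundary
    syllables of adjacent tokens always differ (blocks are contiguous
    audio, so the constraint also holds across block joins). Sequential
    seeded sampling with per-block restarts; raises after ``max_restarts``
    failed attempts on any block.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    words = list(design.words)
    tokens: list[WordSpec] = []
    prev: WordSpec | None = None
    for _ in range(plan.blocks):
        for attempt in range(max_restarts + 1):
            block = _compose_block(words, plan.reps_per_block, prev, rng)
            if block is not None:
                break
        else:
            raise DesignError(
                f"stream composition failed after {max_restarts} restarts"
            )
        tokens.extend(block)
        prev = tokens[-1]
    return tokens


def _compose_block(words, reps, prev, rng):
    counts = {w.word_id: reps for w in words}
    out = []
    for _ in range(len(words) * reps):
        cands = [w for w in words
                 if counts[w.word_id] > 0
                 and (prev is None
                      or (w.word_id != prev.word_id
                          and w.syllables[0] != prev.syllables[2]))]
        if not cands:
            return None  # dead end; caller restarts the block
        weights = np.array([counts[w.word_id] for w in cands], float)
        w = cands[rng.choice(len(cands), p=weights / weights.sum())]
        counts[w.word_id] -= 1
        out.append(w)
        prev = w
    return out


@dataclass
class ChirpSchedule:
    """Which word tokens carry a chirp, and at which inter-syllable interval.

    ``entries`` maps token index -> interval position; a chirp at interval
    position ``p`` starts at ``word_onset + p * syllable_duration``. The
    default interval set (1, 2) places chirps at the two within-word
    inter-syllable boundaries; the 3-position variant (0, 1, 2) also allows
    word onset.
    """

    entries: dict[int, int] = field(default_factory=dict)
    intervals: tuple[int, ...] = (1, 2)
    rate: float = 0.30


def schedule_chirps(tokens: list[WordSpec], rate: float = 0.30,
                    seed: int = 0,
                    intervals: tuple[int, ...] = (1, 2)) -> ChirpSchedule:
    """Schedule chirps on ``rate`` of each word's tokens, counterbalanced.

    Exactly ``round(rate * reps)`` tokens per word are chirped (18 of 60 at
    defaults), split evenly over the interval positions (9/9 at defaults);
    no token carries two chirps. A rate whose per-word chirp count does not
    divide evenly over the interval positions is rejected with the set of
    feasible rates.
    """
    if not 0 <= rate <= 1:
        raise DesignError("chirp rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_word: dict[str, list[int]] = {}
    for i, w in enumerate(tokens):
        by_word.setdefault(w.word_id, []).append(i)
    reps = {len(v) for v in by_word.values()}
    if len(reps) != 1:
        raise DesignError("tokens must contain equal counts of every word")
    reps = reps.pop()
    n_chirp = round(rate * reps)
    k = len(intervals)
    if n_chirp % k != 0:
        feasible = sorted({m * k / reps for m in range(reps // k + 1)})
        raise DesignError(
            f"rate {rate} gives {n_chirp} chirps per word, not divisible "
            f"over {k} interval positions; feasible rates: {feasible}"
        )
    entries: dict[int, int] = {}
    for word_id in sorted(by_word):
        chosen = rng.permutation(by_word[word_id])[:n_chirp]
        slots = np.repeat(intervals, n_chirp // k)
        slots = rng.permutation(slots)
        for tok, pos in zip(chosen, slots):
            entries[int(tok)] = int(pos)
    return ChirpSchedule(entries, tuple(intervals), rate)


def emit_events(tokens: list[WordSpec],
                chirps: ChirpSchedule | None = None,
                plan: StreamPlan = StreamPlan()) -> pd.DataFrame:
    """Tabulate word-onset, syllable-onset, and chirp events of a stream.

    Onsets are in ms from stream start; word ``k`` starts at
    ``k * 3 * syllable_duration``. Chirp onsets sit at the scheduled
    inter-syllable boundary instant.
    """
    rows = []
    per_block = 8 * plan.reps_per_block
    sd = plan.syllable_duration_ms
    for i, w in enumerate(tokens):
        onset = i * 3 * sd
        block = i // per_block + 1
        base = dict(word_id=w.word_id, predictability=w.predictability,
                    block=block, token_index=i)
        rows.append(dict(onset_ms=onset, event_kind="word_onset",
                         syllable_position=None, syllable=w.label,
                         chirp_interval_position=None, **base))
        for p in range(3):
            rows.append(dict(onset_ms=onset + p * sd,
                             event_kind="syllable_onset",
                             syllable_position=p,
                             syllable=w.syllables[p].label,
                             chirp_interval_position=None, **base))
        if chirps is not None and i in chirps.entries:
            pos = chirps.entries[i]
            rows.append(dict(onset_ms=onset + pos * sd, event_kind="chirp",
                             syllable_position=None, syllable=None,
                             chirp_interval_position=pos, **base))
    df = pd.DataFrame(rows).sort_values(
        ["onset_ms", "token_index", "event_kind"], kind="stable")
    return df.reset_index(drop=True)


def empirical_tp(events: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Observed P(next syllable | syllable) over the realized stream.

    Counts every syllable transition, word-boundary transitions included —
    what a listener who hears no boundaries could actually estimate.
    """
    sylls = (events[events["event_kind"] == "syllable_onset"]
             .sort_values("onset_ms")["syllable"].tolist())
    if len(sylls) < 2:
        return {}
    pair_counts: dict[tuple[str, str], int] = {}
    from_counts: dict[str, int] = {}
    for a, b in zip(sylls[:-1], sylls[1:]):
        pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        from_counts[a] = from_counts.get(a, 0) + 1
    return {pair: c / from_counts[pair[0]] for pair, c in pair_counts.items()}


# ---------------------------------------------------------------------------
# audio rendering


def chirp_waveform(sample_rate: int = 44100, duration_s: float = 0.1,
                   f0: float = 450.0, f1: float = 1450.0) -> np.ndarray:
    """The 0.1-s sawtooth sweep (450 -> 1450 Hz) used as the cover-task chirp."""
    from scipy.signal import sawtooth

    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    phase = f0 * t + (f1 - f0) / (2 * duration_s) * t ** 2
    return sawtooth(2 * np.pi * phase)


def _syllable_tone(label: str, index: int, n: int, sample_rate: int) -> np.ndarray:
    """Placeholder synthesis: a distinct harmonic tone per syllable label."""
    t = np.arange(n) / sample_rate
    f = 180.0 + 22.0 * index
    wave = (np.sin(2 * np.pi * f * t)
            + 0.5 * np.sin(2 * np.pi * 2 * f * t)
            + 0.25 * np.sin(2 * np.pi * 3 * f * t))
    # raised envelope: tapered onsets but no inter-syllable silence
    env = 0.2 + 0.8 * np.hanning(n)
    return wave * env


def render_audio(events: pd.DataFrame, sample_rate: int = 44100,
                 plan: StreamPlan = StreamPlan(),
                 chirp_gain: float = 0.5,
                 out_path=None) -> tuple[int, np.ndarray]:
    """Render an event table to a peak-normalized mono waveform.

    Syllable tones are synthesized placeholders (one harmonic timbre per
    label), concatenated without gaps; chirps are added at their scheduled
    instants. If ``out_path`` is given the waveform is also written as a
    16-bit WAV via :mod:`scipy.io.wavfile`.
    """
    sylls = events[events["event_kind"] == "syllable_onset"]
    if sylls.empty:
        return sample_rate, np.zeros(0)
    n_syll = int(round(plan.syllable_duration_ms / 1000 * sample_rate))
    end_ms = sylls["onset_ms"].max() + plan.syllable_duration_ms
    total = int(round(end_ms / 1000 * sample_rate))
    labels = sorted(set(sylls["syllable"]))
    tones = {lab: _syllable_tone(lab, i, n_syll, sample_rate)
             for i, lab in enumerate(labels)}
    wave = np.zeros(total)
    for _, row in sylls.iterrows():
        start = int(round(row["onset_ms"] / 1000 * sample_rate))
        wave[start:start + n_syll] = tones[row["syllable"]][:total - start]
    chirp = chirp_gain * chirp_waveform(sample_rate)
    for _, row in events[events["event_kind"] == "chirp"].iterrows():
        start = int(round(row["onset_ms"] / 1000 * sample_rate))
        seg = chirp[:max(0, total - start)]
        wave[start:start + len(seg)] += seg
    peak = np.abs(wave).max()
    if peak > 0:
        wave = 0.95 * wave / peak
    if out_path is not None:
        from scipy.io import wavfile

        wavfile.write(out_path, sample_rate,
                      np.asarray(wave * 32767, dtype=np.int16))
    return sample_rate, wave


# ---------------------------------------------------------------------------
# BIDS-style events TSV


def write_events_tsv(events: pd.DataFrame, path,
                     plan: StreamPlan = StreamPlan()) -> None:
    """Write an event table as a BIDS-style events TSV (onset/duration in s)."""
    out = events.copy()
    out.insert(0, "onset", out.pop("onset_ms") / 1000.0)
    dur = {"word_onset": 3 * plan.syllable_duration_ms / 1000.0,
           "syllable_onset": plan.syllable_duration_ms / 1000.0,
           "chirp": 0.1}
    out.insert(1, "duration", out["event_kind"].map(dur))
    out = out.rename(columns={"event_kind": "trial_type"})
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style events TSV back into the internal event-table layout."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    df = df.rename(columns={"trial_type": "event_kind"})
    df["onset_ms"] = df.pop("onset") * 1000.0
    return df.drop(columns=["duration"])
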