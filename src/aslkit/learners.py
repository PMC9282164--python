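"""Candidate segmentation strategies: TP tracking vs syllable-frequency tracking.

Two simple statistical learners operationalize the mechanisms contrasted
when interpreting the behavioral data: a learner that tracks forward
transitional probabilities between adjacent syllables, and one that tracks
plain syllable (unigram) frequencies. Both accumulate counts over the raw
syllable sequence — a naive listener hears no word boundaries — and score
test items by familiarity; a Luce/softmax choice rule turns paired
familiarity scores into simulated 2-AFC responses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LearnerState", "FamiliarityScore", "expose", "score_item",
           "simulate_2afc"]


@dataclass
class LearnerState:
    """Running unigram/bigram counts over an exposure stream.

    ``last_syllable`` carries the trailing context so that sequential
    exposure to two half-streams accumulates exactly the same counts as
    exposure to their concatenation.
    """

    bigram_counts: Counter = field(default_factory=Counter)
    unigram_counts: Counter = field(default_factory=Counter)
    total_tokens: int = 0
    last_syllable: str | None = None


def expose(state: LearnerState, events: pd.DataFrame) -> LearnerState:
    """Return a new state with counts updated from an event table."""
    sylls = (events[events["event_kind"] == "syllable_onset"]
             .sort_values("onset_ms")["syllable"].tolist())
    out = LearnerState(Counter(state.bigram_counts),
                       Counter(state.unigram_counts),
                       state.total_tokens, state.last_syllable)
    for s in sylls:
        out.unigram_counts[s] += 1
        out.total_tokens += 1
        if out.last_syllable is not None:
            out.bigram_counts[(out.last_syllable, s)] += 1
        out.last_syllable = s
    return out


@dataclass(frozen=True)
class FamiliarityScore:
    """Familiarity of a trisyllabic item under the two tracking strategies."""

    item: tuple[str, str, str]
    tp_score: float    # mean forward TP of the item's two bigrams
    freq_score: float  # mean relative unigram frequency of its syllables

    def by_strategy(self, strategy: str) -> float:
        if strategy == "tp":
            return self.tp_score
        if strategy == "freq":
            return self.freq_score
        if strategy == "mix":
            return 0.5 * (self.tp_score + self.freq_score)
        raise ValueError(f"unknown strategy {strategy!r}")


def score_item(state: LearnerState, item) -> FamiliarityScore:
    """Score a trisyllabic item (labels or an object with ``.syllables``).

    ``tp_score`` is the mean of P(s2|s1) and P(s3|s2) estimated from the
    bigram/transition counts; an unseen conditioning context or bigram
    contributes probability 0 (no smoothing — word items have full support
    on any exposure stream). ``freq_score`` is the mean relative unigram
    frequency of the three syllables.
    """
    labels = tuple(s.label for s in item.syllables) if hasattr(item, "syllables") \
        else tuple(item)
    if len(labels) != 3:
        raise ValueError("items are syllable triples")
    transitions_from = Counter()
    for (a, _), c in state.bigram_counts.items():
        transitions_from[a] += c
    tps = []
    for a, b in ((labels[0], labels[1]), (labels[1], labels[2])):
        denom = transitions_from[a]
        tps.append(state.bigram_counts[(a, b)] / denom if denom else 0.0)
    if state.total_tokens:
        freqs = [state.unigram_counts[s] / state.total_tokens for s in labels]
    else:
        freqs = [0.0, 0.0, 0.0]
    return FamiliarityScore(labels, float(np.mean(tps)), float(np.mean(freqs)))


def simulate_2afc(scores_word, scores_foil, strategy: str = "tp",
                  temperature: float = 0.1, seed: int = 0,
                  n_trials: int | None = None) -> np.ndarray:
    """Simulate 2-AFC choices from paired familiarity scores.

    ``scores_word`` / ``scores_foil`` are matched sequences of
    :class:`FamiliarityScore` (or raw floats), one pair per trial; if
    ``n_trials`` is given, the pairs are cycled to that length. The choice
    rule is Luce/softmax: P(choose word) = sigmoid((s_w - s_f) / T). As
    T -> inf choices approach chance; as T -> 0 they approach argmax.
    Returns a boolean vector, True where the word was chosen.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")

    def vals(seq):
        return np.array([s.by_strategy(strategy)
                         if isinstance(s, FamiliarityScore) else float(s)
                         for s in np.atleast_1d(seq)])

    sw, sf = vals(scores_word), vals(scores_foil)
    if sw.shape != sf.shape:
        raise ValueError("word and foil score sequences must be the same length")
    if n_trials is not None:
        reps = -(-n_trials // len(sw))
        sw = np.tile(sw, reps)[:n_trials]
        sf = np.tile(sf, reps)[:n_trials]
    rng = np.random.default_rng(seed)
    p_word = 1.0 / (1.0 + np.exp(-(sw - sf) / temperature))
    return rng.random(len(p_word)) < p_word
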