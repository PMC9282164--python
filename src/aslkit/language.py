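"""Artificial-language construction for auditory statistical-learning streams.

A language is built from a 16-syllable syllabary and contains eight
trisyllabic nonsense words differing in internal predictability:

* four **high-TP** words use 12 syllables, each of which occurs in exactly
  one word at one position, so every word-internal transitional probability
  (TP) is 1.0 over the exposure stream;
* four **low-TP** words share the remaining 4 syllables arranged as a 4x3
  Latin rectangle (each syllable once per position, never twice in a word),
  so every word-internal TP is 1/3 and each low-TP syllable is heard three
  times as often as a high-TP syllable.

Foils for the two-alternative forced-choice (2-AFC) test reuse the exposed
syllables at their exposed positions and with their exposed frequencies, but
no adjacent foil pair ever occurs inside any word (design TP = 0).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Syllable", "Syllabary", "WordSpec", "FoilSpec", "LanguageDesign",
    "Trial", "TrialList", "default_syllabary", "build_language",
    "design_tp", "generate_foils", "build_2afc_trials",
    "design_to_json", "design_from_json", "DesignError",
]

#: Words repeated this many times in the nominal exposure stream
#: (6 blocks x 10 repetitions).
NOMINAL_REPS = 60


class DesignError(ValueError):
    """Raised when a language design request or constraint search fails."""


@dataclass(frozen=True, order=True)
class Syllable:
    """A consonant-vowel syllable with its position in the syllabary."""

    label: str
    index: int


@dataclass(frozen=True)
class Syllabary:
    """An inventory of 16 unique syllables, identified as A or B."""

    id: str
    syllables: tuple[Syllable, ...]

    def __post_init__(self):
        labels = [s.label for s in self.syllables]
        if len(self.syllables) != 16:
            raise DesignError(
                f"syllabary must have exactly 16 syllables, got {len(self.syllables)}"
            )
        if len(set(labels)) != 16:
            raise DesignError("syllable labels must be unique within a syllabary")


@dataclass(frozen=True)
class WordSpec:
    """A trisyllabic nonsense word with its predictability class."""

    word_id: str
    syllables: tuple[Syllable, Syllable, Syllable]
    predictability: str  # "high" | "low"

    def __post_init__(self):
        if len(self.syllables) != 3 or len(set(self.syllables)) != 3:
            raise DesignError("a word has 3 distinct syllables")

    @property
    def label(self) -> str:
        return "".join(s.label for s in self.syllables)


@dataclass(frozen=True)
class FoilSpec:
    """A 2-AFC foil: exposed syllables at exposed positions, unseen bigrams."""

    syllables: tuple[Syllable, Syllable, Syllable]
    predictability_class: str

    @property
    def label(self) -> str:
        return "".join(s.label for s in self.syllables)


@dataclass
class LanguageDesign:
    """The full inventory of one auditory statistical-learning task."""

    syllabary: Syllabary
    words: tuple[WordSpec, ...]
    foils: tuple[FoilSpec, ...] = ()
    seed: int | None = None

    @property
    def high_words(self) -> tuple[WordSpec, ...]:
        return tuple(w for w in self.words if w.predictability == "high")

    @property
    def low_words(self) -> tuple[WordSpec, ...]:
        return tuple(w for w in self.words if w.predictability == "low")

    def validate(self) -> None:
        if len(self.high_words) != 4 or len(self.low_words) != 4:
            raise DesignError("design needs 4 high-TP and 4 low-TP words")
        if len({w.label for w in self.words}) != 8:
            raise DesignError("words must be distinct")
        high_sylls = [s for w in self.high_words for s in w.syllables]
        if len(set(high_sylls)) != 12:
            raise DesignError("high-TP words must use 12 syllables once each")
        low_sylls = {s for w in self.low_words for s in w.syllables}
        if len(low_sylls) != 4:
            raise DesignError("low-TP words must draw on exactly 4 syllables")
        if set(high_sylls) & low_sylls:
            raise DesignError("high- and low-TP syllable sets must be disjoint")
        # Latin-rectangle layout: each low syllable once per position.
        for pos in range(3):
            col = [w.syllables[pos] for w in self.low_words]
            if len(set(col)) != 4:
                raise DesignError(
                    "each low-TP syllable must occupy each position exactly once"
                )


# ---------------------------------------------------------------------------
# default syllabaries

_CV_A = ("tu ci da bo pe ga le fu ra so nu vi mi ge do ti").split()
_CV_B = ("ba ke li po ru se ta ve zo du fa go ne ja cu bi").split()


def default_syllabary(which: str = "A") -> Syllabary:
    """The built-in synthetic CV syllabary A or B (disjoint label sets)."""
    labels = {"A": _CV_A, "B": _CV_B}.get(which.upper())
    if labels is None:
        raise DesignError(f"syllabary id must be 'A' or 'B', got {which!r}")
    return Syllabary(which.upper(), tuple(Syllable(l, i) for i, l in enumerate(labels)))


# ---------------------------------------------------------------------------
# language construction


def build_language(syllabary: Syllabary, seed: int) -> LanguageDesign:
    """Build a full language (words + foils) from a 16-syllable syllabary.

    The 16 syllables are partitioned (seeded) into 12 high-TP syllables,
    forming four words that each own their three syllable/position slots,
    and 4 low-TP syllables arranged as a 4x3 Latin rectangle. Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sylls = list(syllabary.syllables)
    order = rng.permutation(16)
    high = [sylls[i] for i in order[:12]]
    low = [sylls[i] for i in order[12:]]

    words = []
    for k in range(4):
        trip = tuple(high[3 * k: 3 * k + 3])
        words.append(WordSpec(f"{syllabary.id}H{k + 1}", trip, "high"))

    # Latin rectangle via cyclic shifts: word i = (low[i], low[i+a], low[i+b]).
    a, b = rng.permutation([1, 2, 3])[:2]
    for k in range(4):
        trip = (low[k], low[(k + a) % 4], low[(k + b) % 4])
        words.append(WordSpec(f"{syllabary.id}L{k + 1}", trip, "low"))

    design = LanguageDesign(syllabary, tuple(words), seed=seed)
    design.validate()
    design.foils = generate_foils(design, seed)
    return design


def _word_bigrams(design: LanguageDesign) -> set[tuple[Syllable, Syllable]]:
    out = set()
    for w in design.words:
        out.add((w.syllables[0], w.syllables[1]))
        out.add((w.syllables[1], w.syllables[2]))
    return out


def design_tp(design: LanguageDesign,
              bigram: tuple[Syllable, Syllable],
              reps: int = NOMINAL_REPS) -> float:
    """Design transitional probability of an ordered syllable pair.

    Defined over the nominal stream in which every word is repeated
    ``reps`` times: word-internal occurrences of the bigram divided by the
    total number of tokens of its first syllable. This reproduces the three
    printed design values — 1.0 for high-TP word bigrams, 1/3 for low-TP
    word bigrams, 0 for foil bigrams — independently of token order.
    """
    s1, s2 = bigram
    known = set(design.syllabary.syllables)
    if s1 not in known or s2 not in known:
        raise KeyError(f"bigram {s1.label}-{s2.label} not in syllabary {design.syllabary.id}")
    numer = 0
    denom = 0
    for w in design.words:
        for pos in range(3):
            if w.syllables[pos] == s1:
                denom += reps
                if pos < 2 and w.syllables[pos + 1] == s2:
                    numer += reps
    if denom == 0:
        return 0.0
    return numer / denom


def generate_foils(design: LanguageDesign, seed: int,
                   max_nodes: int = 200_000) -> tuple[FoilSpec, ...]:
    """Seeded backtracking search for four foils per predictability class.

    Constraints per class: every foil syllable keeps a positional slot it
    occupied in the source words, the multiset of (syllable, position) slots
    is exactly that of the source words (equal per-stream token frequency),
    each foil has three distinct syllables, and no adjacent foil pair is a
    word-internal bigram of any word (design TP = 0). Fails loudly if the
    constraint set is infeasible.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    bigrams = _word_bigrams(design)
    foils: list[FoilSpec] = []
    for klass in ("high", "low"):
        source = [w for w in design.words if w.predictability == klass]
        # Remaining (syllable, position) slots; one per source occurrence.
        pools = [[w.syllables[p] for w in source] for p in range(3)]
        for p in range(3):
            pools[p] = list(rng.permutation(pools[p]))
        assignment: list[list[Syllable]] = [[] for _ in range(4)]
        nodes = 0

        def extend(slot: int) -> bool:
            # slot runs over foil-major order: foil i, position p = slot % 3.
            nonlocal nodes
            if slot == 12:
                return True
            i, p = divmod(slot, 3)
            tried: set[Syllable] = set()
            for j, s in enumerate(pools[p]):
                if s is None or s in tried:
                    continue
                tried.add(s)
                if s in assignment[i]:
                    continue
                if p > 0 and (assignment[i][p - 1], s) in bigrams:
                    continue
                nodes += 1
                if nodes > max_nodes:
                    raise DesignError("foil search exceeded node budget")
                pools[p][j] = None
                assignment[i].append(s)
                if extend(slot + 1):
                    return True
                assignment[i].pop()
                pools[p][j] = s
            return False

        if not extend(0):
            raise DesignError(
                f"no foil assignment satisfies the TP=0 constraints for the "
                f"{klass} class of this design"
            )
        for i in range(4):
            foils.append(FoilSpec(tuple(assignment[i]), klass))
    return tuple(foils)


# ---------------------------------------------------------------------------
# 2-AFC trial construction


@dataclass(frozen=True)
class Trial:
    word: WordSpec
    foil: FoilSpec
    presentation_order: str  # "word_first" | "foil_first"
    block: int  # 1 | 2


@dataclass
class TrialList:
    trials: tuple[Trial, ...]

    def validate(self) -> None:
        if len(self.trials) != 16:
            raise DesignError("a 2-AFC list has 16 trials")
        for block in (1, 2):
            rows = [t for t in self.trials if t.block == block]
            if len(rows) != 8:
                raise DesignError("each block has 8 trials")
            for klass in ("high", "low"):
                first = [t for t in rows
                         if t.word.predictability == klass
                         and t.presentation_order == "word_first"]
                if len(first) != 2:
                    raise DesignError(
                        "half of each word class must be presented word-first"
                    )
        for word_id in {t.word.word_id for t in self.trials}:
            rows = [t for t in self.trials if t.word.word_id == word_id]
            if len(rows) != 2 or rows[0].foil.label == rows[1].foil.label:
                raise DesignError("each word appears twice, with two different foils")


def build_2afc_trials(design: LanguageDesign, seed: int) -> TrialList:
    """Build the 16-trial, two-block 2-AFC list with its counterbalancing.

    Each word is paired with two different foils of its own predictability
    class (one pairing per block); within each block half of the high- and
    half of the low-TP words are presented word-first. Trial order within
    blocks and the block order are randomized under the seed.
    """
    if len(design.foils) != 8:
        raise DesignError("design needs 8 foils; run generate_foils first")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for klass in ("high", "low"):
        words = list(rng.permutation([w for w in design.words
                                      if w.predictability == klass]))
        foils = list(rng.permutation([f for f in design.foils
                                      if f.predictability_class == klass]))
        # word-first flags: 2 of 4 per class per block, complementary halves
        flags = list(rng.permutation([True, True, False, False]))
        for block in (1, 2):
            for i, w in enumerate(words):
                f = foils[(i + block - 1) % 4]
                word_first = flags[i] if block == 1 else not flags[i]
                trials.append(Trial(
                    w, f, "word_first" if word_first else "foil_first", block))
    blocks = [1, 2] if rng.random() < 0.5 else [2, 1]
    ordered: list[Trial] = []
    for block in blocks:
        rows = [t for t in trials if t.block == block]
        ordered.extend(rng.permutation(rows))
    out = TrialList(tuple(ordered))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# serialization


def design_to_json(design: LanguageDesign, trial_list: TrialList | None = None) -> str:
    doc = {
        "syllabary": {"id": design.syllabary.id,
                      "syllables": [s.label for s in design.syllabary.syllables]},
        "seed": design.seed,
        "words": [{"word_id": w.word_id,
                   "syllables": [s.label for s in w.syllables],
                   "predictability": w.predictability} for w in design.words],
        "foils": [{"syllables": [s.label for s in f.syllables],
                   "predictability_class": f.predictability_class}
                  for f in design.foils],
    }
    if trial_list is not None:
        doc["trials"] = [{"word": t.word.word_id,
                          "foil": t.foil.label,
                          "presentation_order": t.presentation_order,
                          "block": t.block} for t in trial_list.trials]
    return json.dumps(doc, indent=2)


def design_from_json(text: str) -> LanguageDesign:
    doc = json.loads(text)
    syl = Syllabary(doc["syllabary"]["id"],
                    tuple(Syllable(l, i)
                          for i, l in enumerate(doc["syllabary"]["syllables"])))
    by_label = {s.label: s for s in syl.syllables}
    words = tuple(WordSpec(w["word_id"],
                           tuple(by_label[l] for l in w["syllables"]),
                           w["predictability"]) for w in doc["words"])
    foils = tuple(FoilSpec(tuple(by_label[l] for l in f["syllables"]),
                           f["predictability_class"]) for f in doc["foils"])
    design = LanguageDesign(syl, words, foils, seed=doc.get("seed"))
    design.validate()
    return design
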