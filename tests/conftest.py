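import numpy as np
import pandas as pd
import pytest

import aslkit as ak
from aslkit.stream import StreamPlan


@pytest.fixture(scope="session")
def design():
    return ak.build_language(ak.default_syllabary("A"), seed=3)


@pytest.fixture(scope="session")
def default_plan():
    return StreamPlan()


@pytest.fixture(scope="session")
def tokens(design, default_plan):
    return ak.compose_stream(design, default_plan, seed=1)


@pytest.fixture(scope="session")
def chirps(tokens):
    return ak.schedule_chirps(tokens, seed=2)


@pytest.fixture(scope="session")
def events(tokens, chirps, default_plan):
    return ak.emit_events(tokens, chirps, default_plan)


@pytest.fixture(scope="session")
def small_plan():
    return StreamPlan(blocks=2, reps_per_block=3)


@pytest.fixture(scope="session")
def small_events(design, small_plan):
    toks = ak.compose_stream(design, small_plan, seed=11)
    return ak.emit_events(toks, None, small_plan)


def nominal_token_list(design, reps=60):
    """Brute-force oracle input: every word repeated ``reps`` times."""
    return [w for w in design.words for _ in range(reps)]


def brute_force_design_tp(design, bigram, reps=60):
    """Enumerate the nominal token list and count word-internal bigrams."""
    s1, s2 = bigram
    numer = denom = 0
    for w in nominal_token_list(design, reps):
        for pos in range(3):
            if w.syllables[pos] == s1:
                denom += 1
                if pos < 2 and w.syllables[pos + 1] == s2:
                    numer += 1
    return numer / denom if denom else 0.0
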