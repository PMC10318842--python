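import random

import pytest

from eulertigs import build_dbg

# Worked-example inputs: a two-string k=3 instance whose graph contains
# self-complemental nodes, and a single k=4 string on which greedy
# heuristics can go wrong while a single Eulerian string exists.
FIG1_STRINGS = ["GAATG", "ATCTGCT"]
FIG1_K = 3
FIG1_OPTIMUM = {"ATC", "AGAATGCTG"}

FIG2_STRING = "AGGTGCCGTGGGAT"
FIG2_K = 4


@pytest.fixture
def fig1_strings():
    return list(FIG1_STRINGS)


@pytest.fixture
def fig1_graph():
    return build_dbg(FIG1_STRINGS, FIG1_K)


@pytest.fixture
def fig2_graph():
    return build_dbg([FIG2_STRING], FIG2_K)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_instance(rng: random.Random, k: int, max_extra: int = 40):
    n = rng.randint(1, 3)
    return [
        random_dna(rng, rng.randint(k, k + rng.choice([2, 10, max_extra])))
        for _ in range(n)
    ]
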