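"""Synthetic genome fixtures: a random reference plus mutated replicates.

Emulates the redundancy of a small pangenome: near-identical sequences
whose shared k-mers collapse in the spectrum while point mutations
introduce bubbles and branch nodes.  Fully reproducible from the seed.
"""

from __future__ import annotations

import random

__all__ = ["generate_random_genomes"]

_BASES = "ACGT"


def generate_random_genomes(
    n_strings: int,
    length: int,
    mutation_rate: float,
    seed: int,
) -> list[str]:
    """One uniform-random reference and ``n_strings - 1`` mutated copies.

    Each replicate substitutes every position independently with
    probability ``mutation_rate`` by a different uniformly chosen base.
    """
    if n_strings < 1:
        raise ValueError("n_strings must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = random.Random(seed)
    reference = "".join(rng.choice(_BASES) for _ in range(length))
    genomes = [reference]
    for _ in range(n_strings - 1):
        chars = []
        for ch in reference:
            if rng.random() < mutation_rate:
                chars.append(rng.choice([b for b in _BASES if b != ch]))
            else:
                chars.append(ch)
        genomes.append("".join(chars))
    return genomes
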