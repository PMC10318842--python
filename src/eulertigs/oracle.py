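"""Exhaustive minimum unique-walk-cover oracle for tiny graphs.

Independent of the Eulerisation pipeline: a bitmask dynamic program over
(set of covered arcs, incidence where the current walk ends) computes the
true minimum number of walks covering every arc exactly once in exactly
one orientation.  Used to certify optimality of the pipeline on small
random instances.  A permutation-enumeration variant is provided as a
second, even more literal oracle for cross-checking the DP itself.
"""

from __future__ import annotations

from itertools import permutations, product

from .dna import DNA, ComplementMap
from .graph import BiGraph, build_dbg, negate

__all__ = ["brute_force_min_spss", "min_unique_walk_cover", "MAX_ORACLE_ARCS"]

MAX_ORACLE_ARCS = 8


def min_unique_walk_cover(g: BiGraph, max_arcs: int = MAX_ORACLE_ARCS) -> int:
    """Minimum number of walks covering each arc exactly once.

    Dynamic program: ``dp[mask][end]`` is the least number of walks that
    together cover exactly the arc set ``mask``, with the latest walk
    ending at incidence ``end``.  A walk is extended by any uncovered arc
    entering at the negation of ``end``; a new walk may start anywhere.
    """
    arcs = sorted(g.arcs)
    n = len(arcs)
    if n == 0:
        return 0
    if n > max_arcs:
        raise ValueError(
            f"graph has {n} arcs; the exhaustive oracle refuses more than "
            f"{max_arcs}"
        )
    moves = []  # per arc: list of (entry, exit)
    for aid in arcs:
        arc = g.arcs[aid]
        moves.append([arc.oriented(True), arc.oriented(False)])

    full = (1 << n) - 1
    dp: list[dict[tuple[str, str], int]] = [dict() for _ in range(1 << n)]
    for j in range(n):
        for _, exit_ in moves[j]:
            bit = 1 << j
            prev = dp[bit].get(exit_)
            if prev is None or prev > 1:
                dp[bit][exit_] = 1

    for mask in range(1, full + 1):
        if not dp[mask]:
            continue
        best_here = min(dp[mask].values())
        for j in range(n):
            if mask & (1 << j):
                continue
            nmask = mask | (1 << j)
            for entry, exit_ in moves[j]:
                # start a fresh walk with arc j
                w = best_here + 1
                cur = dp[nmask].get(exit_)
                if cur is None or cur > w:
                    dp[nmask][exit_] = w
                # or continue a walk ending at the matching incidence
                want = (entry[0], negate(entry[1]))
                w2 = dp[mask].get(want)
                if w2 is not None:
                    cur = dp[nmask].get(exit_)
                    if cur is None or cur > w2:
                        dp[nmask][exit_] = w2
    return min(dp[full].values())


def _enumeration_min_cover(g: BiGraph, max_arcs: int = 5) -> int:
    """Literal oracle: try every arc permutation and orientation vector,
    split greedily into maximal valid walks, take the fewest walks.

    Correct because the arcs of an optimal cover, listed walk by walk,
    form one of the enumerated permutation/orientation combinations.
    """
    arcs = sorted(g.arcs)
    n = len(arcs)
    if n == 0:
        return 0
    if n > max_arcs:
        raise ValueError(f"enumeration oracle capped at {max_arcs} arcs")
    best = n
    for perm in permutations(range(n)):
        for orient in product((True, False), repeat=n):
            walks = 1
            prev_exit = None
            for idx in perm:
                entry, exit_ = g.arcs[arcs[idx]].oriented(orient[idx])
                if prev_exit is not None and entry != (
                    prev_exit[0],
                    negate(prev_exit[1]),
                ):
                    walks += 1
                prev_exit = exit_
            best = min(best, walks)
    return best


def brute_force_min_spss(
    strings: list[str],
    k: int,
    cmap: ComplementMap = DNA,
    max_arcs: int = MAX_ORACLE_ARCS,
) -> int:
    """True minimum string count of an SPSS without repetitions.

    Builds the de Bruijn graph of the input and runs the exhaustive
    walk-cover oracle; refuses graphs with more than ``max_arcs`` arcs.
    """
    g = build_dbg(strings, k, cmap)
    return min_unique_walk_cover(g, max_arcs=max_arcs)
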