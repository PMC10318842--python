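"""Greedy SPSS heuristics: forward extension (UST-style, with the join
post-pass) and bidirectional extension (ProphAsm-style).

Both produce valid SPSSs without repetitions but not necessarily of
minimum cumulative length.  Extension ties are broken by smallest arc
identifier; the choice of starting arcs can be pinned via ``start_order``
to reproduce adversarial traces.
"""

from __future__ import annotations

from .dna import canonical
from .graph import BiGraph, Walk, negate, spell
from .pipeline import SPSS

__all__ = ["greedy_forward_spss", "greedy_bidirectional_spss"]


def _resolve_starts(
    g: BiGraph, start_order
) -> list[tuple[str, bool]]:
    """Resolve start_order into oriented (arc id, forward) picks.

    Entries may be canonical arc identifiers (traversed forward) or any
    orientation of an arc's label, in which case the arc is traversed so
    that it spells the given text.  Remaining arcs follow in identifier
    order, forward.
    """
    resolved: list[tuple[str, bool]] = []
    pinned: set[str] = set()
    if start_order != "lexicographic":
        for text in start_order:
            if text in g.arcs:
                resolved.append((text, True))
                pinned.add(text)
                continue
            try:
                can = canonical(text, g.cmap)
            except ValueError:
                can = None
            if can is None or can not in g.arcs:
                raise KeyError(f"unknown arc identifier {text!r}")
            resolved.append((can, text == can))
            pinned.add(can)
    for aid in sorted(g.arcs):
        if aid not in pinned:
            resolved.append((aid, True))
    return resolved


def _successor(
    g: BiGraph, unused: set[str], node: str, sign: str
) -> tuple[str, bool] | None:
    """Smallest-identifier unused arc entering at (node, sign)."""
    best: tuple[str, bool] | None = None
    for arc in g.incident_arcs(node):
        if arc.identifier not in unused:
            continue
        for fwd in (True, False):
            entry, _ = arc.oriented(fwd)
            if entry == (node, sign):
                if best is None or arc.identifier < best[0]:
                    best = (arc.identifier, fwd)
                break
    return best


def _predecessor(
    g: BiGraph, unused: set[str], node: str, sign: str
) -> tuple[str, bool] | None:
    """Smallest-identifier unused arc whose oriented exit is (node, sign)."""
    best: tuple[str, bool] | None = None
    for arc in g.incident_arcs(node):
        if arc.identifier not in unused:
            continue
        for fwd in (True, False):
            _, exit_ = arc.oriented(fwd)
            if exit_ == (node, sign):
                if best is None or arc.identifier < best[0]:
                    best = (arc.identifier, fwd)
                break
    return best


def _extend_forward(g: BiGraph, unused: set[str], steps: list) -> None:
    while True:
        _, (v, d) = g.arcs[steps[-1][0]].oriented(steps[-1][1])
        nxt = _successor(g, unused, v, negate(d))
        if nxt is None:
            return
        unused.discard(nxt[0])
        steps.append(nxt)


def _extend_backward(g: BiGraph, unused: set[str], steps: list) -> None:
    while True:
        (v, d), _ = g.arcs[steps[0][0]].oriented(steps[0][1])
        prv = _predecessor(g, unused, v, negate(d))
        if prv is None:
            return
        unused.discard(prv[0])
        steps.insert(0, prv)


def _spell_all(g: BiGraph, walks: list[list]) -> SPSS:
    return SPSS(strings=[spell(g, Walk(w)) for w in walks], k=g.k)


def greedy_forward_spss(g: BiGraph, start_order="lexicographic") -> SPSS:
    """Forward-only greedy extension with the end-to-start join rule.

    Repeatedly picks the next unused arc per ``start_order`` and extends
    forwards while an unused sign-compatible successor exists.  A
    post-pass joins any walk whose last arc has a successor that starts
    another walk (first match by smallest leading-arc identifier).
    """
    unused = set(g.arcs)
    walks: list[list] = []
    for aid, fwd in _resolve_starts(g, start_order):
        if aid not in unused:
            continue
        unused.discard(aid)
        steps = [(aid, fwd)]
        _extend_forward(g, unused, steps)
        walks.append(steps)

    # join pass: successor-of-last-arc meets first-arc-of-another-walk.
    # Walks are strand-symmetric, so either participant may be flipped;
    # the first join found (smallest leading-arc identifier) is applied
    # and the scan restarts until no join remains.
    def _flip(steps):
        return [(a, not f) for a, f in reversed(steps)]

    changed = True
    while changed:
        changed = False
        for i in range(len(walks)):
            for wa in (walks[i], _flip(walks[i])):
                _, (v, d) = g.arcs[wa[-1][0]].oriented(wa[-1][1])
                want = negate(d)
                best: tuple[int, list] | None = None
                for j, other in enumerate(walks):
                    if j == i:
                        continue
                    for wb in (other, _flip(other)):
                        entry, _ = g.arcs[wb[0][0]].oriented(wb[0][1])
                        if entry == (v, want) and (
                            best is None or wb[0][0] < best[1][0][0]
                        ):
                            best = (j, wb)
                if best is not None:
                    j, wb = best
                    merged = wa + wb
                    walks[i] = merged
                    del walks[j]
                    changed = True
                    break
            if changed:
                break
    return _spell_all(g, walks)


def greedy_bidirectional_spss(g: BiGraph, start_order="lexicographic") -> SPSS:
    """Greedy extension forwards to exhaustion, then backwards."""
    unused = set(g.arcs)
    walks: list[list] = []
    for aid, fwd in _resolve_starts(g, start_order):
        if aid not in unused:
            continue
        unused.discard(aid)
        steps = [(aid, fwd)]
        _extend_forward(g, unused, steps)
        _extend_backward(g, unused, steps)
        walks.append(steps)
    return _spell_all(g, walks)
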