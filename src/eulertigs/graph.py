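"""The bidirected arc-centric de Bruijn graph.

Nodes are canonical (k-1)-mers, arcs are canonical k-mers.  Each arc
endpoint carries a *sign*: ``+`` where the (k-1)-mer occurs in its
canonical orientation at that end of the k-mer (outgoing), ``-`` where it
occurs reverse-complemented (incoming), and ``.`` at self-complemental
nodes, where orientation is meaningless.  A walk must leave a node with
the sign opposite to the one it arrived with, which makes walks spell
exactly the strings whose k-mers are contained in the graph.

Sign assignment for an arc with canonical k-mer label ``h``::

    start node v  = canonical(pre_{k-1}(h)):  '+' if pre is canonical, else '-'
    end   node v' = canonical(suf_{k-1}(h)):  '-' if suf is canonical, else '+'
    either endpoint self-complemental:        '.'

With this convention two arcs chain at a shared node with negated signs
precisely when their (k-1)-overlaps match (possibly via reverse
complement); this equivalence is the normative contract and is
property-tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .dna import (
    DNA,
    ComplementMap,
    canonical,
    clean_fragments,
    canonical_spectrum,
    kmer_sequence,
)

__all__ = [
    "PLUS",
    "MINUS",
    "DOT",
    "negate",
    "Node",
    "Arc",
    "Walk",
    "BiGraph",
    "build_dbg",
    "build_dbg_from_kmers",
    "incidence_count",
    "node_imbalance",
    "connected_components",
    "compact",
    "spell",
    "walk_kmers",
    "walk_for_string",
    "gfa_dump",
    "BREAK_PREFIX",
]

PLUS = "+"
MINUS = "-"
DOT = "."

_NEGATE = {PLUS: MINUS, MINUS: PLUS, DOT: DOT}

#: Reserved identifier namespace for balancing arcs, disjoint from any
#: DNA word (the section sign is outside every complement alphabet).
BREAK_PREFIX = "§BREAK§"


def negate(sign: str) -> str:
    """Sign negation: ``+`` <-> ``-``, ``.`` is self-inverse."""
    return _NEGATE[sign]


def is_breaking_id(identifier: str) -> bool:
    return identifier.startswith(BREAK_PREFIX)


@dataclass(frozen=True)
class Node:
    label: str
    self_complemental: bool


@dataclass(frozen=True)
class Arc:
    """An arc: two signed incidences plus a unique identifier.

    For real arcs the identifier *is* the canonical k-mer (or, after
    compaction, the canonical spelled unitig) and ``label`` equals it.
    Balancing arcs carry a reserved identifier and ``label is None``.
    """

    identifier: str
    v1: str
    d1: str
    v2: str
    d2: str
    label: str | None

    @property
    def is_breaking(self) -> bool:
        return self.label is None

    def incidences(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return ((self.v1, self.d1), (self.v2, self.d2))

    def incidence_multiplicity(self, node: str, sign: str) -> int:
        """#_e(node, sign): 0, 1, or 2 (a self-loop counts twice)."""
        return sum(
            1 for v, d in self.incidences() if v == node and d == sign
        )

    def oriented(self, forward: bool) -> tuple[tuple[str, str], tuple[str, str]]:
        """Entry and exit incidences when traversed in a given direction."""
        if forward:
            return (self.v1, self.d1), (self.v2, self.d2)
        return (self.v2, self.d2), (self.v1, self.d1)


@dataclass
class Walk:
    """A sign-consistent sequence of oriented arc traversals.

    ``steps`` is a list of ``(arc identifier, forward)`` pairs; traversing
    forward uses the arc as stored, reverse uses its reversal.
    """

    steps: list[tuple[str, bool]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def reversed(self) -> "Walk":
        return Walk([(aid, not fwd) for aid, fwd in reversed(self.steps)])


class InvalidWalkError(ValueError):
    pass


class BiGraph:
    """Bidirected graph with arcs keyed by identifier, nodes by label.

    ``adjacency`` maps a node label to the list of ``(arc id, endpoint
    index)`` incidences in stable insertion order; a self-loop appears
    twice (once per endpoint).
    """

    def __init__(self, k: int, cmap: ComplementMap = DNA, compacted: bool = False):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        self.k = k
        self.cmap = cmap
        self.compacted = compacted
        self.nodes: dict[str, Node] = {}
        self.arcs: dict[str, Arc] = {}
        self.adjacency: dict[str, list[tuple[str, int]]] = {}

    # -- construction ---------------------------------------------------

    def _ensure_node(self, kmer_text: str) -> Node:
        can = canonical(kmer_text, self.cmap)
        node = self.nodes.get(can)
        if node is None:
            node = Node(can, self_complemental=can == self.cmap.rc(can))
            self.nodes[can] = node
            self.adjacency[can] = []
        return node

    def add_arc(self, arc: Arc) -> None:
        if arc.identifier in self.arcs:
            raise ValueError(f"duplicate arc identifier {arc.identifier!r}")
        for (v, d) in arc.incidences():
            if v not in self.nodes:
                raise ValueError(f"arc endpoint {v!r} references no node")
            if self.nodes[v].self_complemental:
                if d != DOT:
                    raise ValueError(
                        f"self-complemental node {v} requires '.' sign, got {d!r}"
                    )
            elif d not in (PLUS, MINUS):
                raise ValueError(f"normal node {v} requires '+'/'-' sign, got {d!r}")
        self.arcs[arc.identifier] = arc
        self.adjacency[arc.v1].append((arc.identifier, 0))
        self.adjacency[arc.v2].append((arc.identifier, 1))

    def add_kmer_arc(self, label: str) -> Arc:
        """Insert the arc for a canonical label spanning >= k characters.

        Endpoints are the canonical (k-1)-prefix/suffix with signs per the
        module convention.  Used both for plain k-mers and for compacted
        unitig labels.
        """
        k = self.k
        pre, suf = label[: k - 1], label[-(k - 1):]
        n1 = self._ensure_node(pre)
        n2 = self._ensure_node(suf)
        if n1.self_complemental:
            d1 = DOT
        else:
            d1 = PLUS if pre == n1.label else MINUS
        if n2.self_complemental:
            d2 = DOT
        else:
            d2 = MINUS if suf == n2.label else PLUS
        arc = Arc(label, n1.label, d1, n2.label, d2, label)
        self.add_arc(arc)
        return arc

    # -- queries --------------------------------------------------------

    def incident_arcs(self, node: str) -> list[Arc]:
        seen: set[str] = set()
        out = []
        for aid, _ in self.adjacency[node]:
            if aid not in seen:
                seen.add(aid)
                out.append(self.arcs[aid])
        return out

    def arc_count(self) -> int:
        return len(self.arcs)

    def spectrum(self) -> frozenset[str]:
        return frozenset(a.label for a in self.arcs.values() if a.label is not None)


def build_dbg_from_kmers(
    kmers, k: int, cmap: ComplementMap = DNA
) -> BiGraph:
    """Build the graph with one arc per canonical k-mer of ``kmers``.

    K-mers are canonicalised; duplicates collapse.  Insertion order is
    the first-seen order, so construction is deterministic for a
    deterministic input iteration.
    """
    g = BiGraph(k, cmap)
    for kmer in kmers:
        if len(kmer) != k:
            raise ValueError(f"k-mer {kmer!r} does not have length k={k}")
        can = canonical(kmer, cmap)
        if can not in g.arcs:
            g.add_kmer_arc(can)
    return g


def build_dbg(strings: list[str], k: int, cmap: ComplementMap = DNA) -> BiGraph:
    """Build the order-k bidirected de Bruijn graph of a set of strings.

    One arc per canonical k-mer occurring in the input (occurrence
    multiplicity is ignored).  Strings are uppercased and split at
    non-alphabet characters first; an empty spectrum yields an empty
    graph.  Hash-based construction, O(total input length * k).
    """
    g = BiGraph(k, cmap)
    for frag in clean_fragments(strings, k, cmap):
        for kmer in kmer_sequence(frag, k):
            can = canonical(kmer, cmap)
            if can not in g.arcs:
                g.add_kmer_arc(can)
    return g


def incidence_count(g: BiGraph, node: str, sign: str) -> int:
    """Multiplicity of the incidence (node, sign) over all arcs."""
    total = 0
    for aid, endpoint in g.adjacency[node]:
        arc = g.arcs[aid]
        v, d = arc.incidences()[endpoint]
        if v == node and d == sign:
            total += 1
    return total


def node_imbalance(g: BiGraph, node: str) -> int:
    """Outdegree minus indegree; for self-complemental nodes, degree parity."""
    n = g.nodes[node]
    if n.self_complemental:
        return incidence_count(g, node, DOT) % 2
    return incidence_count(g, node, PLUS) - incidence_count(g, node, MINUS)


def connected_components(g: BiGraph) -> list[BiGraph]:
    """Maximal connected subgraphs (connectivity ignores signs).

    Components are returned ordered by their smallest node label.
    """
    seen: set[str] = set()
    components: list[BiGraph] = []
    for root in sorted(g.nodes):
        if root in seen:
            continue
        labels = {root}
        stack = [root]
        seen.add(root)
        while stack:
            v = stack.pop()
            for aid, _ in g.adjacency[v]:
                arc = g.arcs[aid]
                for u in (arc.v1, arc.v2):
                    if u not in seen:
                        seen.add(u)
                        labels.add(u)
                        stack.append(u)
        sub = BiGraph(g.k, g.cmap, compacted=g.compacted)
        for label in sorted(labels):
            sub.nodes[label] = g.nodes[label]
            sub.adjacency[label] = []
        for aid, arc in g.arcs.items():
            if arc.v1 in labels:
                sub.arcs[aid] = arc
                sub.adjacency[arc.v1].append((aid, 0))
                sub.adjacency[arc.v2].append((aid, 1))
        components.append(sub)
    return components


# -- walks and spelling -------------------------------------------------


def _check_chain(g: BiGraph, walk: Walk) -> None:
    prev_exit: tuple[str, str] | None = None
    for idx, (aid, fwd) in enumerate(walk.steps):
        arc = g.arcs.get(aid)
        if arc is None:
            raise InvalidWalkError(f"step {idx}: unknown arc {aid!r}")
        entry, exit_ = arc.oriented(fwd)
        if prev_exit is not None:
            if entry[0] != prev_exit[0] or entry[1] != negate(prev_exit[1]):
                raise InvalidWalkError(
                    f"step {idx}: entry incidence {entry} does not chain with "
                    f"previous exit {prev_exit}"
                )
        prev_exit = exit_


def is_cycle(g: BiGraph, walk: Walk) -> bool:
    if not walk.steps:
        return False
    first_entry, _ = g.arcs[walk.steps[0][0]].oriented(walk.steps[0][1])
    _, last_exit = g.arcs[walk.steps[-1][0]].oriented(walk.steps[-1][1])
    return first_entry[0] == last_exit[0] and first_entry[1] == negate(last_exit[1])


def walk_kmers(g: BiGraph, walk: Walk) -> list[str]:
    """The label sequence of a walk: the arc label when traversed forward,
    its reverse complement when traversed in reverse."""
    _check_chain(g, walk)
    out = []
    for aid, fwd in walk.steps:
        arc = g.arcs[aid]
        if arc.label is None:
            raise InvalidWalkError(f"breaking arc {aid!r} has no label to spell")
        out.append(arc.label if fwd else g.cmap.rc(arc.label))
    return out


def spell(g: BiGraph, walk: Walk) -> str:
    """Collapse a walk's label sequence, overlapping by k-1 characters.

    Emits the first label in full, then everything past the first k-1
    characters of each subsequent label.  On an uncompacted graph the
    output length is ``k - 1 + len(walk)``.
    """
    labels = walk_kmers(g, walk)
    if not labels:
        return ""
    parts = [labels[0]]
    for lab in labels[1:]:
        parts.append(lab[g.k - 1 :])
    return "".join(parts)


def walk_for_string(g: BiGraph, s: str) -> Walk:
    """A walk whose spelling is exactly ``s`` (uncompacted graphs).

    Each k-mer of ``s`` is mapped to its arc, traversed forward when the
    k-mer is canonical and in reverse otherwise.
    """
    if g.compacted:
        raise ValueError("walk_for_string requires an uncompacted graph")
    steps = []
    for kmer in kmer_sequence(s, g.k):
        can = canonical(kmer, g.cmap)
        if can not in g.arcs:
            raise KeyError(f"canonical k-mer {can!r} absent from graph")
        steps.append((can, kmer == can))
    walk = Walk(steps)
    _check_chain(g, walk)
    return walk


# -- compaction ---------------------------------------------------------


def _contractible(g: BiGraph, label: str) -> bool:
    node = g.nodes[label]
    arcs = g.incident_arcs(label)
    if node.self_complemental:
        return (
            len(arcs) == 2
            and all(a.incidence_multiplicity(label, DOT) == 1 for a in arcs)
        )
    if incidence_count(g, label, PLUS) != 1 or incidence_count(g, label, MINUS) != 1:
        return False
    # a (+,-) self-loop is one arc with both incidences; it cannot merge
    # with itself
    return len(arcs) == 2


def _extend(g: BiGraph, contractible: set[str], aid: str, fwd: bool,
            used: set[str]) -> list[tuple[str, bool]]:
    """Extend forward from an oriented arc through contractible nodes."""
    steps = [(aid, fwd)]
    used.add(aid)
    while True:
        arc = g.arcs[steps[-1][0]]
        _, (v, d) = arc.oriented(steps[-1][1])
        if v not in contractible:
            break
        want = negate(d)
        nxt = None
        for cand in g.incident_arcs(v):
            if cand.identifier in used:
                continue
            for forward in (True, False):
                entry, _ = cand.oriented(forward)
                if entry == (v, want):
                    nxt = (cand.identifier, forward)
                    break
            if nxt:
                break
        if nxt is None:
            break
        used.add(nxt[0])
        steps.append(nxt)
    return steps


def compact(g: BiGraph) -> BiGraph:
    """Contract all branch-free nodes, merging arc runs into unitig arcs.

    A node is contracted when it is self-complemental with exactly two
    arcs holding one incidence each, or normal with exactly one incoming
    and one outgoing arc.  Merged arc identifiers are the canonical
    spelled string of the merged walk.  A node-disjoint pure cycle keeps
    its lexicographically smallest node as an anchor so the cyclic unitig
    survives contraction.
    """
    contractible = {lab for lab in g.nodes if _contractible(g, lab)}
    # pure cycles: walk each contractible chain; if it closes on itself
    # without meeting a non-contractible node, pin the smallest label.
    unvisited = set(contractible)
    while unvisited:
        start = min(unvisited)
        chain = {start}
        frontier = [start]
        pure = True
        while frontier:
            v = frontier.pop()
            unvisited.discard(v)
            for arc in g.incident_arcs(v):
                for u in (arc.v1, arc.v2):
                    if u not in contractible:
                        pure = False
                    elif u not in chain:
                        chain.add(u)
                        frontier.append(u)
        if pure and chain:
            contractible.discard(min(chain))

    cg = BiGraph(g.k, g.cmap, compacted=True)
    used: set[str] = set()
    for aid in sorted(g.arcs):
        if aid in used:
            continue
        fwd_steps = _extend(g, contractible, aid, True, used)
        # re-extend backwards from the start through contractible nodes
        back = _extend(g, contractible, aid, False, used={aid})
        back_steps = [
            (a, not f) for a, f in reversed(back[1:])
        ]
        for a, _ in back_steps:
            used.add(a)
        steps = back_steps + fwd_steps
        walk = Walk(steps)
        label = spell(g, walk)
        label = min(label, g.cmap.rc(label))
        if label not in cg.arcs:
            cg.add_kmer_arc(label)
    return cg


# -- inspection ---------------------------------------------------------


def gfa_dump(g: BiGraph) -> str:
    """GFA1-style textual dump for inspection (not round-tripped).

    Nodes become S-lines labelled with their (k-1)-mer; arcs become
    L-lines with +/- orientations, with dot-sign incidences flagged in a
    ``ds`` tag.
    """
    lines = ["H\tVN:Z:1.0"]
    for label in sorted(g.nodes):
        node = g.nodes[label]
        tag = "\tsc:i:1" if node.self_complemental else ""
        lines.append(f"S\t{label}\t{label}{tag}")
    for aid in sorted(g.arcs):
        arc = g.arcs[aid]
        o1 = "+" if arc.d1 == PLUS else "-"
        o2 = "+" if arc.d2 == MINUS else "-"
        dot = []
        if arc.d1 == DOT:
            o1 = "+"
            dot.append("1")
        if arc.d2 == DOT:
            o2 = "+"
            dot.append("2")
        tag = f"\tds:Z:{','.join(dot)}" if dot else ""
        lines.append(
            f"L\t{arc.v1}\t{o1}\t{arc.v2}\t{o2}\t{g.k - 2}M\tid:Z:{aid}{tag}"
        )
    return "\n".join(lines) + "\n"
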