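"""Minimum SPSS without repetitions via bidirected Eulerisation.

The pipeline, per connected component of the de Bruijn graph:

1. *Eulerise*: insert unlabeled balancing ("breaking") arcs pairing up the
   unbalanced incidence needs, so every node reaches imbalance zero.
2. Compute a bidirected Eulerian cycle (Hierholzer with an in-place
   sub-cycle splice and a ``first_unfinished`` scan pointer).
3. Break the cycle at the breaking arcs and drop them.
4. Spell the resulting walks.

The number of walks equals ``max(1, imbalance(G) / 2)`` per component,
which is also the lower bound on the string count of any SPSS without
repetitions, so the spelled string set has minimum cumulative length:
``CL = sum over walks of (k - 1 + |W|)``.

Where the underlying algorithm says "arbitrary" (which unbalanced
incidences to pair, which arc to take next in the cycle search) this
module uses fixed deterministic conventions, documented next to the
``_PAIRING`` / ``_ARC_ORDER`` / ``_START_SIGNS`` constants below, so two
runs on the same input produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import DNA, ComplementMap, canonical_spectrum
from .graph import (
    BREAK_PREFIX,
    DOT,
    MINUS,
    PLUS,
    Arc,
    BiGraph,
    Walk,
    build_dbg,
    compact,
    connected_components,
    negate,
    node_imbalance,
    spell,
)

__all__ = [
    "SPSS",
    "EuleriseResult",
    "ValidationReport",
    "graph_imbalance",
    "lower_bound",
    "eulerise",
    "eulerian_cycle",
    "break_cycle",
    "compute_eulertigs",
    "compute_eulertigs_from_graph",
    "unitigs",
    "validate_spss",
]


# Deterministic conventions for the "arbitrary" choices of the algorithm,
# frozen so that two runs on the same input are byte-identical:
#   * the sorted list L of unbalanced incidence needs is paired into
#     breaking arcs consecutively (L[0]-L[1], L[2]-L[3], ...);
#   * the Eulerian cycle search starts at the lexicographically largest
#     node label, trying signs in the order '.', '+', '-';
#   * among the arcs satisfying the sign constraint, breaking arcs are
#     preferred in insertion order, then real arcs by identifier.
_PAIRING = "adjacent"
_BREAKS_FIRST = True
_ARC_ORDER = "id"
_START_RULE = "maxlabel"
_START_SIGNS = (DOT, PLUS, MINUS)


@dataclass
class SPSS:
    """A spectrum-preserving string set with its size metrics."""

    strings: list[str]
    k: int

    @property
    def cumulative_length(self) -> int:
        """CL: total character count over all strings."""
        return sum(len(s) for s in self.strings)

    @property
    def string_count(self) -> int:
        """SC: number of strings."""
        return len(self.strings)


@dataclass
class EuleriseResult:
    graph: BiGraph
    breaking_ids: list[str]


class NotEulerianError(ValueError):
    pass


class DisconnectedError(ValueError):
    pass


def graph_imbalance(g: BiGraph) -> int:
    """Sum of absolute node imbalances; always even."""
    return sum(abs(node_imbalance(g, v)) for v in g.nodes)


def lower_bound(g: BiGraph) -> int:
    """Minimum string count of any SPSS without repetitions of ``g``.

    Per connected component with at least one arc: ``max(1,
    imbalance(component) / 2)``.  The pipeline attains this bound.
    """
    total = 0
    for comp in connected_components(g):
        if comp.arc_count() == 0:
            continue
        total += max(1, graph_imbalance(comp) // 2)
    return total


def _copy_graph(g: BiGraph) -> BiGraph:
    out = BiGraph(g.k, g.cmap, compacted=g.compacted)
    out.nodes = dict(g.nodes)
    out.arcs = dict(g.arcs)
    out.adjacency = {v: list(inc) for v, inc in g.adjacency.items()}
    return out


def eulerise(g: BiGraph) -> EuleriseResult:
    """Balance every node by inserting breaking arcs; returns a new graph.

    Builds the list L of unbalanced incidence needs -- a normal node with
    imbalance +i contributes i entries needing a ``-`` (incoming)
    incidence, one with imbalance -i contributes i entries needing ``+``,
    and a self-complemental node of odd degree contributes one ``.``
    entry -- then pairs entries of L (sorted by node label) into breaking
    arcs until L is empty.  L always has even length because the graph
    imbalance is even.
    """
    needs: list[tuple[str, str]] = []
    for label in sorted(g.nodes):
        imb = node_imbalance(g, label)
        if imb == 0:
            continue
        if g.nodes[label].self_complemental:
            needs.append((label, DOT))
        elif imb > 0:
            needs.extend([(label, MINUS)] * imb)
        else:
            needs.extend([(label, PLUS)] * (-imb))
    assert len(needs) % 2 == 0, "graph imbalance must be even"

    if _PAIRING == "nested":
        pairs = [
            (needs[i], needs[len(needs) - 1 - i]) for i in range(len(needs) // 2)
        ]
    else:  # adjacent
        pairs = [(needs[i], needs[i + 1]) for i in range(0, len(needs), 2)]

    out = _copy_graph(g)
    breaking_ids: list[str] = []
    for n, ((v1, d1), (v2, d2)) in enumerate(pairs):
        aid = f"{BREAK_PREFIX}{n}"
        out.add_arc(Arc(aid, v1, d1, v2, d2, label=None))
        breaking_ids.append(aid)
    return EuleriseResult(graph=out, breaking_ids=breaking_ids)


class _Candidates:
    """Per-incidence sorted candidate lists for the cycle search.

    Every arc is listed under both of its traversal entries; a used arc
    is skipped via the shared ``used`` set.  Ranking: breaking arcs in
    insertion order before real arcs in identifier order (the frozen
    convention), so the search is deterministic.
    """

    def __init__(self, g: BiGraph):
        self.g = g
        self.used: set[str] = set()
        self.lists: dict[tuple[str, str], list[tuple[str, bool]]] = {}
        self.pos: dict[tuple[str, str], int] = {}
        for aid in g.arcs:
            arc = g.arcs[aid]
            for fwd in (True, False):
                entry, _ = arc.oriented(fwd)
                self.lists.setdefault(entry, []).append((aid, fwd))
        for key, lst in self.lists.items():
            lst.sort(key=lambda t: self._rank(t))
            self.pos[key] = 0

    def _rank(self, step: tuple[str, bool]) -> tuple:
        aid, fwd = step
        if aid.startswith(BREAK_PREFIX):
            group = 0 if _BREAKS_FIRST else 1
            return (group, int(aid[len(BREAK_PREFIX):]), not fwd)
        if _ARC_ORDER == "spell":
            arc = self.g.arcs[aid]
            label = arc.label if fwd else self.g.cmap.rc(arc.label)
            return (0 if not _BREAKS_FIRST else 1, label, not fwd)
        return (1 if _BREAKS_FIRST else 0, aid, not fwd)

    def take(self, node: str, sign: str) -> tuple[str, bool] | None:
        """Pop the best unused candidate entering at (node, sign)."""
        key = (node, sign)
        lst = self.lists.get(key)
        if lst is None:
            return None
        i = self.pos[key]
        while i < len(lst) and lst[i][0] in self.used:
            i += 1
        self.pos[key] = i
        if i == len(lst):
            return None
        aid, fwd = lst[i]
        self.used.add(aid)
        self.pos[key] = i + 1
        return (aid, fwd)

    def peek_available(self, node: str, sign: str) -> bool:
        key = (node, sign)
        lst = self.lists.get(key)
        if lst is None:
            return False
        i = self.pos[key]
        while i < len(lst) and lst[i][0] in self.used:
            i += 1
        self.pos[key] = i
        return i < len(lst)


def eulerian_cycle(g: BiGraph) -> Walk:
    """A cycle using every arc exactly once, in one orientation only.

    Requires a connected graph in which every node has imbalance zero;
    otherwise an error naming an offending node is raised.  Hierholzer's
    algorithm adapted to signs: a step arriving at a node with sign ``d``
    must be followed by an arc entering that node with ``negate(d)``.
    The iterative postorder formulation is used: arcs are pushed onto a
    path stack while an unused compatible continuation exists, and popped
    to the output when the path is stuck; the reversed output is the
    Eulerian cycle, with stuck sub-cycles ending up spliced in place.
    """
    for label in g.nodes:
        if node_imbalance(g, label) != 0:
            raise NotEulerianError(f"node {label!r} is unbalanced")
    if g.arc_count() == 0:
        return Walk([])
    if len(connected_components(g)) > 1:
        raise DisconnectedError("graph is not connected")

    if _START_RULE == "maxlabel":
        start = max(g.nodes)
    else:
        start = min(g.nodes)

    cand = _Candidates(g)
    first = None
    for sign in _START_SIGNS:
        first = cand.take(start, sign)
        if first is not None:
            break
    assert first is not None, "balanced node with arcs must offer a start"

    stack = [first]
    out: list[tuple[str, bool]] = []
    while stack:
        aid, fwd = stack[-1]
        _, (v, d) = g.arcs[aid].oriented(fwd)
        nxt = cand.take(v, negate(d))
        if nxt is not None:
            stack.append(nxt)
        else:
            out.append(stack.pop())

    if len(out) < g.arc_count():
        raise DisconnectedError(
            "arcs remain unreachable from the start node (graph disconnected?)"
        )
    walk = Walk(list(reversed(out)))
    from .graph import is_cycle

    assert is_cycle(g, walk), "Hierholzer produced a non-cycle"
    return walk


def break_cycle(cycle: Walk, breaking_ids: list[str]) -> list[Walk]:
    """Split a Eulerian cycle at its breaking arcs and drop them.

    With zero breaking arcs the cycle is linearised starting at the arc
    with the smallest identifier; with one, it is rotated so the breaking
    arc comes last and the breaking step dropped.  With ``b >= 2``
    breaking arcs the maximal runs of real arcs between them become
    exactly ``b`` walks.
    """
    steps = cycle.steps
    breaking = set(breaking_ids)
    positions = [i for i, (aid, _) in enumerate(steps) if aid in breaking]
    if not steps:
        return []
    if not positions:
        pivot = min(range(len(steps)), key=lambda i: steps[i][0])
        return [Walk(steps[pivot:] + steps[:pivot])]
    if len(positions) == 1:
        p = positions[0]
        return [Walk(steps[p + 1 :] + steps[:p])]
    walks: list[Walk] = []
    for a, b in zip(positions, positions[1:]):
        walks.append(Walk(steps[a + 1 : b]))
    walks.append(Walk(steps[positions[-1] + 1 :] + steps[: positions[0]]))
    for w in walks:
        assert w.steps, "empty run between breaking arcs contradicts minimality"
    return walks


def _canonical_string(s: str, cmap: ComplementMap) -> str:
    rc = cmap.rc(s)
    return rc if rc < s else s


def compute_eulertigs_from_graph(g: BiGraph) -> SPSS:
    """Run eulerise -> Eulerian cycle -> break -> spell per component.

    Components are processed in order of their smallest node label; each
    output string is emitted as the lexicographic minimum of itself and
    its reverse complement.
    """
    out: list[str] = []
    for comp in connected_components(g):
        if comp.arc_count() == 0:
            continue
        res = eulerise(comp)
        cycle = eulerian_cycle(res.graph)
        for walk in break_cycle(cycle, res.breaking_ids):
            out.append(_canonical_string(spell(comp, walk), g.cmap))
    return SPSS(strings=out, k=g.k)


def compute_eulertigs(
    strings: list[str],
    k: int,
    cmap: ComplementMap = DNA,
    compacted: bool = True,
) -> SPSS:
    """Minimum-cumulative-length SPSS without repetitions of the input.

    The output has the same canonical k-spectrum as the input, contains
    each canonical k-mer exactly once, and its string count equals the
    imbalance lower bound of the input's de Bruijn graph.  By default the
    pipeline runs on the compacted graph (contracting branch-free runs
    first); ``compacted=False`` runs it arc-per-k-mer instead, which can
    only change which of the equally minimal string sets is emitted, not
    the metrics.
    """
    g = build_dbg(strings, k, cmap)
    if compacted:
        g = compact(g)
    return compute_eulertigs_from_graph(g)


def unitigs(strings: list[str], k: int, cmap: ComplementMap = DNA) -> SPSS:
    """The maximal branch-free strings (unitigs) of the input's graph."""
    g = compact(build_dbg(strings, k, cmap))
    return SPSS(strings=sorted(g.arcs), k=k)


@dataclass
class ValidationReport:
    """Outcome of checking a claimed SPSS against an input string set."""

    spectrum_equal: bool
    no_repetitions: bool
    minimal: bool
    missing_kmers: list[str] = field(default_factory=list)
    extra_kmers: list[str] = field(default_factory=list)
    repeated_kmers: list[str] = field(default_factory=list)
    expected_string_count: int = 0
    string_count: int = 0

    @property
    def valid(self) -> bool:
        """Spectrum preserved and repetition-free (minimality reported
        separately: a valid-but-suboptimal SPSS is still an SPSS)."""
        return self.spectrum_equal and self.no_repetitions

    @property
    def all_passed(self) -> bool:
        return self.valid and self.minimal


def validate_spss(
    input_strings: list[str],
    spss: SPSS,
    k: int,
    cmap: ComplementMap = DNA,
) -> ValidationReport:
    """Check spectrum equality, per-k-mer uniqueness, and minimality.

    Failures are reported, never raised.
    """
    from collections import Counter

    from .dna import canonical, clean_fragments, kmer_sequence

    want = canonical_spectrum(input_strings, k, cmap).kmers
    counts: Counter[str] = Counter()
    for frag in clean_fragments(spss.strings, k, cmap):
        for kmer in kmer_sequence(frag, k):
            counts[canonical(kmer, cmap)] += 1
    have = frozenset(counts)
    repeated = sorted(km for km, c in counts.items() if c > 1)
    expected_sc = lower_bound(build_dbg(input_strings, k, cmap))
    return ValidationReport(
        spectrum_equal=have == want,
        no_repetitions=not repeated,
        minimal=spss.string_count == expected_sc,
        missing_kmers=sorted(want - have),
        extra_kmers=sorted(have - want),
        repeated_kmers=repeated,
        expected_string_count=expected_sc,
        string_count=spss.string_count,
    )
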