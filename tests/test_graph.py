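import random

import pytest

from eulertigs import (
    build_dbg,
    compact,
    connected_components,
    gfa_dump,
    incidence_count,
    node_imbalance,
    reverse_complement,
    spell,
    walk_for_string,
    walk_kmers,
)
from eulertigs.graph import DOT, MINUS, PLUS, InvalidWalkError, Walk, _check_chain
from conftest import FIG1_STRINGS, random_dna


def test_worked_example_topology(fig1_graph):
    g = fig1_graph
    assert set(g.arcs) == {"GAA", "AAT", "ATG", "ATC", "AGA", "CAG", "GCA", "AGC"}
    assert set(g.nodes) == {"GA", "AA", "AT", "CA", "AG", "GC"}
    selfc = {v for v, n in g.nodes.items() if n.self_complemental}
    assert selfc == {"AT", "GC"}
    gaa = g.arcs["GAA"]
    assert (gaa.v1, gaa.d1, gaa.v2, gaa.d2) == ("GA", PLUS, "AA", MINUS)
    aat = g.arcs["AAT"]
    assert (aat.v1, aat.d1, aat.v2, aat.d2) == ("AA", PLUS, "AT", DOT)


def test_single_repeated_kmer_becomes_self_loop():
    g = build_dbg(["AAAA"], 3)
    assert set(g.nodes) == {"AA"} and set(g.arcs) == {"AAA"}
    arc = g.arcs["AAA"]
    assert {arc.d1, arc.d2} == {PLUS, MINUS} and arc.v1 == arc.v2 == "AA"
    assert node_imbalance(g, "AA") == 0


def test_self_complemental_kmer_even_k():
    # ACGT equals its reverse complement; both (k-1)-mer endpoints
    # canonicalise to the same node, giving a (+,+) self-loop.
    g = build_dbg(["ACGT"], 4)
    assert set(g.arcs) == {"ACGT"}
    arc = g.arcs["ACGT"]
    assert arc.v1 == arc.v2 == "ACG"
    assert arc.d1 == arc.d2 == PLUS
    assert incidence_count(g, "ACG", PLUS) == 2
    assert incidence_count(g, "ACG", MINUS) == 0


def test_incidence_counts_and_imbalance(fig1_graph):
    g = fig1_graph
    # GA has two outgoing arcs (GAA, ATC's reverse-complement end) and one
    # incoming (AGA)
    assert incidence_count(g, "GA", PLUS) == 2
    assert incidence_count(g, "GA", MINUS) == 1
    assert node_imbalance(g, "GA") == 1
    # AA sits inside a branch-free run
    assert (incidence_count(g, "AA", PLUS), incidence_count(g, "AA", MINUS)) == (1, 1)
    assert node_imbalance(g, "AA") == 0
    # a self-complemental node with three dot incidences has odd degree
    assert incidence_count(g, "AT", DOT) == 3
    assert node_imbalance(g, "AT") == 1
    # dot count on a normal node is zero, not an error
    assert incidence_count(g, "GA", DOT) == 0


def test_incidence_slots_sum_to_twice_the_arcs(fig1_graph):
    g = fig1_graph
    total = sum(
        incidence_count(g, v, sign)
        for v in g.nodes
        for sign in (PLUS, MINUS, DOT)
    )
    assert total == 2 * len(g.arcs)


def test_construction_is_strand_invariant(fig1_graph):
    g = fig1_graph
    h = build_dbg([reverse_complement(s) for s in FIG1_STRINGS], 3)
    assert set(g.nodes) == set(h.nodes)
    assert set(g.arcs) == set(h.arcs)
    for aid in g.arcs:
        a, b = g.arcs[aid], h.arcs[aid]
        assert (a.v1, a.d1, a.v2, a.d2) == (b.v1, b.d1, b.v2, b.d2)


def _overlap_equivalences_hold(g, e1, e2):
    """The four (k-1)-overlap equivalences defining arc adjacency."""
    k = g.k
    rc = g.cmap.rc
    h1, h2 = e1.label, e2.label
    cases = [
        (
            e1.v2 == e2.v1 and e1.d2 == {"+": "-", "-": "+", ".": "."}[e2.d1],
            h1[-(k - 1):] == h2[: k - 1],
        ),
        (
            e1.v2 == e2.v2 and e1.d2 == {"+": "-", "-": "+", ".": "."}[e2.d2],
            h1[-(k - 1):] == rc(h2)[: k - 1],
        ),
        (
            e1.v1 == e2.v1 and e1.d1 == {"+": "-", "-": "+", ".": "."}[e2.d1],
            rc(h1)[-(k - 1):] == h2[: k - 1],
        ),
        (
            e1.v1 == e2.v2 and e1.d1 == {"+": "-", "-": "+", ".": "."}[e2.d2],
            rc(h1)[-(k - 1):] == rc(h2)[: k - 1],
        ),
    ]
    return all(lhs == rhs for lhs, rhs in cases)


def test_overlap_equivalences_on_random_graphs():
    rng = random.Random(42)
    for _ in range(60):
        k = rng.choice([3, 4, 5])
        g = build_dbg([random_dna(rng, rng.randint(k, k + 12))], k)
        arcs = list(g.arcs.values())
        for e1 in arcs:
            for e2 in arcs:
                assert _overlap_equivalences_hold(g, e1, e2), (k, e1, e2)


def test_spell_single_arc_both_orientations(fig1_graph):
    g = fig1_graph
    assert spell(g, Walk([("ATC", True)])) == "ATC"
    assert spell(g, Walk([("ATC", False)])) == "GAT"
    assert walk_kmers(g, Walk([("ATC", False)])) == ["GAT"]
    assert walk_kmers(g, Walk([])) == []


def test_walks_spell_the_construction_strings(fig1_graph):
    # the graph contains the strings it was built from, on both strands
    g = fig1_graph
    for s in FIG1_STRINGS:
        assert spell(g, walk_for_string(g, s)) == s
        rc = reverse_complement(s)
        assert spell(g, walk_for_string(g, rc)) == rc


def test_walk_for_string_rejects_foreign_kmers(fig1_graph):
    with pytest.raises(KeyError, match="CCC"):
        walk_for_string(fig1_graph, "CCCC")


def test_invalid_walk_chaining_is_rejected(fig1_graph):
    with pytest.raises(InvalidWalkError, match="step 1"):
        spell(fig1_graph, Walk([("GAA", True), ("ATC", True)]))


def test_spell_length_and_kmer_roundtrip():
    rng = random.Random(7)
    for _ in range(50):
        k = rng.choice([3, 4, 5])
        s = random_dna(rng, rng.randint(k, k + 20))
        g = build_dbg([s], k)
        w = walk_for_string(g, s)
        out = spell(g, w)
        assert len(out) == (k - 1) + len(w)
        # re-extracting k-mers from the spelled string reproduces the
        # walk's k-mer sequence
        kmers = walk_kmers(g, w)
        assert [out[i : i + k] for i in range(len(out) - k + 1)] == kmers


def test_connected_components(fig1_graph):
    assert len(connected_components(fig1_graph)) == 1
    g = build_dbg(["AAAA", "CCCC"], 3)
    comps = connected_components(g)
    assert len(comps) == 2
    assert [sorted(c.arcs) for c in comps] == [["AAA"], ["CCC"]]
    assert connected_components(build_dbg([], 3)) == []


def test_compaction_contracts_branch_free_runs():
    # a simple path of 3 arcs with 1-in/1-out internal nodes becomes one arc
    g = build_dbg(["ATCGGA"], 4)
    cg = compact(g)
    assert list(cg.arcs) == [min("ATCGGA", reverse_complement("ATCGGA"))]


def test_compaction_of_pure_cycle_keeps_anchor():
    g = build_dbg(["GTGCCGTG"], 4)  # 5 arcs forming a node-disjoint cycle
    assert all(node_imbalance(g, v) == 0 for v in g.nodes)
    cg = compact(g)
    assert len(cg.arcs) == 1
    (label,) = cg.arcs
    arc = cg.arcs[label]
    assert arc.v1 == arc.v2  # the cyclic unitig anchors at one node
    assert len(label) == 8


def test_compaction_preserves_structure():
    rng = random.Random(11)
    from eulertigs import canonical_spectrum, graph_imbalance

    for _ in range(40):
        k = rng.choice([3, 4, 5])
        strings = [random_dna(rng, rng.randint(k, k + 25)) for _ in range(2)]
        g = build_dbg(strings, k)
        cg = compact(g)
        assert graph_imbalance(g) == graph_imbalance(cg)
        assert len(connected_components(g)) == len(connected_components(cg))
        assert canonical_spectrum(list(cg.arcs), k) == canonical_spectrum(
            strings, k
        )


def test_gfa_dump_shape(fig1_graph):
    text = gfa_dump(fig1_graph)
    lines = text.strip().split("\n")
    assert lines[0].startswith("H\t")
    assert sum(1 for ln in lines if ln.startswith("S\t")) == 6
    assert sum(1 for ln in lines if ln.startswith("L\t")) == 8
    assert "ds:Z:" in text  # dot-sign incidences are flagged


def test_check_chain_accepts_built_walks(fig1_graph):
    w = walk_for_string(fig1_graph, "ATCTGCT")
    _check_chain(fig1_graph, w)  # must not raise
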