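# Methods

## Model

Throughout, a k-mer is identified with its reverse complement; the
canonical form is the lexicographically smaller of the two, and a k-mer
equal to its own reverse complement is *self-complemental* (possible
only for even k). The canonical k-spectrum `CS_k(I)` of a string set is
the set of canonical forms of all length-k substrings. A
spectrum-preserving string set (SPSS) of `I` is any string set with the
same canonical spectrum; "without repetitions" means every canonical
k-mer occurs exactly once across the output.

The de Bruijn graph is arc-centric and bidirected: one node per
canonical (k−1)-mer, one arc per canonical k-mer, regardless of how
often the k-mer occurs. The endpoint signs encode strandedness:

* start node `v = canonical(pre_{k-1}(h))` for arc label `h`: `+` when
  the prefix occurs canonically, `-` when reverse-complemented;
* end node `v' = canonical(suf_{k-1}(h))`: `-` when the suffix occurs
  canonically, `+` otherwise;
* `·` at a self-complemental node, where strand is meaningless.

A walk leaves a node with the negation of its arrival sign. Under this
convention two arcs chain at a shared node precisely when the
corresponding (k−1)-overlap of their labels matches, possibly through
the reverse complement — all four orientation cases. This equivalence
is the normative contract of the construction and is property-tested on
random graphs (`tests/test_graph.py`); it guarantees that walks spell
exactly the strings composable from the graph's k-mers, so an SPSS
without repetitions is the same thing as a unique walk cover.

Construction is hash-based (canonical k-mer → arc, canonical (k−1)-mer
→ node), costing O(total input length × k) rather than the
suffix-tree-based O(total length × log |Σ|) that is theoretically
possible; at the scale this package targets the simple constructor is
the right trade-off, and every downstream step is linear in the graph.

## The minimum SPSS pipeline

Per connected component (components are processed in order of their
smallest node label):

1. **Eulerise.** Every node's imbalance is computed: out-degree minus
   in-degree for normal nodes; degree parity (1 if odd) for
   self-complemental nodes. The graph imbalance (sum of absolute node
   imbalances) is always even. Unbalanced incidence *needs* are listed
   sorted by node label — a node with imbalance +i needs i incoming
   (`-`) slots, −i needs i outgoing (`+`) slots, an odd self-complemental
   node needs one `·` slot — and consecutive entries are paired into
   unlabeled *breaking arcs*. Pairing two needs of the same node yields
   a self-loop whose incidence counts twice, which removes two units of
   imbalance; no special case is required.
2. **Eulerian cycle.** Hierholzer's algorithm in its iterative
   postorder form: arcs are pushed onto a path stack while an unused
   continuation with the required sign exists, and popped to the output
   when the path is stuck; the reversed output is the cycle. Balance
   guarantees the path can only get stuck at its origin, and stuck
   sub-cycles end up spliced in place.
3. **Break.** The cycle is cut at every breaking arc and the breaking
   steps discarded. With b ≥ 2 breaking arcs this yields exactly b
   walks (an empty run between two breaking arcs would contradict the
   lower bound); with one, the cycle is rotated so the breaking arc is
   last and dropped; with zero, the cycle is linearised starting at the
   smallest arc identifier.
4. **Spell.** Each walk emits its first label (or reverse complement,
   per traversal direction) in full, then the part of each subsequent
   label past the (k−1)-character overlap. Each output string is
   emitted as min(s, rc(s)).

A walk of length |W| spells k − 1 + |W| characters, so the cumulative
length is `Σ_walks (k − 1 + |W|)`; the arc total is fixed by the
spectrum, hence minimising CL is minimising the walk count, and the
walk count achieved — `max(1, imbalance/2)` per component — matches the
imbalance lower bound. Optimality is additionally certified against an
exhaustive oracle (below).

By default the pipeline runs on the **compacted** graph: nodes that are
either normal with exactly one incoming and one outgoing arc (two
distinct arcs), or self-complemental with exactly two arcs of one
incidence each, are contracted, and merged arcs take the spelled unitig
as identifier. A node-disjoint pure cycle keeps its smallest node label
as an anchor so the cyclic unitig survives. Compaction changes neither
imbalance, component count, nor spectrum, so the result metrics are
identical to the arc-per-k-mer pipeline (tested); only which of the
equally minimal string sets is emitted can differ. `compacted=False`
selects the plain pipeline.

## Deterministic conventions

The algorithm leaves several choices arbitrary. They are frozen so that
two runs are byte-identical:

* needs are paired consecutively in sorted order;
* the cycle search starts at the lexicographically largest node label,
  trying signs `·`, `+`, `-`;
* among sign-compatible continuations, breaking arcs are preferred in
  insertion order, then real arcs by identifier;
* output strings are canonicalised per string and concatenated across
  components in component order.

This particular combination also reproduces the published worked
example of the algorithm verbatim, which the test suite pins.

## Greedy baselines

`greedy_forward_spss` starts at the next unused arc (a caller-supplied
start order, then identifier order), extends forward while an unused
sign-compatible successor exists (smallest identifier first), and then
applies the join rule: a walk whose final arc has a successor that is
the first arc of another walk absorbs that walk. Joins are
reverse-complement-aware — either participant may be flipped — because
walks are strand-symmetric objects; without this a walk started
mid-unitig in reverse orientation could never rejoin and the unitig
upper bound would fail. `greedy_bidirectional_spss` extends forward to
exhaustion, then backward, with no join pass. Both always produce valid
SPSSs without repetitions satisfying
`CL(eulertigs) ≤ CL(greedy) ≤ CL(unitigs)`; the tie-breaking details
are conventions sufficient to reproduce the published 17-versus-14
adversarial example, not claims about the original tools' exact
behaviour.

## Oracle

`min_unique_walk_cover` is an exhaustive dynamic program over
(bitmask of covered arcs, incidence at which the current walk ends),
independent of the Eulerisation machinery; it is capped at 8 arcs
(2⁸ × incidences states). A second, literal oracle — every permutation
and orientation vector, split greedily into maximal walks — cross-checks
the DP on ≤ 5 arcs. Acceptance sweeps certify that the pipeline's
string count equals the oracle's minimum on ≥ 500 random instances.

## Input handling

FASTA input (plain or gzipped, via Biopython) is uppercased; records
are split at every non-ACGT character into maximal valid fragments and
fragments shorter than k are dropped with a logged warning, matching
common k-mer-tool behaviour. The complement map is configurable but
must be an involution, validated at construction. An optional
`min_abundance` filter keeps only canonical k-mers whose pooled count
(k-mer and reverse complement together, across all fragments) reaches
the threshold; this per-canonical-form convention is one of several
possible abundance semantics and is noted here as a package choice.

## Synthetic data

`generate_random_genomes(n_strings, length, mutation_rate, seed)` draws
one uniform-random reference and n−1 point-substituted replicates,
emulating the redundancy of a small pangenome: shared k-mers collapse
in the spectrum while mutations create bubbles and branch nodes.
Defaults (2 strings, length 200, substitution rate 0.02) give graphs
with a realistic mix of long unitigs and branching. What the generator
does not emulate: sequencing errors and coverage (no read model),
repeats beyond what uniform sequence produces, indels, and genome-scale
k-mer counts. Passing tests therefore demonstrate correctness of the
combinatorics on graphs with the right local structure, not performance
or robustness at pangenome scale.

## Test problem sizes and numerics

Seeded sweeps use 500–1000 random instances of 1–3 strings of length up
to k + 50 with k ∈ {3, 4, 5, 6, 31} — even k included deliberately, as
it is the only case producing self-complemental nodes and k-mers. These
sizes keep the whole suite in a few seconds while covering every corner
case class; all arithmetic is exact (integer/string), so there are no
tolerances. Degenerate inputs: an empty input or one with no fragment
of length ≥ k yields an empty SPSS; a single repeated k-mer yields a
self-loop handled by the same rules as every other arc.

## Known limitations

* Quadratic-ish constant factors of pure Python make multi-megabase
  inputs slow; the construction is O(||I||·k), not O(||I||·log|Σ|).
* Repetition-allowing minimum SPSSs (joining walks by repeating up to
  k−1 k-mers, solved via matching) are out of scope.
* The GFA dump is for inspection only and is not round-tripped.
* Abundance filtering is a plain count threshold; no quality-aware
  counting.
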