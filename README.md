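# eulertigs

Minimum plain-text representations of DNA k-mer sets, without k-mer
repetitions, in time linear in the size of the graph.

## The problem

Many genomics pipelines reduce their input sequences to the set of
constituent *k*-mers, where a *k*-mer is considered equal to its reverse
complement. A *spectrum-preserving string set* (SPSS, also known as
simplitigs) stores such a set as plain strings: a set of strings `I'` is
an SPSS of an input `I` when their canonical *k*-spectra agree,
`CS_k(I) = CS_k(I')`. The smaller the cumulative length
`CL = Σ_{s ∈ I'} |s|`, the cheaper the representation is to store, load
and index — provided each canonical *k*-mer still occurs exactly once.

Greedy tools (ProphAsm-style bidirectional extension, UST-style forward
extension) produce near-minimum SPSSs but can be provably suboptimal.
This package computes the exact minimum.

## The algorithm

The input is modelled as a bidirected arc-centric de Bruijn graph: nodes
are canonical (*k*−1)-mers, arcs are canonical *k*-mers, and each arc
endpoint carries a sign (`+` outgoing, `-` incoming, `·` at nodes equal
to their own reverse complement). A walk must leave a node with the sign
opposite to the one it entered with, so walks spell exactly the strings
composable from the graph's *k*-mers. An SPSS without repetitions is
then a *unique walk cover* — every arc traversed exactly once, in one
orientation — and since each walk of length `|W|` spells `k − 1 + |W|`
characters, minimising CL means minimising the number of walks.

Define `imbalance(v) = δ⁺(v) − δ⁻(v)` for a normal node and, for a
self-complemental node, 1 if its degree is odd and 0 otherwise. No walk
cover of a connected graph can use fewer than
`max(1, Σ_v |imbalance(v)| / 2)` walks, and the bound is attained
constructively:

1. **Eulerise** — insert unlabeled *breaking arcs* pairing up the
   unbalanced incidences until every node is balanced;
2. compute a bidirected **Eulerian cycle** (Hierholzer's algorithm with
   sign-aware continuation);
3. **break** the cycle at the breaking arcs and discard them;
4. **spell** the resulting walks.

The output — the *eulertigs* of the input — is a provably
minimum-cumulative-length SPSS without repetitions. The package also
ships the two greedy baselines, unitig computation, the imbalance lower
bound, a validator, and an exhaustive walk-cover oracle so that
optimality is testable end to end.

## Worked example

The two strings `GAATG` and `ATCTGCT` share 8 canonical 3-mers:

```python
>>> from eulertigs import compute_eulertigs, build_dbg, graph_imbalance, lower_bound
>>> spss = compute_eulertigs(["GAATG", "ATCTGCT"], k=3)
>>> spss.strings, spss.cumulative_length, spss.string_count
(['AGAATGCTG', 'ATC'], 12, 2)
>>> g = build_dbg(["GAATG", "ATCTGCT"], 3)
>>> graph_imbalance(g), lower_bound(g)
(4, 2)
```

The graph has total imbalance 4, so no repetition-free SPSS can use
fewer than 4/2 = 2 strings; the pipeline emits exactly two, of total
length 12, each canonical 3-mer spelled exactly once. Each output
string is reported as the lexicographic minimum of itself and its
reverse complement.

Greedy heuristics can be forced into a worse answer. On the single
string `AGGTGCCGTGGGAT` (k = 4) the optimum is that one string of
length 14, but a forward-greedy run that starts at `AGGT` and takes the
`GTGG` branch at node `GTG` strands the 5-cycle
`GTGC→TGCC→GCCG→CCGT→CGTG` and pays for a second string:

```python
>>> from eulertigs import greedy_forward_spss
>>> g = build_dbg(["AGGTGCCGTGGGAT"], 4)
>>> bad = greedy_forward_spss(g, start_order=["AGGT"])
>>> bad.strings, bad.cumulative_length
(['AGGTGGGAT', 'ACGGCACG'], 17)
```

The same operations are available from the shell:

```
eulertigs compute -k 3 -i input.fa -o out.fa --json-report report.json
eulertigs validate -k 3 -i input.fa -s out.fa --require-minimal
eulertigs lower-bound -k 4 -i input.fa
eulertigs simulate -o sim.fa --n-strings 2 --length 200 --mutation-rate 0.02 --seed 1
```

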