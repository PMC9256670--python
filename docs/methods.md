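# Methods

## Problem and model

A connectome is represented as a directed simple graph G(V, E): one vertex
per neuron (or muscle / end-organ), one edge per ordered pair of cells with
at least one synaptic connection. Each edge carries a categorical *color*
drawn from a small palette — connection type (`chemical`, `electrical`,
`both`) or strength class (`moderate`, `strong`) — plus a nonnegative weight
holding the synapse count. Vertices may carry colors too (cell types).
Self-loops are stored; multi-edges are collapsed at load.

A *motif* of order k is an isomorphism class of connected induced
k-subgraphs: two subgraphs belong to the same class exactly when a vertex
bijection preserves every edge (and, in colored mode, every edge color and
vertex color). The *census* is the exact count of connected induced
k-subgraphs per class.

## Canonical labeling

Class identity is the canonical label: encode the k×k color-code adjacency
matrix row-major as a string over `0-9A-Z` (0 = no edge), and take the
lexicographic minimum over all k! simultaneous row/column permutations. With
vertex colors, the pair (vertex-color block, matrix block) is minimized
jointly, vertex block first; colors travel with the vertices, which is
equivalent to restricting to color-preserving bijections. Diagonal entries
(self-loops) participate in the string.

Minimization is exhaustive rather than delegated to an isomorphism engine:
at the orders enumerated here (k ≤ 8, i.e. at most 40,320 permutations, and
in practice k ≤ 5) a direct scan is fast, exactly deterministic, and
supports edge colors natively with no layered-graph encoding. A memoization
cache keyed on the raw (vertex colors, matrix) input makes repeated
isomorphic subgraphs — the overwhelmingly common case during enumeration —
pay the factorial scan once; the cache is capacity-bounded (2^20 entries)
and never changes results. Tests cross-check labels against an independent
VF2 engine (python-igraph) and against explicit bijection search.

Convention choices left open by the problem: the matrix string is row-major,
and comparison order is vertex block before matrix block; both are fixed and
recorded in census-file headers via the label format itself.

## Enumeration

Enumeration is rooted with min-index pruning. For each root v, the search
yields every connected induced k-set whose minimum-index member is v:
candidate vertices are the unvisited in-or-out neighbors of the previous
tree level with index above the root, and each level claims between 1 and
the remaining budget of them, so the level sizes traverse every composition
of k−1. Because every k-set has a unique minimum-index member, the union
over roots covers each subgraph exactly once — which also makes per-root
work embarrassingly parallel with no deduplication.

Connectivity means *weak* connectivity of the directed induced subgraph.
Subgraphs are induced: every edge among the chosen vertices enters the
label. Self-loops never contribute to connectivity or neighborhoods but do
appear on the label diagonal by default; `ignore_self_loops` drops them from
labels entirely, and the choice is recorded in census metadata.

Counts are plain Python integers (arbitrary precision), and only the
label → count map is kept, never the subgraphs themselves, so memory is
O(#classes). The independent oracle, `brute_force_census`, scans all C(n, k)
subsets and filters by connectivity; the two paths are compared
label-for-label on dozens of seeded random digraphs in the test suite.

## Load balancing

With arbitrary vertex ids a few low-index hubs dominate rooted-enumeration
time, because a root's work grows like C(h, k−1) in the number h of its
neighbors with *larger* enumeration index. The enumeration ordering is
therefore reassigned greedily: repeatedly give the next index (from 0) to
the unassigned vertex with the smallest residual degree — ties broken by
smallest original id — and decrement the residual degrees of its unassigned
neighbors. Degree counts distinct neighbors, ignoring direction,
multiplicity, and self-loops. Hubs end up with high indices, where pruning
shields them.

The per-root cost model is C(h, k−1) + 1: the binomial is a proven lower
bound on the rooted yield (the immediate neighborhood alone contains that
many sets), first-order only since wider neighborhoods correlate poorly with
yield; the +1 keeps zero-yield roots at positive cost and is this package's
own offset. Roots are packed into batches by longest-processing-time-first
greedy (deterministic, 4/3-approximate). Censuses are invariant under any
ordering and any batching — asserted label-for-label and byte-for-byte in
tests — so the ordering affects only balance. Wall-time and idle-time
statistics are logged as information only; they are hardware-dependent and
never asserted.

## Community divide-and-conquer

For graphs too dense to enumerate whole, vertices are first split into c
roughly equal communities and each community's induced subgraph is
enumerated in isolation; cross-community edges are dropped entirely. The
merged census therefore undercounts the full census by exactly the subgraphs
spanning communities: per-label merged ≤ full, with equality iff no
connected k-set crosses a boundary (c = 1 reproduces the full census
identically). The reported `spanning_loss` is the difference of totals when
a full census is available.

Partitioning runs on the undirected unit-weight projection. The built-in
`greedy-balanced` method grows BFS regions of size at most ⌈n/c⌉ from
highest-degree seeds, reserving one vertex per remaining community so no
community is empty; it is deterministic and dependency-free. A `metis`
method delegates to a multilevel partitioner backend when one is importable
and otherwise raises with a pointer to the fallback. Manual partitions
(e.g. anatomical brain regions) are accepted from vertex-name → region
labels, with community ids following sorted region names and balance checked
only as a warning.

## Census comparison

Censuses are compared as vectors indexed by canonical label, aligned on the
*union* of labels (absent labels count zero — intersection alignment would
inflate similarity). Cosine similarity is computed on raw counts; it is
scale-invariant, so raw counts and relative frequencies give identical
values, and the pairwise matrix reports the off-diagonal minimum as the
headline statistic. Top-N reports order classes by descending count with
ties broken by ascending label string, a total order stable across runs.

## Synthetic fixtures

All building and testing runs on generated graphs; nothing is downloaded.
Closed-form families (directed path, out-star, directed cycle, complete
bidirectional graph) have known censuses — n−k+1, C(n−1, k−1), n, and
C(n, k) subgraphs respectively, each in a single class — and anchor
exactness tests. Random families: Erdős–Rényi digraphs with independent
ordered pairs, optional uniform edge colors and per-vertex self-loop
probability; planted complete bidirectional cliques in an Erdős–Rényi
background; a two-block model with dense intra- and sparse inter-block
edges; and a directed preferential-attachment family whose heavy-tailed
degrees exercise the load balancer. All randomness flows through a seeded
PCG64 generator whose stream is platform-independent, so a spec identifies
a graph byte-for-byte.

These fixtures deliberately do not reproduce real connectome features —
spatial structure, reciprocity excess, degree-correlated wiring, neuron
classes — so passing tests demonstrate algorithmic correctness (exact
counts, invariances, balance direction), not biological conclusions.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale: oracle
comparisons use n ≤ 12 and k ≤ 5 (brute force is C(n, k)); invariance and
community checks use n = 40–300 with k = 3; load-balance checks use a
2000-vertex preferential-attachment graph scored by the cost model rather
than timed. Counts are exact integers throughout, so there are no numerical
tolerances in the census path; cosine similarities are ordinary float64.
Degenerate inputs are defined: empty graphs yield empty censuses, k = 1
counts vertices by color class, a census of an edgeless graph is empty, and
all-zero censuses refuse similarity comparison.

## Known limitations

- Pure-Python enumeration: throughput is orders of magnitude below a C++
  implementation; trillion-subgraph runs are out of scope. The batch
  files + merge contract is the integration point for cluster execution.
- Exhaustive permutation minimization caps the motif order at k = 8.
- The greedy-balanced partitioner heuristically reduces, not minimizes, cut
  edges; community censuses are partition-dependent, and only direction
  (dominance, monotone loss) is asserted.
- Whether published connectome censuses treat self-loop colors as label
  features is unknowable from counts alone; the default (keep) is recorded
  in census metadata rather than asserted as the field's convention.
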