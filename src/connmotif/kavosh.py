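"""Exact enumeration of connected induced k-subgraphs (Kavosh-style).

The search is rooted: for each vertex v in increasing index order, every
connected induced subgraph of size k whose minimum-index member is v is
generated exactly once.  Pruning follows from the root-partition argument —
any neighbor with an index below the root is ignored, since the subgraph
containing it will be found from its own, smaller, root.  Within a root the
search grows a tree level by level: each level claims some vertices from the
frontier of unvisited higher-index neighbors of the previous level, so the
level sizes traverse every composition of k-1.

Subgraphs are never stored individually; each one is canonical-labeled on
the fly and the census keeps only exact integer counts per label, so memory
is proportional to the number of distinct motif classes, not the number of
subgraphs (Python integers make the counts exact at any magnitude).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np

from connmotif.canonical import CanonicalLabel, canonical_label
from connmotif.errors import BudgetError, MergeError, SizeError
from connmotif.graph_model import ConnectomeGraph

DEFAULT_BRUTE_FORCE_BUDGET = 5_000_000


@dataclass(frozen=True)
class Composition:
    """Ordered parts summing to k-1: how many vertices each tree level claims."""

    parts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.parts or any(p < 1 for p in self.parts):
            raise ValueError(f"composition parts must be positive, got {self.parts}")

    @property
    def total(self) -> int:
        return sum(self.parts)


def compositions(m: int) -> list[Composition]:
    """All 2^(m-1) ordered compositions of m, in separator order, each once."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    out = []
    # each of the m-1 gaps between units is either a separator or not
    for mask in range(1 << (m - 1)):
        parts = []
        run = 1
        for gap in range(m - 1):
            if mask >> gap & 1:
                parts.append(run)
                run = 1
            else:
                run += 1
        parts.append(run)
        out.append(Composition(tuple(parts)))
    return out


@dataclass
class MotifCensus:
    """Exact per-motif-class counts for one motif order k.

    Counts are arbitrary-precision integers; censuses with matching k,
    colored flag, and palette merge by per-label addition.
    """

    k: int
    colored: bool
    counts: dict[CanonicalLabel, int] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, label: CanonicalLabel, count: int = 1) -> None:
        self.counts[label] = self.counts.get(label, 0) + count

    def copy(self) -> "MotifCensus":
        return MotifCensus(self.k, self.colored, dict(self.counts), dict(self.metadata))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifCensus):
            return NotImplemented
        return self.k == other.k and self.colored == other.colored and self.counts == other.counts

    def items_sorted(self) -> list[tuple[CanonicalLabel, int]]:
        return sorted(self.counts.items(), key=lambda kv: kv[0].text)


def enumerate_rooted(
    g: ConnectomeGraph,
    root: int,
    k: int,
    _nbrs: Sequence[set[int]] | None = None,
) -> Iterator[tuple[int, ...]]:
    """Yield every connected induced k-set whose minimum index is ``root``.

    The graph's vertex ids serve as enumeration indices.  Neighborhoods are
    the union of in- and out-neighbors (self-loops excluded).  Each set is
    yielded exactly once, as an (unsorted) tuple containing the root.
    """
    if not 0 <= root < g.n:
        raise IndexError(f"root {root} outside 0..{g.n - 1}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        yield (root,)
        return
    nbrs = g.neighbors() if _nbrs is None else _nbrs
    visited = bytearray(g.n)
    visited[root] = 1
    selection = [root]

    def levels(frontier: Sequence[int], remainder: int) -> Iterator[tuple[int, ...]]:
        # valid children of this level: unvisited neighbors above the root;
        # they stay marked while the level's subsets are explored so deeper
        # levels cannot re-claim them, and are released afterwards
        children: list[int] = []
        for u in frontier:
            for w in nbrs[u]:
                if w > root and not visited[w]:
                    visited[w] = 1
                    children.append(w)
        children.sort()
        for take in range(1, min(len(children), remainder) + 1):
            for chosen in itertools.combinations(children, take):
                selection.extend(chosen)
                if remainder == take:
                    yield tuple(selection)
                else:
                    yield from levels(chosen, remainder - take)
                del selection[-take:]
        for w in children:
            visited[w] = 0

    yield from levels((root,), k - 1)


def _label_subgraph(
    g: ConnectomeGraph,
    vertices: Sequence[int],
    colored: bool,
    ignore_self_loops: bool,
) -> CanonicalLabel:
    vs = sorted(vertices)
    k = len(vs)
    flat = []
    edges = g.edges
    for u in vs:
        for v in vs:
            e = edges.get((u, v))
            code = 0 if e is None else e[0]
            if u == v and ignore_self_loops:
                code = 0
            flat.append(code if colored else min(code, 1))
    mat = np.asarray(flat, dtype=np.int64).reshape(k, k)
    vc = None
    if colored and g.vertex_color is not None:
        vc = tuple(g.vertex_color[v] for v in vs)
    return canonical_label(mat, vc)


def census(
    g: ConnectomeGraph,
    k: int,
    colored: bool = False,
    roots: Iterable[int] | None = None,
    ordering=None,
    ignore_self_loops: bool = False,
    max_k: int = 8,
) -> MotifCensus:
    """Motif census of all connected induced k-subgraphs of ``g``.

    Enumeration runs rooted at each requested root (default: every vertex)
    under the given enumeration ordering (default: the graph's own vertex
    ids).  Edge and vertex colors enter the labels iff ``colored``; with
    ``colored=False`` every edge collapses to code 1 and vertex colors are
    dropped, so the census is purely topological.
    """
    if k > max_k:
        raise SizeError(f"k={k} exceeds canonical-labeling maximum {max_k}")
    out = MotifCensus(k=k, colored=colored)
    out.metadata["graph"] = g.content_hash()
    out.metadata["palette"] = ",".join(g.palette.names)
    if ordering is not None:
        out.metadata["ordering"] = ordering.digest()

    if ordering is None:
        h = g
        to_orig = None
        idx_of = None
    else:
        # relabel into enumeration-index space; labels are index-invariant so
        # only the pruning order changes
        idx_of = ordering.index_of
        to_orig = ordering.inverse()
        h = ConnectomeGraph(g.n, g.palette)
        for (u, v), (c, w) in g.edges.items():
            h.add_edge(idx_of[u], idx_of[v], c, w)

    root_ids = range(g.n) if roots is None else sorted(set(roots))
    nbrs = h.neighbors()
    if k == 1:
        for r in root_ids:
            out.add(_label_subgraph(g, (r,), colored, ignore_self_loops))
        return out
    for r in root_ids:
        ri = r if idx_of is None else idx_of[r]
        for tup in enumerate_rooted(h, ri, k, _nbrs=nbrs):
            vs = tup if to_orig is None else tuple(to_orig[i] for i in tup)
            out.add(_label_subgraph(g, vs, colored, ignore_self_loops))
    return out


def brute_force_census(
    g: ConnectomeGraph,
    k: int,
    colored: bool = False,
    ignore_self_loops: bool = False,
    budget: int = DEFAULT_BRUTE_FORCE_BUDGET,
) -> MotifCensus:
    """Census by exhaustive k-subset scan; the independent oracle for ``census``.

    Every k-subset of vertices is tested for weak connectivity of its induced
    subgraph and labeled if connected.  Cost is C(n, k); refused beyond the
    budget.
    """
    if comb(g.n, k) > budget:
        raise BudgetError(f"C({g.n},{k}) = {comb(g.n, k)} subsets exceed budget {budget}")
    out = MotifCensus(k=k, colored=colored)
    out.metadata["graph"] = g.content_hash()
    out.metadata["palette"] = ",".join(g.palette.names)
    out.metadata["method"] = "brute-force"
    nbrs = g.neighbors()
    for subset in itertools.combinations(range(g.n), k):
        members = set(subset)
        seen = {subset[0]}
        stack = [subset[0]]
        while stack:
            u = stack.pop()
            for w in nbrs[u]:
                if w in members and w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != k:
            continue
        out.add(_label_subgraph(g, subset, colored, ignore_self_loops))
    return out


def merge(
    censuses: Sequence[MotifCensus],
    require_same_graph: bool = False,
) -> MotifCensus:
    """Per-label sum of censuses sharing k, colored flag, and palette.

    With ``require_same_graph`` the graph content hashes recorded in the
    metadata must also agree — the guard used when combining batch parts, so
    parts of different graphs never merge silently.
    """
    if not censuses:
        raise MergeError("nothing to merge")
    first = censuses[0]
    out = MotifCensus(k=first.k, colored=first.colored, metadata=dict(first.metadata))
    graphs = []
    for c in censuses:
        if c.k != first.k:
            raise MergeError(f"mismatched k: {c.k} != {first.k}")
        if c.colored != first.colored:
            raise MergeError("mismatched colored flags")
        if c.metadata.get("palette") != first.metadata.get("palette"):
            raise MergeError("mismatched palettes")
        if require_same_graph and c.metadata.get("graph") != first.metadata.get("graph"):
            raise MergeError(
                f"graph hash mismatch: {c.metadata.get('graph')} != {first.metadata.get('graph')}"
            )
        graphs.append(c.metadata.get("graph", ""))
        for label, count in c.counts.items():
            out.add(label, count)
    out.metadata["merged_parts"] = str(len(censuses))
    if len(set(graphs)) > 1:
        out.metadata["graph"] = "+".join(sorted(set(graphs)))
    return out


# -- census TSV I/O ----------------------------------------------------------

def write_census(c: MotifCensus, path) -> None:
    """Write the census TSV: ``#key=value`` header lines, then sorted
    ``label<TAB>count`` rows.  Byte-stable across runs and platforms."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#k={c.k}\n")
        fh.write(f"#colored={'true' if c.colored else 'false'}\n")
        for key in sorted(c.metadata):
            fh.write(f"#{key}={c.metadata[key]}\n")
        for label, count in c.items_sorted():
            fh.write(f"{label.text}\t{count}\n")


def read_census(path) -> MotifCensus:
    k = None
    colored = False
    metadata: dict[str, str] = {}
    counts: dict[CanonicalLabel, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "k":
                    k = int(value)
                elif key == "colored":
                    colored = value.lower() == "true"
                else:
                    metadata[key] = value
                continue
            label_text, _, count_text = line.partition("\t")
            counts[CanonicalLabel.from_text(label_text)] = int(count_text)
    if k is None:
        raise MergeError(f"{path}: missing #k header")
    return MotifCensus(k=k, colored=colored, counts=counts, metadata=metadata)
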