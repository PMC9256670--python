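"""Divide-and-conquer enumeration over balanced vertex communities.

For graphs too dense or too large to enumerate whole, vertices are first
split into roughly equal communities and the census runs independently
inside each one.  Cross-community edges are dropped, so any subgraph
spanning two communities is missed — the per-label merged count is a lower
bound on the full census, tight exactly when no connected k-set crosses a
boundary.  Partitions may come from a multilevel partitioner backend, from
the built-in deterministic greedy-balanced fallback, or from manual labels
such as anatomical brain regions.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

from connmotif.errors import PartitionBackendError
from connmotif.graph_model import ConnectomeGraph
from connmotif.kavosh import MotifCensus, census, merge


@dataclass(frozen=True)
class CommunityPartition:
    """Assignment of every vertex to one of c communities."""

    community_of: tuple[int, ...]
    c: int
    balance_tolerance: float = 1.5

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("community count must be >= 1")
        used = set(self.community_of)
        if used != set(range(self.c)):
            raise ValueError(f"communities must be exactly 0..{self.c - 1}, got {sorted(used)}")

    def sizes(self) -> list[int]:
        out = [0] * self.c
        for comm in self.community_of:
            out[comm] += 1
        return out

    def members(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.c)]
        for v, comm in enumerate(self.community_of):
            out[comm].append(v)
        return out

    def cut_edges(self, g: ConnectomeGraph) -> int:
        """Number of edges joining different communities (self-loops never cut)."""
        return sum(
            1 for (u, v) in g.edges if u != v and self.community_of[u] != self.community_of[v]
        )


def partition_graph(
    g: ConnectomeGraph,
    c: int,
    seed: int = 0,
    method: str = "greedy-balanced",
    balance_tolerance: float = 1.5,
) -> CommunityPartition:
    """Balanced c-way partition of the vertex set.

    ``method="metis"`` delegates to a multilevel partitioner backend when one
    is importable; ``method="greedy-balanced"`` (the built-in default) grows
    BFS regions of size at most ceil(n/c) from high-degree seed vertices on
    the undirected unit-weight projection.  Deterministic given (graph, c,
    seed, method); the seed is recorded so downstream census metadata can
    cite it.
    """
    if not 1 <= c <= g.n:
        raise ValueError(f"community count {c} must be in 1..{g.n}")
    if method == "metis":
        return _partition_metis(g, c, seed, balance_tolerance)
    if method != "greedy-balanced":
        raise ValueError(f"unknown partition method {method!r}")

    nbrs = g.neighbors()
    n = g.n
    target = math.ceil(n / c)
    community_of = [-1] * n
    # seeds by descending degree (ties: lowest id) keep hubs at region cores
    seed_order = sorted(range(n), key=lambda v: (-len(nbrs[v]), v))
    assigned = 0
    for comm in range(c):
        # reserve one vertex for each community still to come
        cap = min(target, n - assigned - (c - comm - 1))
        if cap <= 0:
            cap = 1
        start = next(v for v in seed_order if community_of[v] == -1)
        community_of[start] = comm
        assigned += 1
        size = 1
        queue = deque([start])
        while queue and size < cap:
            u = queue.popleft()
            for w in sorted(nbrs[u]):
                if community_of[w] == -1:
                    community_of[w] = comm
                    assigned += 1
                    size += 1
                    queue.append(w)
                    if size >= cap:
                        break
    # disconnected leftovers: fill the lightest community (ties: lowest id)
    sizes = [0] * c
    for comm in community_of:
        if comm >= 0:
            sizes[comm] += 1
    for v in range(n):
        if community_of[v] == -1:
            comm = min(range(c), key=lambda b: (sizes[b], b))
            community_of[v] = comm
            sizes[comm] += 1
    return CommunityPartition(tuple(community_of), c, balance_tolerance)


def _partition_metis(g: ConnectomeGraph, c: int, seed: int, balance_tolerance: float) -> CommunityPartition:
    try:
        import pymetis  # type: ignore[import-not-found]
    except ImportError:
        raise PartitionBackendError(
            "multilevel partitioner backend (pymetis) is not installed; "
            "use method='greedy-balanced'"
        ) from None
    adjacency = [sorted(s) for s in g.neighbors()]
    _, membership = pymetis.part_graph(c, adjacency=adjacency)
    # normalize community ids to 0..c-1 in first-appearance order
    remap: dict[int, int] = {}
    out = []
    for m in membership:
        if m not in remap:
            remap[m] = len(remap)
        out.append(remap[m])
    return CommunityPartition(tuple(out), len(remap), balance_tolerance)


def accept_manual_partition(
    g: ConnectomeGraph,
    labels: Mapping[str, str],
) -> CommunityPartition:
    """Convert biological region labels (vertex name -> region name) into a
    partition.  Community ids follow sorted region names.  Balance is not
    enforced — a warning is emitted if regions are badly uneven."""
    missing = [name for name in g.vertex_name if name not in labels]
    if missing:
        raise KeyError(f"vertices without a community label: {missing[:5]}" +
                       (" ..." if len(missing) > 5 else ""))
    regions = sorted({labels[name] for name in g.vertex_name})
    region_id = {r: i for i, r in enumerate(regions)}
    community_of = tuple(region_id[labels[name]] for name in g.vertex_name)
    part = CommunityPartition(community_of, len(regions), balance_tolerance=float("inf"))
    sizes = part.sizes()
    if g.n and max(sizes) > 1.5 * math.ceil(g.n / len(regions)):
        warnings.warn(
            f"manual partition is unbalanced (sizes {sizes}); divide-and-conquer "
            "speedup will be limited",
            stacklevel=2,
        )
    return part


def community_subgraph(g: ConnectomeGraph, vertices: Sequence[int]) -> ConnectomeGraph:
    """Induced subgraph on one community, re-indexed densely; cross-community
    edges are dropped by construction."""
    vs = sorted(vertices)
    new_id = {v: i for i, v in enumerate(vs)}
    sub = ConnectomeGraph(
        len(vs),
        g.palette,
        vertex_name=[g.vertex_name[v] for v in vs],
        vertex_color=None if g.vertex_color is None else [g.vertex_color[v] for v in vs],
    )
    for (u, v), (color, weight) in g.edges.items():
        if u in new_id and v in new_id:
            sub.add_edge(new_id[u], new_id[v], color, weight)
    return sub


def community_census(
    g: ConnectomeGraph,
    partition: CommunityPartition,
    k: int,
    colored: bool = False,
    full_census: MotifCensus | None = None,
    ignore_self_loops: bool = False,
) -> tuple[list[MotifCensus], MotifCensus, int | None]:
    """Per-community censuses, their merge, and the spanning-subgraph loss.

    Each community is enumerated in isolation (its induced subgraph,
    re-indexed).  The merged census undercounts the full census by exactly
    the subgraphs that span communities; when a full census is supplied the
    loss ``full.total() - merged.total()`` is reported, otherwise None.
    """
    parts: list[MotifCensus] = []
    for comm, vertices in enumerate(partition.members()):
        sub = community_subgraph(g, vertices)
        part = census(sub, k, colored=colored, ignore_self_loops=ignore_self_loops)
        part.metadata["community"] = str(comm)
        parts.append(part)
    merged = merge(parts)
    merged.metadata["graph"] = g.content_hash()
    merged.metadata["communities"] = str(partition.c)
    loss = None
    if full_census is not None:
        loss = full_census.total() - merged.total()
    return parts, merged, loss
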