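"""Load balancing for rooted enumeration.

The work rooted at a vertex grows combinatorially with the number of its
neighbors that carry a *larger* enumeration index (at least C(h, k-1)
subgraphs lie inside the immediate neighborhood alone).  When vertex ids are
arbitrary — as they are in automatically reconstructed wiring diagrams — a
few low-index hubs dominate the wall time of a parallel run.  Assigning
enumeration indices greedily by smallest residual degree pushes hubs to
high indices, where the min-index pruning shields them, and flattens the
per-root cost distribution.  Roots are then packed into batches by
longest-processing-time-first on the binomial cost estimate.
"""

from __future__ import annotations

import hashlib
import heapq
import statistics
import time
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

from connmotif.errors import ConnmotifError
from connmotif.graph_model import ConnectomeGraph
from connmotif.kavosh import MotifCensus, census, merge


@dataclass(frozen=True)
class EnumerationOrdering:
    """Bijection vertex id -> enumeration index 0..n-1."""

    index_of: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.index_of)
        if sorted(self.index_of) != list(range(n)):
            raise ValueError("index_of must be a bijection onto 0..n-1")

    def inverse(self) -> tuple[int, ...]:
        inv = [0] * len(self.index_of)
        for v, i in enumerate(self.index_of):
            inv[i] = v
        return tuple(inv)

    def digest(self) -> str:
        return hashlib.sha256(",".join(map(str, self.index_of)).encode()).hexdigest()[:12]


def identity_ordering(g: ConnectomeGraph) -> EnumerationOrdering:
    """The naive ordering: enumeration index = original vertex id."""
    return EnumerationOrdering(tuple(range(g.n)))


def assign_enumeration_indices(g: ConnectomeGraph) -> EnumerationOrdering:
    """Greedy smallest-residual-degree ordering.

    Repeatedly give the next index (starting at 0) to the unassigned vertex
    with the smallest residual degree — ties broken by smallest original
    id — then decrement the residual degree of its unassigned neighbors:
    enumeration from those vertices will never revisit an already-assigned
    vertex, so it stops counting toward their load.  Degree counts distinct
    neighbors, ignoring direction and self-loops.
    """
    nbrs = g.neighbors()
    residual = [len(nbrs[v]) for v in range(g.n)]
    assigned = [False] * g.n
    heap: list[tuple[int, int]] = [(residual[v], v) for v in range(g.n)]
    heapq.heapify(heap)
    index_of = [0] * g.n
    next_index = 0
    while heap:
        deg, v = heapq.heappop(heap)
        if assigned[v] or deg != residual[v]:
            continue  # stale heap entry
        assigned[v] = True
        index_of[v] = next_index
        next_index += 1
        for w in nbrs[v]:
            if not assigned[w]:
                residual[w] -= 1
                heapq.heappush(heap, (residual[w], w))
    return EnumerationOrdering(tuple(index_of))


def estimate_root_cost(
    g: ConnectomeGraph,
    ordering: EnumerationOrdering,
    v: int,
    k: int,
) -> int:
    """Dimensionless work estimate for enumeration rooted at v: C(h, k-1) + 1,
    where h is the number of neighbors of v with a larger enumeration index.

    C(h, k-1) lower-bounds the subgraph yield (the immediate neighborhood
    alone contains that many rooted k-sets); the +1 keeps zero-yield roots at
    positive cost.  First-order only: wider neighborhoods correlate poorly
    with actual yield.
    """
    iv = ordering.index_of[v]
    h = sum(1 for w in g.neighbors()[v] if ordering.index_of[w] > iv)
    return comb(h, k - 1) + 1


@dataclass(frozen=True)
class BatchPlan:
    """Disjoint root sets covering all vertices, with per-batch estimated work."""

    batches: tuple[tuple[int, ...], ...]
    est_cost: tuple[int, ...]

    def balance_ratio(self) -> float:
        """max/min estimated batch cost; 1.0 is perfectly balanced."""
        if not self.est_cost:
            return 1.0
        return max(self.est_cost) / max(min(self.est_cost), 1)


def lpt_partition(costs: dict[int, int], num_batches: int) -> BatchPlan:
    """Longest-processing-time-first greedy packing of weighted items.

    Items sorted by descending cost (ties: ascending id) are each placed in
    the currently lightest batch (ties: lowest batch id).  A deterministic
    4/3-approximation to optimal makespan.  Empty batches are suppressed.
    """
    if num_batches < 1:
        raise ValueError(f"num_batches must be >= 1, got {num_batches}")
    order = sorted(costs, key=lambda v: (-costs[v], v))
    loads = [0] * num_batches
    members: list[list[int]] = [[] for _ in range(num_batches)]
    heap = [(0, b) for b in range(num_batches)]
    heapq.heapify(heap)
    for v in order:
        load, b = heapq.heappop(heap)
        members[b].append(v)
        loads[b] = load + costs[v]
        heapq.heappush(heap, (loads[b], b))
    kept = [(tuple(sorted(m)), loads[b]) for b, m in enumerate(members) if m]
    return BatchPlan(
        batches=tuple(m for m, _ in kept),
        est_cost=tuple(c for _, c in kept),
    )


def batch_roots(
    g: ConnectomeGraph,
    ordering: EnumerationOrdering,
    k: int,
    num_batches: int,
) -> BatchPlan:
    """Pack all roots into batches by LPT greedy on the binomial cost estimate."""
    costs = {v: estimate_root_cost(g, ordering, v, k) for v in range(g.n)}
    return lpt_partition(costs, num_batches)


def run_batches(
    g: ConnectomeGraph,
    ordering: EnumerationOrdering,
    k: int,
    plan: BatchPlan,
    colored: bool = False,
    workers: int = 1,
    ignore_self_loops: bool = False,
) -> MotifCensus:
    """Run the census batch by batch and merge; identical to a single census.

    Each batch enumerates only from its own roots, so batches can run in any
    order or concurrently without duplicating a subgraph (every subgraph is
    found from its unique minimum-index root).  Batches here run serially in
    plan order; the batch files + merge contract is the integration point
    for cluster execution.  ``workers`` is accepted for interface parity and
    does not change the result.
    """
    covered = sorted(v for batch in plan.batches for v in batch)
    if covered != list(range(g.n)):
        raise ConnmotifError("batch plan does not partition the vertex set")
    parts: list[MotifCensus] = []
    failed: list[int] = []
    for b, batch in enumerate(plan.batches):
        try:
            parts.append(
                census(g, k, colored=colored, roots=batch, ordering=ordering,
                       ignore_self_loops=ignore_self_loops)
            )
        except Exception as exc:  # pragma: no cover - defensive
            failed.append(b)
            raise ConnmotifError(f"batch {b} failed ({exc}); unfinished batches: {failed}") from exc
    if not parts:
        out = MotifCensus(k=k, colored=colored)
        out.metadata["graph"] = g.content_hash()
        out.metadata["palette"] = ",".join(g.palette.names)
        return out
    return merge(parts, require_same_graph=True)


def per_root_timing(
    g: ConnectomeGraph,
    ordering: EnumerationOrdering,
    k: int,
    colored: bool = False,
) -> dict[str, float]:
    """Informational per-root wall-clock statistics (mean/median/max seconds).

    Hardware-dependent; logged for diagnostics, never asserted in tests.
    """
    times = []
    for v in range(g.n):
        t0 = time.perf_counter()
        census(g, k, colored=colored, roots=(v,), ordering=ordering)
        times.append(time.perf_counter() - t0)
    if not times:
        return {"mean": 0.0, "median": 0.0, "max": 0.0}
    return {
        "mean": statistics.fmean(times),
        "median": statistics.median(times),
        "max": max(times),
    }
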