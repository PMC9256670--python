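"""Deterministic synthetic-graph generation.

Every module is testable without downloading a connectome: fixtures cover
closed-form families (path, star, cycle, complete bidirectional), random
families (Erdős–Rényi digraphs with optional edge colors and self-loops,
planted bidirectional cliques, two-community block models), and a directed
preferential-attachment family with power-law-ish degrees for load-balance
experiments.  All randomness flows through a seeded PCG64 generator, whose
stream is identical across platforms, so the same spec always yields the
same graph byte for byte.  These fixtures deliberately do not mimic real
connectome degree distributions or spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from connmotif.canonical import canonical_label
from connmotif.graph_model import MONO, ConnectomeGraph, EdgeColorPalette
from connmotif.kavosh import MotifCensus

MODELS = (
    "path",
    "star",
    "cycle",
    "complete-bidirectional",
    "erdos-renyi",
    "planted-clique",
    "two-communities",
    "scale-free",
)


def _palette(num_colors: int) -> EdgeColorPalette:
    if num_colors == 1:
        return MONO
    return EdgeColorPalette(tuple(f"c{i}" for i in range(1, num_colors + 1)))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic graph.

    Parameters
    ----------
    model
        One of :data:`MODELS`.
    n
        Vertex count.
    p
        Edge probability (erdos-renyi, planted-clique background,
        two-communities intra-block density).
    num_colors
        Edge colors drawn uniformly from 1..num_colors where the model is
        random; structured models use color 1.
    self_loop_p
        Per-vertex self-loop probability (random models only).
    seed
        RNG seed; identical spec implies identical graph.
    clique_size
        Planted-clique order (default n // 5, at least 3).
    inter_p
        two-communities cross-block density (default p / 10).
    attach
        scale-free: out-edges each new vertex attaches preferentially.
    """

    model: str
    n: int
    p: float = 0.0
    num_colors: int = 1
    self_loop_p: float = 0.0
    seed: int = 0
    clique_size: int = 0
    inter_p: float | None = None
    attach: int = 2

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown fixture model {self.model!r}; choose from {MODELS}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


def _random_color(rng: np.random.Generator, num_colors: int) -> int:
    return 1 if num_colors == 1 else int(rng.integers(1, num_colors + 1))


def make_graph(spec: FixtureSpec) -> ConnectomeGraph:
    """Build the graph a spec describes; deterministic in the spec alone."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    palette = _palette(spec.num_colors)
    g = ConnectomeGraph(spec.n, palette)
    n = spec.n

    if spec.model == "path":
        for i in range(n - 1):
            g.add_edge(i, i + 1, 1)
    elif spec.model == "star":
        for leaf in range(1, n):
            g.add_edge(0, leaf, 1)
    elif spec.model == "cycle":
        for i in range(n):
            g.add_edge(i, (i + 1) % n, 1)
    elif spec.model == "complete-bidirectional":
        for u in range(n):
            for v in range(n):
                if u != v:
                    g.add_edge(u, v, 1)
    elif spec.model == "erdos-renyi":
        _add_er_edges(g, rng, range(n), range(n), spec.p, spec.num_colors)
        _add_self_loops(g, rng, spec)
    elif spec.model == "planted-clique":
        _add_er_edges(g, rng, range(n), range(n), spec.p, spec.num_colors)
        size = spec.clique_size or max(3, n // 5)
        members = sorted(int(v) for v in rng.choice(n, size=min(size, n), replace=False))
        for u in members:
            for v in members:
                if u != v:
                    g.add_edge(u, v, _random_color(rng, spec.num_colors))
        _add_self_loops(g, rng, spec)
    elif spec.model == "two-communities":
        half = n // 2
        inter = spec.inter_p if spec.inter_p is not None else spec.p / 10
        _add_er_edges(g, rng, range(half), range(half), spec.p, spec.num_colors)
        _add_er_edges(g, rng, range(half, n), range(half, n), spec.p, spec.num_colors)
        _add_er_edges(g, rng, range(half), range(half, n), inter, spec.num_colors, both_ways=True)
        _add_self_loops(g, rng, spec)
    elif spec.model == "scale-free":
        # directed preferential attachment: each arriving vertex sends
        # `attach` edges to targets drawn proportional to degree + 1
        targets: list[int] = [0]
        for v in range(1, n):
            m = min(spec.attach, v)
            chosen: set[int] = set()
            while len(chosen) < m:
                t = targets[int(rng.integers(0, len(targets)))]
                if t != v:
                    chosen.add(t)
            for t in sorted(chosen):
                g.add_edge(v, t, _random_color(rng, spec.num_colors))
                targets.append(t)
            targets.append(v)
        _add_self_loops(g, rng, spec)
    return g


def _add_er_edges(g, rng, rows, cols, p, num_colors, both_ways=False) -> None:
    for u in rows:
        for v in cols:
            if u == v:
                continue
            if rng.random() < p:
                g.add_edge(u, v, _random_color(rng, num_colors))
            if both_ways and rng.random() < p:
                g.add_edge(v, u, _random_color(rng, num_colors))


def _add_self_loops(g, rng, spec: FixtureSpec) -> None:
    if spec.self_loop_p <= 0:
        return
    for v in range(spec.n):
        if rng.random() < spec.self_loop_p:
            g.add_edge(v, v, _random_color(rng, spec.num_colors))


def expected_census(spec: FixtureSpec, k: int) -> MotifCensus | None:
    """Closed-form census for the structured families, or None.

    path: n-k+1 windows, all the directed k-path; star: C(n-1, k-1) rooted
    out-stars; cycle (k < n): n windows, each the directed k-path;
    complete bidirectional: C(n, k) copies of the bidirectional clique.
    """
    n = spec.n
    if spec.model == "path" or spec.model == "cycle":
        count = n - k + 1 if spec.model == "path" else n
        if spec.model == "cycle" and k >= n:
            return None
        mat = np.zeros((k, k), dtype=np.int64)
        for i in range(k - 1):
            mat[i, i + 1] = 1
        label = canonical_label(mat)
    elif spec.model == "star":
        count = comb(n - 1, k - 1)
        mat = np.zeros((k, k), dtype=np.int64)
        mat[0, 1:] = 1
        label = canonical_label(mat)
    elif spec.model == "complete-bidirectional":
        count = comb(n, k)
        mat = np.ones((k, k), dtype=np.int64)
        np.fill_diagonal(mat, 0)
        label = canonical_label(mat)
    else:
        return None
    out = MotifCensus(k=k, colored=False)
    out.metadata["palette"] = ",".join(_palette(spec.num_colors).names)
    out.metadata["method"] = "closed-form"
    if count > 0:
        out.add(label, count)
    return out
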