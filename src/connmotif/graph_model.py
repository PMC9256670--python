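"""Graph data model for connectome wiring diagrams.

A connectome is modeled as a directed simple graph: one vertex per neuron
(or muscle/end-organ), one edge per ordered pair of cells with at least one
synaptic connection.  Edges carry a categorical *color* (connection type or
strength class) and a nonnegative *weight* (synapse count).  Self-loops are
permitted.  Multi-edges are collapsed at load time: weights sum, and rows
whose colors disagree receive the palette's designated "combined" color
(e.g. ``both`` for a chemical+electrical pair).
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from connmotif.errors import CollapseError, PaletteError, ParseError

#: Single-character rendering of color codes 0..35 used in canonical labels.
CODE_CHARS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
MAX_COLORS = 35


@dataclass(frozen=True)
class EdgeColorPalette:
    """Ordered set of edge-color names; code 0 is reserved for "no edge".

    Parameters
    ----------
    names
        Color names in fixed order; the i-th name maps to integer code i+1.
    combined
        Optional name of the color assigned when multi-edge rows between the
        same ordered pair disagree on color (e.g. ``"both"`` for a vertex
        pair linked by both a chemical and an electrical synapse).  Must be
        one of ``names``.
    """

    names: tuple[str, ...]
    combined: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise PaletteError(f"duplicate color names in palette: {self.names}")
        if len(self.names) > MAX_COLORS:
            raise PaletteError(f"palette has {len(self.names)} colors; max {MAX_COLORS}")
        if not self.names:
            raise PaletteError("palette must contain at least one color")
        if self.combined is not None and self.combined not in self.names:
            raise PaletteError(f"combined color {self.combined!r} not in palette {self.names}")

    @property
    def num_colors(self) -> int:
        return len(self.names)

    def code_of(self, name: str) -> int:
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise PaletteError(f"color {name!r} not in palette {self.names}") from None

    def name_of(self, code: int) -> str:
        if not 1 <= code <= len(self.names):
            raise PaletteError(f"color code {code} outside palette range 1..{len(self.names)}")
        return self.names[code - 1]

    @property
    def combined_code(self) -> int | None:
        return None if self.combined is None else self.code_of(self.combined)


#: Default palette for weighted graphs with a single undifferentiated edge type.
MONO = EdgeColorPalette(("edge",))
#: Synaptic-strength palette used after pruning weak connections.
STRENGTH = EdgeColorPalette(("moderate", "strong"))
#: C. elegans connection-type palette: chemical synapse, gap junction, or both.
CHEMICAL_ELECTRICAL = EdgeColorPalette(("chemical", "electrical", "both"), combined="both")


class ConnectomeGraph:
    """Directed simple graph with colored, weighted edges and optional vertex colors.

    Vertices are dense integers ``0..n-1`` assigned in first-appearance order;
    original identifiers (neuron names) are kept in :attr:`vertex_name`.
    At most one edge is stored per ordered pair; self-loops are allowed.
    """

    def __init__(
        self,
        n: int,
        palette: EdgeColorPalette = MONO,
        vertex_name: Sequence[str] | None = None,
        vertex_color: Sequence[int] | None = None,
    ) -> None:
        self.n = int(n)
        self.palette = palette
        self.vertex_name: list[str] = list(vertex_name) if vertex_name is not None else [str(i) for i in range(n)]
        self.vertex_color: list[int] | None = list(vertex_color) if vertex_color is not None else None
        if len(self.vertex_name) != self.n:
            raise ValueError("vertex_name length must equal n")
        if self.vertex_color is not None and len(self.vertex_color) != self.n:
            raise ValueError("vertex_color length must equal n")
        # (u, v) -> (color code, weight)
        self.edges: dict[tuple[int, int], tuple[int, float]] = {}
        self._nbrs: list[set[int]] | None = None

    # -- construction ------------------------------------------------------

    def add_edge(self, u: int, v: int, color: int = 1, weight: float = 1.0) -> None:
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise IndexError(f"edge ({u},{v}) outside vertex range 0..{self.n - 1}")
        if not 1 <= color <= self.palette.num_colors:
            raise PaletteError(f"edge color code {color} outside palette range 1..{self.palette.num_colors}")
        self.edges[(u, v)] = (color, float(weight))
        self._nbrs = None

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def edge_color(self, u: int, v: int) -> int:
        """Color code of edge u->v, or 0 if absent."""
        e = self.edges.get((u, v))
        return 0 if e is None else e[0]

    def neighbors(self) -> list[set[int]]:
        """Undirected neighborhoods (in- plus out-neighbors), self excluded.

        Self-loops never contribute to neighborhoods or connectivity; they
        only appear on the diagonal of induced adjacency matrices.
        """
        if self._nbrs is None:
            nbrs: list[set[int]] = [set() for _ in range(self.n)]
            for (u, v) in self.edges:
                if u != v:
                    nbrs[u].add(v)
                    nbrs[v].add(u)
            self._nbrs = nbrs
        return self._nbrs

    def degree(self, v: int) -> int:
        """Number of distinct neighbors, ignoring direction and self-loops."""
        return len(self.neighbors()[v])

    def copy(self) -> "ConnectomeGraph":
        g = ConnectomeGraph(self.n, self.palette, self.vertex_name, self.vertex_color)
        g.edges = dict(self.edges)
        return g

    def content_hash(self) -> str:
        """sha256 of the canonical edge-list text; identifies the graph in census files."""
        buf = io.StringIO()
        _write_edge_list_stream(self, buf)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ConnectomeGraph(n={self.n}, edges={self.num_edges}, palette={self.palette.names})"


# -- synapse-strength classification ---------------------------------------

WEAK_MAX = 3       # weakly connected: three or fewer synapses
MODERATE_MAX = 9   # moderately connected: more than three but fewer than ten


def classify_strength(synapse_count: float) -> str:
    """Classify a synapse count as ``weak``, ``moderate``, or ``strong``.

    Weak means three or fewer synapses, moderate between four and nine,
    strong ten or more.
    """
    if synapse_count < 0:
        raise ValueError(f"synapse count must be nonnegative, got {synapse_count}")
    if synapse_count <= WEAK_MAX:
        return "weak"
    if synapse_count <= MODERATE_MAX:
        return "moderate"
    return "strong"


def prune_weak_edges(g: ConnectomeGraph, strength_palette: bool = False) -> ConnectomeGraph:
    """Drop weakly connected edges (synapse count <= 3); vertex set unchanged.

    Each ordered pair is pruned independently by its own summed synapse
    count.  With ``strength_palette=True`` surviving edges are recolored by
    strength class (moderate -> 1, strong -> 2) under the strength palette.
    """
    palette = STRENGTH if strength_palette else g.palette
    out = ConnectomeGraph(g.n, palette, g.vertex_name, g.vertex_color)
    for (u, v), (color, weight) in g.edges.items():
        strength = classify_strength(weight)
        if strength == "weak":
            continue
        if strength_palette:
            color = 1 if strength == "moderate" else 2
        out.add_edge(u, v, color, weight)
    return out


# -- multi-edge collapsing --------------------------------------------------

def collapse_multi_edges(
    rows: Sequence[tuple[int, int, float, int]],
    palette: EdgeColorPalette,
) -> tuple[int, int, float, int]:
    """Collapse parallel edge rows for one ordered pair into a single edge.

    Weights sum.  If all rows agree on color that color is kept; otherwise
    the palette's configured combined color is assigned (an edge color that
    marks a pair of cells joined by multiple connection types).  Order of
    the input rows never affects the result.
    """
    if not rows:
        raise ValueError("collapse_multi_edges requires at least one row")
    pairs = {(u, v) for (u, v, _, _) in rows}
    if len(pairs) != 1:
        raise ValueError(f"rows span multiple ordered pairs: {sorted(pairs)}")
    (u, v) = pairs.pop()
    weight = sum(w for (_, _, w, _) in rows)
    colors = {c for (_, _, _, c) in rows}
    if len(colors) == 1:
        color = colors.pop()
    else:
        code = palette.combined_code
        if code is None:
            raise CollapseError(
                f"edge ({u},{v}) has conflicting colors {sorted(colors)} "
                "and the palette has no combined color configured"
            )
        color = code
    return (u, v, weight, color)


# -- readers / writers -------------------------------------------------------

def load_edge_list(
    path,
    palette: EdgeColorPalette = MONO,
    drop_zero_weight: bool = True,
) -> ConnectomeGraph:
    """Load a graph from an edge-list CSV with columns source,target[,weight,color].

    Vertex identifiers are arbitrary strings; they receive dense integer ids
    in first-appearance order and are retained as vertex names.  Rows sharing
    an ordered pair are collapsed via :func:`collapse_multi_edges`.  Missing
    weight defaults to 1, missing color to code 1.  Edges with weight 0 are
    dropped.
    """
    ids: dict[str, int] = {}
    rows_by_pair: dict[tuple[int, int], list[tuple[int, int, float, int]]] = {}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        header = [h.strip().lower() for h in header]
        try:
            i_src = header.index("source")
            i_tgt = header.index("target")
        except ValueError:
            raise ParseError(f"{path}: header must contain 'source' and 'target', got {header}") from None
        i_w = header.index("weight") if "weight" in header else None
        i_c = header.index("color") if "color" in header else None

        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            src, tgt = row[i_src].strip(), row[i_tgt].strip()
            if not src or not tgt:
                raise ParseError(f"{path}:{lineno}: empty source or target")
            try:
                weight = float(row[i_w]) if i_w is not None and row[i_w].strip() else 1.0
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad weight {row[i_w]!r}") from None
            color = palette.code_of(row[i_c].strip()) if i_c is not None and row[i_c].strip() else 1
            for name in (src, tgt):
                if name not in ids:
                    ids[name] = len(ids)
            u, v = ids[src], ids[tgt]
            rows_by_pair.setdefault((u, v), []).append((u, v, weight, color))

    names = [None] * len(ids)
    for name, i in ids.items():
        names[i] = name
    g = ConnectomeGraph(len(ids), palette, vertex_name=names)
    for pair, rows in rows_by_pair.items():
        u, v, weight, color = collapse_multi_edges(rows, palette)
        if drop_zero_weight and weight == 0:
            continue
        g.add_edge(u, v, color, weight)
    return g


def _write_edge_list_stream(g: ConnectomeGraph, fh) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(["source", "target", "weight", "color"])
    for (u, v) in sorted(g.edges):
        color, weight = g.edges[(u, v)]
        wtxt = f"{int(weight)}" if float(weight).is_integer() else repr(weight)
        writer.writerow([g.vertex_name[u], g.vertex_name[v], wtxt, g.palette.name_of(color)])


def write_edge_list(g: ConnectomeGraph, path) -> None:
    """Write the edge-list CSV dialect read by :func:`load_edge_list`.

    Rows are sorted by (source id, target id) so output is byte-stable.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write_edge_list_stream(g, fh)


def load_adjacency_matrix(
    path,
    palette: EdgeColorPalette = MONO,
    dialect: str = "colored",
) -> ConnectomeGraph:
    """Load a graph from a square numeric CSV adjacency matrix.

    Two dialects, declared explicitly rather than guessed: in ``colored``
    each nonzero entry (i, j) is the color code of edge i->j (weight 1); in
    ``weighted`` each nonzero entry is a synapse weight (color 1).
    """
    if dialect not in ("colored", "weighted"):
        raise ValueError(f"unknown matrix dialect {dialect!r}")
    mat = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float, ndmin=2))
    if mat.size == 0:
        return ConnectomeGraph(0, palette)
    if mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: adjacency matrix must be square, got shape {mat.shape}")
    n = mat.shape[0]
    g = ConnectomeGraph(n, palette)
    for i, j in zip(*np.nonzero(mat)):
        entry = mat[i, j]
        if dialect == "colored":
            code = int(entry)
            if code != entry or not 1 <= code <= palette.num_colors:
                raise PaletteError(f"{path}: entry ({i},{j})={entry} outside palette range 1..{palette.num_colors}")
            g.add_edge(int(i), int(j), code, 1.0)
        else:
            if entry < 0:
                raise ParseError(f"{path}: negative weight at ({i},{j})")
            g.add_edge(int(i), int(j), 1, float(entry))
    return g


def induced_subgraph(g: ConnectomeGraph, vertices: Iterable[int]) -> np.ndarray:
    """Colored adjacency matrix of the induced subgraph on a vertex set.

    Vertices are taken in sorted-id order; entry (i, j) is the color code of
    the edge from the i-th to the j-th chosen vertex (0 if absent), and the
    diagonal carries self-loop colors.
    """
    vs = sorted(set(vertices))
    for v in vs:
        if not 0 <= v < g.n:
            raise IndexError(f"vertex {v} outside 0..{g.n - 1}")
    k = len(vs)
    adj = np.zeros((k, k), dtype=np.int64)
    for i, u in enumerate(vs):
        for j, v in enumerate(vs):
            adj[i, j] = g.edge_color(u, v)
    return adj


def subgraph_vertex_colors(g: ConnectomeGraph, vertices: Iterable[int]) -> tuple[int, ...] | None:
    """Vertex colors of a vertex set in sorted-id order, or None if uncolored."""
    if g.vertex_color is None:
        return None
    return tuple(g.vertex_color[v] for v in sorted(set(vertices)))
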