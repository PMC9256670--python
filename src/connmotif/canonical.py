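"""Canonical labeling of small vertex/edge-colored directed graphs.

Two induced subgraphs belong to the same motif class exactly when some
bijection of their vertices preserves every edge color (and vertex color).
The canonical label is the representative we count under: the
lexicographically minimal string encoding of the colored adjacency matrix
over all k! simultaneous row/column permutations.  Minimization is
exhaustive — for the motif orders used here (k <= 8, so at most 40,320
permutations) this is tractable, deterministic, and needs no layered-graph
encoding to support edge colors.

Labels render color codes as single characters ``0-9A-Z`` (0 = no edge),
row-major; a vertex-colored label prefixes a block of k vertex-color
characters, compared before the matrix block.  Text form:
``[<vertex_block>:]<matrix_block>``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from connmotif.errors import BudgetError, SizeError
from connmotif.graph_model import CODE_CHARS

#: Permutation minimization is factorial; labels above this order are refused.
DEFAULT_MAX_K = 8

#: Generation budget for exhaustive class enumeration (number of matrices).
DEFAULT_ENUMERATION_BUDGET = 5_000_000

_CODE_OF_CHAR = {c: i for i, c in enumerate(CODE_CHARS)}


@dataclass(frozen=True, order=True)
class CanonicalLabel:
    """Identity of a motif class: minimal string form of its colored adjacency matrix."""

    k: int
    matrix_block: str
    vertex_block: str | None = None

    def __post_init__(self) -> None:
        if len(self.matrix_block) != self.k * self.k:
            raise ValueError(f"matrix_block length {len(self.matrix_block)} != k^2 = {self.k * self.k}")
        if self.vertex_block is not None and len(self.vertex_block) != self.k:
            raise ValueError(f"vertex_block length {len(self.vertex_block)} != k = {self.k}")

    @property
    def text(self) -> str:
        if self.vertex_block is None:
            return self.matrix_block
        return f"{self.vertex_block}:{self.matrix_block}"

    @classmethod
    def from_text(cls, text: str) -> "CanonicalLabel":
        vertex_block: str | None = None
        matrix_block = text
        if ":" in text:
            vertex_block, matrix_block = text.split(":", 1)
        k = int(round(len(matrix_block) ** 0.5))
        if k * k != len(matrix_block):
            raise ValueError(f"matrix block length {len(matrix_block)} is not a perfect square")
        return cls(k=k, matrix_block=matrix_block, vertex_block=vertex_block or None)

    def to_matrix(self) -> np.ndarray:
        """Decode the k x k color-code matrix of the canonical permutation."""
        codes = [_CODE_OF_CHAR[c] for c in self.matrix_block]
        return np.array(codes, dtype=np.int64).reshape(self.k, self.k)

    def vertex_colors(self) -> tuple[int, ...] | None:
        if self.vertex_block is None:
            return None
        return tuple(_CODE_OF_CHAR[c] for c in self.vertex_block)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


@lru_cache(maxsize=16)
def _perm_maps(k: int) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All k! permutations with their flat-index maps for row-major k x k matrices.

    For permutation p, entry (i, j) of the permuted matrix is entry
    (p[i], p[j]) of the original; the map gives those source flat indices.
    """
    maps = []
    for p in itertools.permutations(range(k)):
        flat = tuple(p[i] * k + p[j] for i in range(k) for j in range(k))
        maps.append((p, flat))
    return tuple(maps)


# raw (vertex colors, flat matrix) -> label; required in the enumeration hot
# path so repeated isomorphic subgraphs pay the k! scan once.
_label_cache: dict[tuple, CanonicalLabel] = {}
_LABEL_CACHE_MAX = 1 << 20


def clear_label_cache() -> None:
    _label_cache.clear()


def canonical_label(
    adj,
    vertex_colors: Sequence[int] | None = None,
    max_k: int = DEFAULT_MAX_K,
) -> CanonicalLabel:
    """Canonical label of a k x k color-code matrix with optional vertex colors.

    Returns the lexicographic minimum of (vertex_block, matrix_block) over
    all permutations of the k vertices applied simultaneously to rows,
    columns, and the vertex-color sequence.  Diagonal (self-loop) entries
    participate.  Deterministic; memoized on the raw input.
    """
    mat = np.asarray(adj, dtype=np.int64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {mat.shape}")
    k = mat.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > max_k:
        raise SizeError(f"k={k} exceeds canonical-labeling maximum {max_k}")
    if mat.min() < 0 or mat.max() >= len(CODE_CHARS):
        raise ValueError(f"color codes must lie in 0..{len(CODE_CHARS) - 1}")

    flat = tuple(int(x) for x in mat.ravel())
    vc = None if vertex_colors is None else tuple(int(c) for c in vertex_colors)
    if vc is not None and len(vc) != k:
        raise ValueError(f"vertex_colors length {len(vc)} != k = {k}")
    key = (vc, flat)
    cached = _label_cache.get(key)
    if cached is not None:
        return cached

    chars = [CODE_CHARS[c] for c in flat]
    if vc is None:
        best = min("".join(chars[t] for t in fmap) for _, fmap in _perm_maps(k))
        label = CanonicalLabel(k=k, matrix_block=best)
    else:
        vchars = [CODE_CHARS[c] for c in vc]
        best_pair = min(
            ("".join(vchars[i] for i in p), "".join(chars[t] for t in fmap))
            for p, fmap in _perm_maps(k)
        )
        label = CanonicalLabel(k=k, matrix_block=best_pair[1], vertex_block=best_pair[0])

    if len(_label_cache) >= _LABEL_CACHE_MAX:
        _label_cache.clear()
    _label_cache[key] = label
    return label


def decolor(label: CanonicalLabel) -> CanonicalLabel:
    """Project a colored label onto plain topology: nonzero codes become 1,
    the vertex block is dropped, and the result is re-canonicalized."""
    mat = label.to_matrix()
    return canonical_label(np.minimum(mat, 1))


def matrix_is_weakly_connected(adj) -> bool:
    """Weak connectivity of a directed adjacency matrix (self-loops ignored)."""
    mat = np.asarray(adj)
    k = mat.shape[0]
    if k <= 1:
        return True
    sym = (mat != 0) | (mat.T != 0)
    np.fill_diagonal(sym, False)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in np.nonzero(sym[u])[0]:
            if int(v) not in seen:
                seen.add(int(v))
                stack.append(int(v))
    return len(seen) == k


def enumerate_classes(
    k: int,
    num_colors: int = 1,
    allow_self_loops: bool = False,
    connected_only: bool = True,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> set[CanonicalLabel]:
    """All distinct motif classes of order k with up to ``num_colors`` edge colors.

    Generates every k x k matrix over codes 0..num_colors (diagonal forced 0
    unless ``allow_self_loops``), optionally filters to weakly connected, and
    collects the distinct canonical labels.  Exhaustive: intended for k <= 4.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = [(i, j) for i in range(k) for j in range(k) if allow_self_loops or i != j]
    total = (num_colors + 1) ** len(cells)
    if total > budget:
        raise BudgetError(f"{total} matrices exceed generation budget {budget}")
    classes: set[CanonicalLabel] = set()
    base = np.zeros((k, k), dtype=np.int64)
    for combo in itertools.product(range(num_colors + 1), repeat=len(cells)):
        for (i, j), c in zip(cells, combo):
            base[i, j] = c
        if connected_only and not matrix_is_weakly_connected(base):
            continue
        classes.add(canonical_label(base))
    return classes


def are_isomorphic_brute(
    adj_a,
    adj_b,
    vertex_colors_a: Sequence[int] | None = None,
    vertex_colors_b: Sequence[int] | None = None,
) -> bool:
    """Explicit bijection search: do the two colored digraphs match under some
    vertex permutation?  Independent of canonical labeling; test oracle."""
    a = np.asarray(adj_a, dtype=np.int64)
    b = np.asarray(adj_b, dtype=np.int64)
    if a.shape != b.shape:
        return False
    k = a.shape[0]
    vca = None if vertex_colors_a is None else list(vertex_colors_a)
    vcb = None if vertex_colors_b is None else list(vertex_colors_b)
    if (vca is None) != (vcb is None):
        return False
    for p in itertools.permutations(range(k)):
        if vca is not None and any(vca[p[i]] != vcb[i] for i in range(k)):
            continue
        if all(a[p[i], p[j]] == b[i, j] for i in range(k) for j in range(k)):
            return True
    return False
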