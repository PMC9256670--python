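"""Census post-processing: normalization, top-N summaries, cosine comparison.

Censuses from different connectomes (or different communities of one
connectome) are compared as vectors indexed by motif label.  Vectors are
aligned on the *union* of labels — a motif absent from one census counts as
zero there — so similarity is never inflated by discarding classes one side
lacks.  Cosine similarity on raw counts is scale-invariant, so raw counts
and relative frequencies give identical values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from connmotif.canonical import CanonicalLabel
from connmotif.errors import ComparisonError
from connmotif.kavosh import MotifCensus


def _aligned(censuses: Sequence[MotifCensus]) -> tuple[list[CanonicalLabel], np.ndarray]:
    labels = sorted({lab for c in censuses for lab in c.counts}, key=lambda l: l.text)
    mat = np.zeros((len(censuses), len(labels)), dtype=float)
    for i, c in enumerate(censuses):
        for j, lab in enumerate(labels):
            mat[i, j] = c.counts.get(lab, 0)
    return labels, mat


def cosine_similarity(a: MotifCensus, b: MotifCensus) -> float:
    """Cosine of the label-aligned count vectors of two censuses; in [0, 1]."""
    if a.k != b.k:
        raise ComparisonError(f"cannot compare censuses with k={a.k} and k={b.k}")
    if a.colored != b.colored:
        raise ComparisonError("cannot compare colored with colorless censuses")
    if a.total() == 0 or b.total() == 0:
        raise ComparisonError("cosine similarity undefined for an all-zero census")
    _, mat = _aligned([a, b])
    num = float(mat[0] @ mat[1])
    den = float(np.linalg.norm(mat[0]) * np.linalg.norm(mat[1]))
    return min(num / den, 1.0)


def relative_frequencies(a: MotifCensus) -> dict[CanonicalLabel, float]:
    """Counts divided by the census total; sums to 1."""
    total = a.total()
    if total == 0:
        raise ComparisonError("relative frequencies undefined for an empty census")
    return {lab: cnt / total for lab, cnt in a.counts.items()}


def top_n(a: MotifCensus, n: int) -> list[tuple[CanonicalLabel, int, float]]:
    """The n most common motifs: (label, count, proportion), descending count,
    ties broken by ascending label string."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = a.total()
    ranked = sorted(a.counts.items(), key=lambda kv: (-kv[1], kv[0].text))
    return [(lab, cnt, cnt / total if total else 0.0) for lab, cnt in ranked[:n]]


@dataclass(frozen=True)
class PairwiseSimilarity:
    """Symmetric cosine matrix over censuses, with the headline off-diagonal minimum."""

    matrix: np.ndarray
    min_offdiagonal: float


def pairwise_similarity_matrix(censuses: Sequence[MotifCensus]) -> PairwiseSimilarity:
    """All pairwise cosines; symmetric with unit diagonal."""
    if len(censuses) < 2:
        raise ComparisonError("need at least two censuses to compare")
    m = len(censuses)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = cosine_similarity(censuses[i], censuses[j])
    off = mat[~np.eye(m, dtype=bool)]
    return PairwiseSimilarity(matrix=mat, min_offdiagonal=float(off.min()))
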