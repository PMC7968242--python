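"""Cross-network gene distances, optimal matching, and alignment scores.

Local similarity between genes of two networks is the cosine distance of
their embedding vectors, rescaled to ``[0, 1]``::

    d(a, b) = 0.5 - 0.5 * <a, b> / (|a| |b|)

so 0 means identical direction, 0.5 orthogonal, 1 opposite.  The Hungarian
algorithm then produces the one-to-one gene matching with minimum total
distance; the mean matched distance is the *global distance* between the
networks (mean rather than sum, so differently sized networks remain
comparable).  Alignment accuracy against a known correspondence is the
*match fraction*: the proportion of matched pairs agreeing with the truth.

A permutation test checks that the anchored scaffolding really is tied
together: the mean matched distance across the landmark nodes is compared
with the same statistic over many random equal-size gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .anchoring import is_artificial
from .embedding import EmbeddingMatrix, lookup
from .walks import TokenMap

__all__ = [
    "DistanceMatrix",
    "AlignmentResult",
    "cosine_distance",
    "distance_matrix",
    "hungarian_match",
    "match_fraction",
    "anchor_consistency_test",
]


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Rescaled cosine distance between two non-zero vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance is undefined for zero vectors")
    d = 0.5 - 0.5 * float(a @ b) / (na * nb)
    return float(min(1.0, max(0.0, d)))


@dataclass
class DistanceMatrix:
    """All-pairs cosine distances between the genes of two networks."""

    row_genes: list
    col_genes: list
    D: np.ndarray  # (|row_genes|, |col_genes|), entries in [0, 1]
    row_tag: str = "network1"
    col_tag: str = "network2"

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.row_genes), len(self.col_genes)):
            raise ValueError("matrix shape does not match gene lists")

    def submatrix(self, rows: Sequence, cols: Sequence) -> "DistanceMatrix":
        ri = [self.row_genes.index(g) for g in rows]
        ci = [self.col_genes.index(g) for g in cols]
        return DistanceMatrix(
            list(rows), list(cols), self.D[np.ix_(ri, ci)],
            self.row_tag, self.col_tag,
        )


def distance_matrix(
    emb: EmbeddingMatrix,
    genes1: Sequence[str],
    genes2: Sequence[str],
    token_map: TokenMap,
    tag1: str,
    tag2: str,
    include_artificial: bool = False,
) -> DistanceMatrix:
    """Cosine-distance matrix between two gene lists of a joint embedding.

    Artificial dangling nodes are scaffolding and excluded by default;
    set ``include_artificial=True`` to keep them (e.g. for the anchor
    consistency diagnostic).
    """
    if not include_artificial:
        genes1 = [g for g in genes1 if not is_artificial(g)]
        genes2 = [g for g in genes2 if not is_artificial(g)]
    genes1 = [str(g) for g in genes1]
    genes2 = [str(g) for g in genes2]
    if not genes1 or not genes2:
        raise ValueError("gene lists must be non-empty")

    V1 = np.stack([lookup(emb, g, token_map, tag1) for g in genes1]).astype(float)
    V2 = np.stack([lookup(emb, g, token_map, tag2) for g in genes2]).astype(float)
    n1 = np.linalg.norm(V1, axis=1)
    n2 = np.linalg.norm(V2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero embedding vector encountered")
    sim = (V1 / n1[:, None]) @ (V2 / n2[:, None]).T
    D = np.clip(0.5 - 0.5 * sim, 0.0, 1.0)
    return DistanceMatrix(genes1, genes2, D, tag1, tag2)


@dataclass
class AlignmentResult:
    """Optimal one-to-one gene matching between two networks."""

    pairs: list  # (row gene, col gene, distance)
    global_distance: float
    unmatched: list  # surplus genes when the networks differ in size

    @property
    def mapping(self) -> dict:
        return {g1: g2 for g1, g2, _ in self.pairs}


def hungarian_match(dm: DistanceMatrix) -> AlignmentResult:
    """Minimum-total-distance assignment between the two gene sets.

    Rectangular matrices are handled by matching ``min(rows, cols)`` pairs
    and reporting the surplus genes as unmatched.  The global distance is
    the mean matched distance.
    """
    if dm.D.size == 0:
        raise ValueError("cannot match an empty distance matrix")
    rows, cols = linear_sum_assignment(dm.D)
    pairs = [
        (dm.row_genes[i], dm.col_genes[j], float(dm.D[i, j]))
        for i, j in zip(rows, cols)
    ]
    matched_rows = set(rows.tolist())
    matched_cols = set(cols.tolist())
    unmatched = [g for i, g in enumerate(dm.row_genes) if i not in matched_rows]
    unmatched += [g for j, g in enumerate(dm.col_genes) if j not in matched_cols]
    global_distance = float(np.mean([d for _, _, d in pairs]))
    return AlignmentResult(pairs, global_distance, unmatched)


def match_fraction(result: AlignmentResult, truth: Mapping[str, str]) -> float:
    """Fraction of matched pairs agreeing with a known correspondence.

    Pairs whose row gene has no entry in ``truth`` are left out of the
    denominator, so scaffolding or unannotated genes can be excluded by
    simply omitting them from the truth map.
    """
    evaluable = [(g1, g2) for g1, g2, _ in result.pairs if g1 in truth]
    if not evaluable:
        raise ValueError("truth map covers none of the matched genes")
    hits = sum(1 for g1, g2 in evaluable if truth[g1] == g2)
    return hits / len(evaluable)


def anchor_consistency_test(
    dm: DistanceMatrix,
    anchored_nodes: Sequence[str],
    n_random: int = 1000,
    set_size: int | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Permutation test: are the anchored landmarks closer than chance?

    The observed statistic is the mean cross-network distance of each node
    in ``anchored_nodes`` to its namesake (``D[g, g]``); the null
    distribution repeats this for ``n_random`` random gene sets of
    ``set_size`` (default: same size as the anchored list) drawn from the
    non-anchored genes present on both axes.  The p-value uses the add-one
    estimator ``(1 + #{null <= observed}) / (1 + n_random)`` and is never
    exactly zero.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    anchored = [str(g) for g in anchored_nodes]
    row_index = {g: i for i, g in enumerate(dm.row_genes)}
    col_index = {g: j for j, g in enumerate(dm.col_genes)}
    missing = [g for g in anchored if g not in row_index or g not in col_index]
    if missing:
        raise ValueError(f"anchored node(s) absent from the matrix: {missing[:5]}")
    if set_size is None:
        set_size = len(anchored)

    def paired_mean(genes):
        return float(np.mean([dm.D[row_index[g], col_index[g]] for g in genes]))

    observed = paired_mean(anchored)

    pool = sorted((set(row_index) & set(col_index)) - set(anchored))
    if set_size > len(pool):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(pool)} genes shared by "
            "both axes (after removing anchored nodes)"
        )
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_random)
    for r in range(n_random):
        sample = rng.choice(len(pool), size=set_size, replace=False)
        null_means[r] = paired_mean([pool[i] for i in sample])
    p_value = (1 + int(np.sum(null_means <= observed))) / (1 + n_random)
    return observed, null_means, p_value
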