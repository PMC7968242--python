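"""Spectral biclustering of the cross-network distance matrix.

The all-pairs cosine-distance matrix between two networks often has
*checkerboard* structure: groups of genes in one network that keep similar
distances to groups of genes in the other.  Spectral biclustering
partitions rows into ``n_row`` and columns into ``n_col`` clusters so that
each of the ``n_row x n_col`` Cartesian-product blocks is approximately
constant; every row gene therefore belongs to ``n_col`` biclusters and
every column gene to ``n_row``.  Blocks with low mean distance are the
conserved portions of the two networks; blocks with mean distance above
0.5 are "relatively distant" regions worth biological follow-up (their
ranked gene lists can be exported for external enrichment tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.cluster import SpectralBiclustering

from .alignment import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["BiclusterModel", "spectral_bicluster", "bicluster_summary"]

#: Mean-distance threshold flagging a bicluster as relatively distant.
DISTANT_THRESHOLD = 0.5


@dataclass
class BiclusterModel:
    """Checkerboard partition of a distance matrix."""

    n_row_clusters: int
    n_col_clusters: int
    row_labels: np.ndarray  # cluster index per row gene
    col_labels: np.ndarray  # cluster index per column gene


def spectral_bicluster(
    dm: DistanceMatrix,
    n_row: int = 5,
    n_col: int = 5,
    seed: int = 0,
) -> BiclusterModel:
    """Partition rows/columns of a distance matrix into a checkerboard.

    Degenerate (constant) matrices cannot be biclustered; they fall back
    to a single all-inclusive cluster with a logged warning.  The cluster
    counts are analysis choices; scanning a small grid of values and
    inspecting the block means is recommended.
    """
    n_rows, n_cols = dm.D.shape
    if not (1 <= n_row <= n_rows and 1 <= n_col <= n_cols):
        raise ValueError(
            f"cluster counts ({n_row}, {n_col}) must be within the matrix "
            f"shape ({n_rows}, {n_cols})"
        )
    if np.ptp(dm.D) == 0.0:
        logger.warning(
            "distance matrix is constant; falling back to a single bicluster"
        )
        return BiclusterModel(
            1, 1, np.zeros(n_rows, dtype=int), np.zeros(n_cols, dtype=int)
        )
    model = SpectralBiclustering(
        n_clusters=(n_row, n_col),
        method="log",
        random_state=seed,
    )
    model.fit(dm.D)
    return BiclusterModel(
        n_row, n_col,
        np.asarray(model.row_labels_, dtype=int),
        np.asarray(model.column_labels_, dtype=int),
    )


def bicluster_summary(
    dm: DistanceMatrix,
    model: BiclusterModel,
    annotations: Mapping[str, str] | None = None,
) -> list[dict]:
    """Summarise every bicluster, most conserved (lowest mean) first.

    Each record carries the block's row/column cluster indices, member
    genes, entry count, mean distance, a ``distant`` flag (mean > 0.5)
    and — if a gene -> label annotation map is given — the fraction of
    annotated member genes per label plus annotation coverage.
    """
    if len(model.row_labels) != len(dm.row_genes) or len(
        model.col_labels
    ) != len(dm.col_genes):
        raise ValueError("model labels do not match the distance matrix")

    records = []
    for r in range(model.n_row_clusters):
        row_idx = np.flatnonzero(model.row_labels == r)
        for c in range(model.n_col_clusters):
            col_idx = np.flatnonzero(model.col_labels == c)
            block = dm.D[np.ix_(row_idx, col_idx)]
            row_genes = [dm.row_genes[i] for i in row_idx]
            col_genes = [dm.col_genes[j] for j in col_idx]
            record = {
                "bicluster_id": f"r{r}c{c}",
                "row_cluster": r,
                "col_cluster": c,
                "size": int(block.size),
                "mean_distance": float(block.mean()) if block.size else float("nan"),
                "row_genes": row_genes,
                "col_genes": col_genes,
                "distant": bool(block.size and block.mean() > DISTANT_THRESHOLD),
            }
            if annotations is not None:
                members = row_genes + col_genes
                labelled = [annotations[g] for g in members if g in annotations]
                fractions = {}
                for label in labelled:
                    fractions[label] = fractions.get(label, 0) + 1
                total = len(labelled)
                record["annotation_fractions"] = {
                    label: count / total for label, count in sorted(fractions.items())
                } if total else {}
                record["annotated_members"] = total
                record["ignored_members"] = len(members) - total
            records.append(record)
    records.sort(key=lambda rec: (np.isnan(rec["mean_distance"]), rec["mean_distance"]))
    return records
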