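"""Construction of weighted gene co-expression networks (GCNs).

A GCN is an undirected :class:`networkx.Graph` whose nodes are gene IDs and
whose edge weights lie in ``[0, 1]``.  Weights come from the Pearson
correlation coefficient (PCC) of two genes' expression profiles, affinely
mapped from ``[-1, 1]`` onto ``[0, 1]`` so that negative co-expression is
preserved (as weight < 0.5) rather than discarded: ``w = 0.5 + 0.5 * PCC``.
Edges are created only for pairs whose *original* PCC clears a two-sided
threshold (``|PCC| >= 0.8`` by default), so a weight near 0 marks a strong
negative correlation, not a weak one.

Expression matrices are plain pandas DataFrames: genes on the index, samples
on the columns, normalized expression in the body.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "transform_correlation",
    "validate_expression",
    "build_gcn",
    "network_tag",
]


def transform_correlation(pcc):
    """Map a Pearson correlation from ``[-1, 1]`` onto ``[0, 1]``.

    Applies the affine transform ``0.5 + 0.5 * pcc``: perfect negative
    correlation maps to 0, no correlation to 0.5, perfect positive
    correlation to 1.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any value lies outside ``[-1, 1]`` (allowing a hair of floating
        point slop) or is not finite.
    """
    arr = np.asarray(pcc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("correlation values must be finite")
    if np.any(arr < -1.0 - 1e-12) or np.any(arr > 1.0 + 1e-12):
        raise ValueError("correlation values must lie in [-1, 1]")
    out = 0.5 + 0.5 * np.clip(arr, -1.0, 1.0)
    if np.isscalar(pcc) or np.ndim(pcc) == 0:
        return float(out)
    return out


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) and return it unchanged.

    Requirements: unique gene index, unique sample columns, all-finite
    numeric body.
    """
    if not isinstance(expr, pd.DataFrame):
        raise TypeError("expression matrix must be a pandas DataFrame")
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    return expr


def build_gcn(
    expr: pd.DataFrame,
    pcc_threshold: float = 0.8,
    tag: str = "network",
) -> nx.Graph:
    """Build a weighted co-expression network from an expression matrix.

    For every unordered gene pair the PCC across samples is computed; an
    edge is created iff ``|PCC| >= pcc_threshold`` and carries the
    transformed weight ``0.5 + 0.5 * PCC``.  Every gene becomes a node even
    if no edge survives thresholding, so downstream vocabularies cover the
    full gene set.

    Genes with zero variance have undefined correlations; they are kept as
    isolated nodes and a warning is logged.

    Parameters
    ----------
    expr
        Genes x samples DataFrame with at least 3 samples.
    pcc_threshold
        Two-sided threshold on the *original* PCC, in ``(0, 1]``.
    tag
        Label stored as ``graph.graph["tag"]`` identifying the network
        (species, tissue, replicate, ...).
    """
    validate_expression(expr)
    if expr.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {expr.shape[1]}")
    if not (0.0 < pcc_threshold <= 1.0):
        raise ValueError(f"pcc_threshold must be in (0, 1], got {pcc_threshold}")

    genes = [str(g) for g in expr.index]
    values = expr.to_numpy(dtype=float)

    variances = values.var(axis=1)
    constant = variances == 0.0
    if constant.any():
        bad = [genes[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "%d gene(s) with zero variance kept as isolated nodes: %s%s",
            len(bad), bad[:5], "..." if len(bad) > 5 else "",
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)

    graph = nx.Graph(tag=str(tag))
    graph.add_nodes_from(genes)

    iu, ju = np.triu_indices(len(genes), k=1)
    pcc = corr[iu, ju]
    keep = np.isfinite(pcc) & (np.abs(pcc) >= pcc_threshold)
    weights = transform_correlation(np.clip(pcc[keep], -1.0, 1.0))
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(w))
        for i, j, w in zip(iu[keep], ju[keep], weights)
    )
    return graph


def network_tag(network: nx.Graph) -> str:
    """Return the label a network was built with."""
    return str(network.graph.get("tag", "network"))
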