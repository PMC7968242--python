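"""Synthetic networks and expression data with known ground truth.

Two kinds of fixture are provided so every pipeline stage can be exercised
without external data:

* :func:`make_topology` builds the classic unit-weight benchmark graphs —
  line (path), circle (cycle) and cross (two equal paths sharing a center
  node) — whose self-alignment has a known answer (every gene matches
  itself).
* :func:`simulate_expression` draws a block-structured expression matrix:
  genes within a block share a latent Gaussian factor (expected pairwise
  correlation ``rho``), blocks are independent.  Thresholding its
  correlations yields networks of near-cliques, a minimal stand-in for the
  modular structure of real co-expression data.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["make_topology", "simulate_expression", "split_replicates"]

TOPOLOGY_KINDS = ("line", "circle", "cross")


def _gene_names(n: int) -> list[str]:
    return [f"g{i + 1}" for i in range(n)]


def make_topology(kind: str, n: int, tag: str | None = None) -> nx.Graph:
    """Build a synthetic benchmark network with unit edge weights.

    ``line``: path on ``n >= 3`` nodes (n-1 edges).
    ``circle``: cycle on ``n >= 3`` nodes (n edges, all degrees 2).
    ``cross``: two paths of ``(n+1)/2`` nodes sharing their middle node;
    requires odd ``n >= 5``; n-1 edges with exactly one degree-4 node.

    Node labels are synthetic gene IDs ``g1..gn``.
    """
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"kind must be one of {TOPOLOGY_KINDS}, got {kind!r}")
    if kind in ("line", "circle"):
        if n < 3:
            raise ValueError(f"{kind} topology needs n >= 3, got {n}")
    else:
        if n < 5 or n % 2 == 0:
            raise ValueError(f"cross topology needs odd n >= 5, got {n}")

    names = _gene_names(n)
    graph = nx.Graph(tag=str(tag) if tag is not None else kind)
    graph.add_nodes_from(names)

    if kind == "line":
        edges = [(names[i], names[i + 1]) for i in range(n - 1)]
    elif kind == "circle":
        edges = [(names[i], names[(i + 1) % n]) for i in range(n)]
    else:
        # Two paths of m nodes each crossing at the shared middle node of
        # the first path: path A is g1..gm, path B is gm+1.. with the
        # center spliced in.
        m = (n + 1) // 2
        center = m // 2
        path_a = names[:m]
        path_b = names[m:]
        path_b = path_b[:center] + [path_a[center]] + path_b[center:]
        edges = [(path_a[i], path_a[i + 1]) for i in range(m - 1)]
        edges += [(path_b[i], path_b[i + 1]) for i in range(m - 1)]

    graph.add_edges_from(edges, weight=1.0)
    return graph


def simulate_expression(
    n_blocks: int,
    genes_per_block: int,
    n_samples: int,
    rho: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate a block-correlated expression matrix.

    Each block ``b`` has a latent factor ``z_b ~ N(0, 1)`` per sample; gene
    ``g`` in block ``b`` observes ``sqrt(rho) * z_b + sqrt(1 - rho) *
    noise_sd * eps`` with independent ``eps ~ N(0, 1)``.  At
    ``noise_sd = 1`` the expected within-block pairwise correlation is
    exactly ``rho``; across blocks it is 0.  ``noise_sd -> 0`` drives
    within-block correlations to 1.

    Deterministic given ``seed``.  Returns genes x samples DataFrame with
    genes ``g1..g{n_blocks * genes_per_block}`` and samples ``s1..s{n}``.
    """
    if n_blocks < 1 or genes_per_block < 1 or n_samples < 1:
        raise ValueError("n_blocks, genes_per_block and n_samples must be positive")
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd}")

    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_blocks, n_samples))
    n_genes = n_blocks * genes_per_block
    noise = rng.standard_normal((n_genes, n_samples))
    block_of_gene = np.repeat(np.arange(n_blocks), genes_per_block)
    values = (
        np.sqrt(rho) * factors[block_of_gene]
        + np.sqrt(1.0 - rho) * noise_sd * noise
    )
    return pd.DataFrame(
        values,
        index=_gene_names(n_genes),
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )


def split_replicates(expr: pd.DataFrame, k: int, seed: int) -> list[pd.DataFrame]:
    """Split samples into ``k`` disjoint equally sized subsets.

    Samples are shuffled reproducibly, then cut into ``k`` parts of
    ``n_samples // k`` columns each (a remainder is dropped so replicates
    are balanced).  ``k = 1`` returns the input unchanged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = expr.shape[1]
    if k == 1:
        return [expr]
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} non-empty parts")
    per = n // k
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [
        expr.iloc[:, np.sort(order[i * per:(i + 1) * per])]
        for i in range(k)
    ]
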