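"""Anchor genes and shared synthetic dangling structures.

Networks embedded separately live in unrelated coordinate systems.  To make
them jointly embeddable, a set of *anchor genes* present in every network
(typically drawn from conserved cellular-homeostasis processes, whose
network position is expected to be stable) each receive a small synthetic
*dangling structure*: a sparse random connected graph of ``gamma``
artificial nodes with unit edge weights.  The *identical* structure — same
artificial node IDs, same edges — is attached to the matching anchor in
every compared network, giving the walk corpora a shared vocabulary of
landmark tokens that ties the embedding spaces together and breaks graph
symmetries.

Structures are kept sparse (default 15% of potential edges, with a repair
step guaranteeing connectivity) because nodes of a dense graph are
topologically interchangeable and would make poor landmarks; distinct
anchors get pairwise distinct structures so landmarks are distinguishable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ARTIFICIAL_PREFIX",
    "AnchorSet",
    "DanglingStructure",
    "is_artificial",
    "select_anchors",
    "min_required_sparsity",
    "generate_dangling",
    "attach_danglings",
]

#: Reserved namespace for artificial node IDs; real gene IDs must not use it.
ARTIFICIAL_PREFIX = "DANGLE::"


def is_artificial(node: str) -> bool:
    """True for synthetic dangling-structure nodes."""
    return str(node).startswith(ARTIFICIAL_PREFIX)


@dataclass(frozen=True)
class AnchorSet:
    """Ordered, duplicate-free list of anchor gene IDs."""

    anchors: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.anchors)) != len(self.anchors):
            raise ValueError("anchor genes must be unique")

    def __iter__(self):
        return iter(self.anchors)

    def __len__(self):
        return len(self.anchors)


@dataclass(frozen=True)
class DanglingStructure:
    """A sparse connected graph of artificial nodes tied to one anchor.

    All internal edges and the single attachment edge carry weight 1.0.
    """

    gamma: int
    nodes: tuple[str, ...]
    edges: tuple  # sorted tuple of (u, v) node-ID pairs
    attachment_anchor: str
    attachment_node: str

    @property
    def attachment_edge(self) -> tuple[str, str]:
        return (self.attachment_anchor, self.attachment_node)

    def edge_signature(self) -> frozenset:
        """Canonical edge-set identity used for uniqueness checks."""
        return frozenset(frozenset(e) for e in self.edges)


def select_anchors(
    candidates: Sequence[str],
    networks: Sequence[nx.Graph],
    n_anchors: int,
    seed: int,
    strategy: str = "random",
) -> AnchorSet:
    """Choose ``n_anchors`` anchor genes common to all networks.

    Candidates are intersected with the node set of every network, then
    chosen by one of two strategies:

    * ``"random"`` — uniform sampling without replacement (reproducible
      given ``seed``).
    * ``"spread"`` — greedy farthest-point placement over shortest-path
      distance in the first network: the landmarks end up spread across
      the graph, which is what lets them break global symmetries (two
      anchors on the same arm of a symmetric structure leave the rest of
      the graph free to flip).  Isolated candidates are avoided, nodes in
      different connected components count as maximally far apart, and
      ties are broken by degree, deterministically.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if n_anchors < 1:
        raise ValueError(f"n_anchors must be >= 1, got {n_anchors}")
    if strategy not in ("random", "spread"):
        raise ValueError(f"unknown strategy {strategy!r}")
    eligible = [str(c) for c in dict.fromkeys(candidates)]
    for net in networks:
        nodes = set(net.nodes)
        eligible = [c for c in eligible if c in nodes]
    if len(eligible) < n_anchors:
        raise ValueError(
            f"only {len(eligible)} candidate gene(s) are present in every "
            f"network; {n_anchors} anchors requested "
            f"(short by {n_anchors - len(eligible)})"
        )

    if strategy == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(eligible), size=n_anchors, replace=False)
        return AnchorSet(tuple(eligible[i] for i in np.sort(chosen)))

    graph = networks[0]
    connected = [c for c in eligible if graph.degree(c) > 0]
    pool = sorted(connected or eligible)
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    far = max((max(d.values(), default=0) for d in dist.values()), default=0) + 1

    def pair_dist(u: str, v: str) -> int:
        return dist.get(u, {}).get(v, far)

    ecc = {u: max(dist.get(u, {}).values(), default=0) for u in pool}
    first = max(pool, key=lambda u: (ecc[u], graph.degree(u), u))
    chosen = [first]
    while len(chosen) < n_anchors:
        nxt = max(
            (u for u in pool if u not in chosen),
            key=lambda u: (
                min(pair_dist(u, c) for c in chosen), graph.degree(u), u
            ),
        )
        chosen.append(nxt)
    return AnchorSet(tuple(sorted(chosen)))


def min_required_sparsity(n: int) -> float:
    """Fraction of the n(n-1)/2 potential edges needed for connectivity.

    A connected graph on ``n`` nodes needs at least ``n - 1`` edges, and
    ``(n - 1) / (n (n - 1) / 2) = 2 / n``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return 2.0 / n


def generate_dangling(
    gamma: int,
    sparsity: float,
    anchor: str,
    seed: int,
    node_namespace: str | None = None,
) -> DanglingStructure:
    """Generate one random sparse connected dangling structure.

    ``round(sparsity * gamma * (gamma - 1) / 2)`` distinct internal edges
    are drawn uniformly; if the result is disconnected, random edges
    joining distinct components are added until it is connected.  One
    attachment edge runs from the anchor to a uniformly chosen structure
    node.  All weights are 1.0.  Deterministic given ``seed``.
    """
    if gamma < 2:
        raise ValueError(f"gamma must be >= 2, got {gamma}")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")

    rng = np.random.default_rng(seed)
    namespace = node_namespace if node_namespace is not None else str(anchor)
    names = tuple(f"{ARTIFICIAL_PREFIX}{namespace}::d{i + 1}" for i in range(gamma))

    n_potential = gamma * (gamma - 1) // 2
    n_draw = int(round(sparsity * n_potential))
    iu, ju = np.triu_indices(gamma, k=1)
    picked = rng.choice(n_potential, size=n_draw, replace=False) if n_draw else []
    # keep edge containers sorted: iteration order must not depend on the
    # interpreter's string-hash seed or downstream runs lose reproducibility
    edges = sorted({(names[iu[p]], names[ju[p]]) for p in picked})

    graph = nx.Graph()
    graph.add_nodes_from(names)
    graph.add_edges_from(edges)
    while nx.number_connected_components(graph) > 1:
        comps = sorted(sorted(c) for c in nx.connected_components(graph))
        a, b = rng.choice(len(comps), size=2, replace=False)
        u = comps[a][rng.integers(len(comps[a]))]
        v = comps[b][rng.integers(len(comps[b]))]
        edges = sorted(set(edges) | {tuple(sorted((u, v)))})
        graph.add_edge(u, v)

    attachment_node = names[rng.integers(gamma)]
    return DanglingStructure(
        gamma=gamma,
        nodes=names,
        edges=tuple(edges),
        attachment_anchor=str(anchor),
        attachment_node=attachment_node,
    )


def attach_danglings(
    networks: Sequence[nx.Graph],
    anchors: AnchorSet,
    gamma: int = 8,
    sparsity: float = 0.15,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[list[nx.Graph], list[DanglingStructure]]:
    """Attach one shared dangling structure per anchor to every network.

    For each anchor a single structure is generated and the identical copy
    (same artificial node IDs, same edges, weight 1.0 throughout, one
    attachment edge to the anchor) is added to every network.  Structures
    for different anchors are regenerated with fresh sub-seeds until their
    edge sets differ, so all landmarks are distinguishable.

    Returns augmented copies of the networks plus the generated structures;
    inputs are not modified.
    """
    for net in networks:
        nodes = set(net.nodes)
        missing = [a for a in anchors if a not in nodes]
        if missing:
            raise ValueError(
                f"anchor(s) {missing} absent from network "
                f"{net.graph.get('tag', '?')!r}"
            )
        bad = [n for n in nodes if is_artificial(n)]
        if bad:
            raise ValueError(
                f"input network already contains reserved "
                f"{ARTIFICIAL_PREFIX!r} node IDs: {bad[:3]}"
            )

    seq = np.random.SeedSequence(seed)
    structures: list[DanglingStructure] = []
    seen_signatures: set[frozenset] = set()
    for anchor in anchors:
        for attempt in range(max_retries):
            child = seq.spawn(1)[0]
            struct = generate_dangling(
                gamma, sparsity, anchor,
                seed=child.generate_state(1)[0] % (2**31),
            )
            sig = struct.edge_signature()
            # Signatures are on labelled nodes, which differ between
            # anchors by namespace; compare the unlabelled edge pattern.
            pattern = frozenset(
                frozenset(name.rsplit("::", 1)[1] for name in e)
                for e in sig
            )
            if pattern not in seen_signatures:
                seen_signatures.add(pattern)
                structures.append(struct)
                break
        else:
            raise RuntimeError(
                f"could not generate {len(anchors)} pairwise distinct "
                f"dangling structures with gamma={gamma}; increase gamma"
            )

    augmented = []
    for net in networks:
        out = copy.deepcopy(net)
        for struct in structures:
            out.add_nodes_from(struct.nodes)
            out.add_edges_from((tuple(e) for e in struct.edges), weight=1.0)
            out.add_edge(*struct.attachment_edge, weight=1.0)
        augmented.append(out)
    return augmented, structures
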