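"""Weighted random walks over GCNs and gene <-> integer token translation.

Edge weights become transition probabilities by row-normalisation: from node
``i`` the walk moves to neighbour ``j`` with probability
``w_ij / sum_k w_ik``, so strongly co-expressed genes are visited together
often.  Walks are first-order (immediate backtracking allowed) and stop
early at a node with no positive-weight edge; an isolated node yields
length-1 walks of its own token.

Gene IDs are translated to integers before walking.  The *tying policy*
decides which node classes share tokens across networks: under the default
``dangling-only`` policy every real gene of network *k* gets a token unique
to that network while every artificial dangling node maps to one token
shared by all networks — the shared landmarks through which a single
skip-gram model places both networks in one space.  ``dangling-anchors``
additionally shares the anchor genes' tokens.

Walks from all networks are pooled into one shuffled corpus (stored as a
padded int32 matrix) ready for single-model training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from .anchoring import ARTIFICIAL_PREFIX, is_artificial
from .gcn_build import network_tag

__all__ = [
    "TokenMap",
    "WalkCorpus",
    "build_token_map",
    "transition_probabilities",
    "generate_walks",
]

TYING_POLICIES = ("dangling-only", "dangling-anchors")

#: Padding value in the corpus token matrix (walks shorter than walk_length).
PAD = -1


@dataclass(frozen=True)
class TokenMap:
    """Bidirectional gene <-> integer token translation.

    Keys of ``forward`` are either plain node IDs (token shared by all
    networks: artificial nodes, plus anchors under ``dangling-anchors``)
    or ``"<tag>::<gene>"`` for network-private gene tokens.
    """

    forward: dict[str, int]
    tying_policy: str = "dangling-only"
    anchors: frozenset = frozenset()

    @property
    def backward(self) -> dict[int, str]:
        return {tok: key for key, tok in self.forward.items()}

    def __len__(self) -> int:
        return len(self.forward)

    def is_shared(self, node: str) -> bool:
        """True if this node's token is common to all networks."""
        return is_artificial(node) or (
            self.tying_policy == "dangling-anchors" and node in self.anchors
        )

    def key(self, tag: str, node: str) -> str:
        return node if self.is_shared(node) else f"{tag}::{node}"

    def token(self, tag: str, node: str) -> int:
        try:
            return self.forward[self.key(tag, node)]
        except KeyError:
            raise KeyError(
                f"node {node!r} of network {tag!r} is not in the token map"
            ) from None

    def node(self, token: int) -> str:
        """Invert a token to its key (strip a tag prefix for private genes)."""
        return self.backward[token]

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "tying_policy": self.tying_policy,
            "anchors": sorted(self.anchors),
            "forward": self.forward,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TokenMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            forward={k: int(v) for k, v in payload["forward"].items()},
            tying_policy=payload["tying_policy"],
            anchors=frozenset(payload["anchors"]),
        )


def build_token_map(
    networks: Sequence[nx.Graph],
    tying_policy: str = "dangling-only",
    anchors: Iterable[str] = (),
) -> TokenMap:
    """Assign integer tokens 0..V-1 to the nodes of the given networks.

    Shared classes (artificial dangling nodes; anchors too under the
    ``dangling-anchors`` policy) receive one token across all networks;
    every other gene gets a network-private token.  Deterministic: tokens
    follow sorted key order.
    """
    if tying_policy not in TYING_POLICIES:
        raise ValueError(f"tying_policy must be one of {TYING_POLICIES}")
    anchor_set = frozenset(str(a) for a in anchors)
    probe = TokenMap({}, tying_policy, anchor_set)

    keys = set()
    for net in networks:
        tag = network_tag(net)
        for node in net.nodes:
            node = str(node)
            if "::" in node and not is_artificial(node):
                raise ValueError(
                    f"gene ID {node!r} collides with the reserved "
                    "'::' token-key namespace"
                )
            keys.add(probe.key(tag, node))
    forward = {key: tok for tok, key in enumerate(sorted(keys))}
    return TokenMap(forward, tying_policy, anchor_set)


def transition_probabilities(network: nx.Graph) -> dict:
    """Per-node transition tables: neighbour list plus probabilities.

    ``P(j | i) = w_ij / sum_k w_ik`` over positive-weight incident edges.
    Nodes whose incident edges all have zero weight (or that are isolated)
    get an empty table.
    """
    tables = {}
    for node in network.nodes:
        nbrs, weights = [], []
        # sorted so tables do not depend on edge insertion order
        for other, attrs in sorted(network[node].items(), key=lambda kv: str(kv[0])):
            w = float(attrs.get("weight", 1.0))
            if w < 0:
                raise ValueError(f"negative edge weight on ({node}, {other})")
            if w > 0:
                nbrs.append(other)
                weights.append(w)
        if nbrs:
            probs = np.asarray(weights, dtype=float)
            probs /= probs.sum()
            tables[node] = (nbrs, probs)
        else:
            tables[node] = ([], np.empty(0))
    return tables


@dataclass
class WalkCorpus:
    """Pooled random-walk corpus from one or more networks.

    ``tokens`` is an ``(n_walks, walk_length)`` int32 matrix padded with
    :data:`PAD`; ``lengths`` gives each walk's true length and
    ``origin_network`` the tag of the network it was started in.
    """

    tokens: np.ndarray
    lengths: np.ndarray
    origin_network: np.ndarray  # array of tags (object/str), one per walk
    walk_length: int
    walks_per_node: int

    @property
    def n_walks(self) -> int:
        return self.tokens.shape[0]

    @property
    def walks(self) -> Iterator[list[int]]:
        """Iterate walks as plain token lists (padding stripped)."""
        for row, ln in zip(self.tokens, self.lengths):
            yield [int(t) for t in row[:ln]]

    def vocabulary(self) -> np.ndarray:
        """Sorted distinct tokens appearing in the corpus."""
        flat = self.tokens[self.tokens != PAD]
        return np.unique(flat)

    def save(self, path: str | Path) -> None:
        """Write one space-separated walk per line."""
        with open(path, "w") as fh:
            for walk in self.walks:
                fh.write(" ".join(map(str, walk)) + "\n")


def _csr_tables(network: nx.Graph, nodes: list, node_index: dict):
    """Flatten transition tables to CSR arrays for vectorised stepping.

    ``key[e] = source_node_index + cumulative_probability`` lets one global
    ``searchsorted`` resolve a uniform draw for every active walk at once.
    """
    tables = transition_probabilities(network)
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    nbr_chunks, key_chunks = [], []
    for i, node in enumerate(nodes):
        nbrs, probs = tables[node]
        indptr[i + 1] = indptr[i] + len(nbrs)
        if nbrs:
            nbr_chunks.append(np.fromiter(
                (node_index[x] for x in nbrs), dtype=np.int64, count=len(nbrs)
            ))
            cum = np.cumsum(probs)
            cum[-1] = 1.0
            key_chunks.append(i + cum)
    nbr = np.concatenate(nbr_chunks) if nbr_chunks else np.empty(0, np.int64)
    key = np.concatenate(key_chunks) if key_chunks else np.empty(0, float)
    return indptr, nbr, key


def _walk_network(
    network: nx.Graph,
    walks_per_node: int,
    walk_length: int,
    token_map: TokenMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    tag = network_tag(network)
    nodes = sorted(str(n) for n in network.nodes)
    node_index = {n: i for i, n in enumerate(nodes)}
    tokens_of = np.fromiter(
        (token_map.token(tag, n) for n in nodes), dtype=np.int32, count=len(nodes)
    )
    indptr, nbr, key = _csr_tables(network, nodes, node_index)
    deg = np.diff(indptr)

    n_walks = len(nodes) * walks_per_node
    cur = np.repeat(np.arange(len(nodes), dtype=np.int64), walks_per_node)
    out = np.full((n_walks, walk_length), PAD, dtype=np.int32)
    lengths = np.ones(n_walks, dtype=np.int32)
    out[:, 0] = tokens_of[cur]

    alive = deg[cur] > 0
    for step in range(1, walk_length):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        # value in [v, v+1) indexes into node v's cumulative segment
        flat = np.searchsorted(key, cur[idx] + u, side="right")
        cur[idx] = nbr[flat]
        out[idx, step] = tokens_of[cur[idx]]
        lengths[idx] = step + 1
        alive[idx] = deg[cur[idx]] > 0
    return out, lengths


def generate_walks(
    networks: Sequence[nx.Graph],
    walks_per_node: int,
    walk_length: int,
    token_map: TokenMap,
    seed: int,
) -> WalkCorpus:
    """Generate the pooled, shuffled walk corpus from all networks.

    ``walks_per_node`` first-order weighted random walks of at most
    ``walk_length`` tokens start from every node of every network (1000
    per node with a single training epoch is the default regime: corpus
    size, not epoch count, carries representation quality).  The pooled
    corpus is shuffled under ``seed`` so the single downstream model sees
    the networks interleaved.  Deterministic given ``seed``.
    """
    if walks_per_node < 1 or walk_length < 1:
        raise ValueError("walks_per_node and walk_length must be >= 1")
    rng = np.random.default_rng(seed)
    chunks, length_chunks, tag_chunks = [], [], []
    for net in networks:
        toks, lens = _walk_network(net, walks_per_node, walk_length, token_map, rng)
        chunks.append(toks)
        length_chunks.append(lens)
        tag_chunks.append(np.full(toks.shape[0], network_tag(net), dtype=object))
    tokens = np.concatenate(chunks)
    lengths = np.concatenate(length_chunks)
    tags = np.concatenate(tag_chunks)
    order = rng.permutation(tokens.shape[0])
    return WalkCorpus(
        tokens=tokens[order],
        lengths=lengths[order],
        origin_network=tags[order],
        walk_length=walk_length,
        walks_per_node=walks_per_node,
    )
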