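"""Skip-gram embedding of the pooled walk corpus.

Walks are sentences and gene tokens are words: a skip-gram model with
negative sampling (SGNS) learns, for every token, a vector whose inner
products with the context vectors predict which tokens co-occur within a
small window of it in the walks — i.e. which genes sit close together in
the networks.  Because walks from all networks pass through the shared
dangling-landmark tokens, a single model places the genes of every
network in one space where cross-network distances are meaningful.

Training is deterministic and full-batch: the corpus is scanned once (one
epoch) to accumulate window-weighted co-occurrence counts, and the exact
expected SGNS loss defined by those counts is then minimised by momentum
gradient descent.  Three details make the joint space actually joint:

* negative-sampling mass is computed per *origin network* — a walk's
  negatives come from its own network's unigram^0.75 distribution — so
  inner products between genes of different networks are unconstrained
  by the data (they never co-occur, and they are never negatives of one
  another either);
* an annealed ridge penalty selects, among the many factorizations that
  fit each network individually, the minimum-norm one, which is tied
  across networks through the shared dangling tokens;
* the factors start at zero except the shared dangling rows (random,
  seeded), so the optimization follows the symmetric trajectory and
  structure propagates outward from the landmarks.

The embedding dimension should stay at or below the rank the shared
landmarks can pin (a handful of strong directions per anchor); dimensions
beyond that rank are free to rotate independently per network, which
silently destroys cross-network comparability while leaving each network's
internal geometry intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .walks import PAD, TokenMap, WalkCorpus

__all__ = ["EmbeddingMatrix", "train_embeddings", "lookup"]

#: Ridge penalty schedule as (penalty, iterations) stages: strong early
#: stages pull the networks into the shared minimum-norm solution; later
#: stages release the penalty to restore distance discrimination without
#: leaving that basin.  The final weakest stage is kept short — unpinned
#: directions drift if it runs long.
DEFAULT_LAMBDA_SCHEDULE = (
    (1.0, 1000), (0.3, 1000), (0.1, 1000), (0.03, 1000), (0.01, 500),
)
DEFAULT_ITERS_PER_STAGE = 1000
_LOGIT_CLIP = 30.0


@dataclass
class EmbeddingMatrix:
    """Learned token vectors, one row per vocabulary token.

    ``vectors[t]`` is the vector of token ``t``; tokens are the contiguous
    integers a :class:`~coexalign.walks.TokenMap` assigns, so the map's
    keys index rows directly.
    """

    vectors: np.ndarray  # (vocab_size, N) float32
    training_meta: dict = field(default_factory=dict)

    @property
    def n_dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def vocabulary(self) -> np.ndarray:
        return np.arange(self.vectors.shape[0])

    def save(self, path: str | Path, token_map: TokenMap | None = None) -> None:
        """Persist as TSV (token key, v1..vN) plus a JSON meta sidecar."""
        path = Path(path)
        backward = token_map.backward if token_map is not None else {}
        with open(path, "w") as fh:
            for tok, row in enumerate(self.vectors):
                key = backward.get(tok, str(tok))
                fh.write(key + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
        meta = dict(self.training_meta)
        meta["n_dim"] = int(self.n_dim)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )


def _cooccurrence(corpus: WalkCorpus, vocab_size: int, window: int):
    """Window-weighted co-occurrence counts plus per-network row masses.

    A pair at offset ``d`` inside a walk counts ``(window + 1 - d) /
    window``, the expected weight under word2vec's uniformly shrunk
    dynamic window.  Returns the symmetric count matrix ``C`` and, per
    origin network, each token's total positive-pair mass (the basis of
    the expected negative-sampling terms) and center-occurrence counts
    (the basis of the noise distribution).
    """
    tags = sorted(set(corpus.origin_network))
    tag_index = {t: i for i, t in enumerate(tags)}
    origin = np.fromiter(
        (tag_index[t] for t in corpus.origin_network), dtype=np.int64,
        count=corpus.n_walks,
    )
    tokens = corpus.tokens
    valid = tokens != PAD

    C = np.zeros((vocab_size, vocab_size))
    row_mass = np.zeros((len(tags), vocab_size))
    center_counts = np.zeros((len(tags), vocab_size))
    for k in range(len(tags)):
        sel = origin == k
        t = tokens[sel]
        center_counts[k] = np.bincount(
            t[valid[sel]].ravel(), minlength=vocab_size
        )
    for d in range(1, window + 1):
        if d >= tokens.shape[1]:
            break
        w = (window + 1 - d) / window
        a = tokens[:, :-d]
        b = tokens[:, d:]
        mask = valid[:, :-d] & valid[:, d:]
        for k in range(len(tags)):
            sel = origin == k
            m = mask[sel]
            ai = a[sel][m].astype(np.int64)
            bi = b[sel][m].astype(np.int64)
            pair = np.bincount(
                ai * vocab_size + bi, minlength=vocab_size * vocab_size
            ).reshape(vocab_size, vocab_size) * w
            C += pair + pair.T
            row_mass[k] += pair.sum(axis=1) + pair.sum(axis=0)
    return C, row_mass, center_counts


def _expected_negatives(
    row_mass: np.ndarray, center_counts: np.ndarray, negative: int
) -> np.ndarray:
    """Expected negative-sampling weight for every (token, noise) pair.

    Each positive pair of a walk from network ``k`` contributes
    ``negative`` draws from that network's unigram^0.75 distribution, so
    ``Neg[w, c] = negative * sum_k row_mass_k[w] * P_k(c)``.
    """
    V = row_mass.shape[1]
    Neg = np.zeros((V, V))
    for k in range(row_mass.shape[0]):
        p = center_counts[k] ** 0.75
        total = p.sum()
        if total > 0:
            Neg += np.outer(negative * row_mass[k], p / total)
    return Neg


def train_embeddings(
    corpus: WalkCorpus,
    n_dim: int = 6,
    window: int = 5,
    epochs: int = 1,
    seed: int = 0,
    negative: int = 5,
    token_map: TokenMap | None = None,
    vocab_size: int | None = None,
    lambda_schedule: tuple = DEFAULT_LAMBDA_SCHEDULE,
    iters_per_stage: int = DEFAULT_ITERS_PER_STAGE,
    learning_rate: float = 0.3,
    momentum: float = 0.9,
) -> EmbeddingMatrix:
    """Train SGNS vectors over a walk corpus.

    Every token in the corpus receives a vector (no minimum count — every
    gene must be embedded; genes with no co-occurrences at all, i.e.
    isolated nodes, end up with a tiny seeded random vector carrying no
    information).  The corpus is scanned ``epochs`` times when
    accumulating co-occurrence statistics; the default single pass over a
    deliberately large corpus is the intended regime.  Fully
    deterministic given the corpus and ``seed``.

    Passing the ``token_map`` enables the landmark-seeded initialization
    (recommended whenever shared dangling tokens are present).

    Raises
    ------
    ValueError
        If the corpus is empty or contains a token outside the vocabulary.
    """
    if n_dim < 2:
        raise ValueError(f"n_dim must be >= 2, got {n_dim}")
    if epochs < 1:
        raise ValueError(f"epochs must be >= 1, got {epochs}")
    if corpus.n_walks == 0:
        raise ValueError("corpus is empty")
    max_token = int(corpus.tokens.max())
    if vocab_size is None:
        vocab_size = (
            len(token_map) if token_map is not None else max_token + 1
        )
    if max_token >= vocab_size:
        raise ValueError(
            f"corpus token {max_token} is outside the vocabulary "
            f"(size {vocab_size})"
        )

    C, row_mass, center_counts = _cooccurrence(corpus, vocab_size, window)
    if epochs > 1:
        C = C * epochs
        row_mass = row_mass * epochs
    Neg = _expected_negatives(row_mass, center_counts, negative)

    rng = np.random.default_rng(seed)
    shared = np.zeros(vocab_size, dtype=bool)
    if token_map is not None:
        for key, tok in token_map.forward.items():
            if token_map.is_shared(key):
                shared[tok] = True
    if token_map is not None and shared.any():
        # landmark-seeded start: only shared rows carry random structure
        U = np.zeros((vocab_size, n_dim))
        W = np.zeros((vocab_size, n_dim))
        U[shared] = rng.standard_normal((int(shared.sum()), n_dim)) * 0.1
        W[shared] = rng.standard_normal((int(shared.sum()), n_dim)) * 0.1
    else:
        U = (rng.random((vocab_size, n_dim)) - 0.5) / n_dim
        W = (rng.random((vocab_size, n_dim)) - 0.5) / n_dim

    scale = (C.sum() + Neg.sum()) / vocab_size
    if scale == 0:
        raise ValueError("corpus contains no co-occurrence pairs")
    stages = [
        (float(stage[0]), int(stage[1])) if isinstance(stage, (tuple, list))
        else (float(stage), int(iters_per_stage))
        for stage in lambda_schedule
    ]
    vel_u = np.zeros_like(U)
    vel_w = np.zeros_like(W)
    for lam, n_iters in stages:
        for _ in range(n_iters):
            S = U @ W.T
            P = 1.0 / (1.0 + np.exp(-np.clip(S, -_LOGIT_CLIP, _LOGIT_CLIP)))
            dS = (C * (P - 1.0) + Neg * P) / scale
            grad_u = dS @ W + lam * U
            grad_w = dS.T @ U + lam * W
            vel_u = momentum * vel_u - learning_rate * grad_u
            vel_w = momentum * vel_w - learning_rate * grad_w
            U += vel_u
            W += vel_w

    # isolated tokens (no pairs, no gradient) get an uninformative but
    # non-zero vector so cosine distances stay defined
    dead = np.linalg.norm(U, axis=1) < 1e-12
    if dead.any():
        U[dead] = rng.standard_normal((int(dead.sum()), n_dim)) * 1e-6

    meta = {
        "n_dim": int(n_dim),
        "window": int(window),
        "epochs": int(epochs),
        "negative": int(negative),
        "lambda_schedule": [[lam, n] for lam, n in stages],
        "learning_rate": float(learning_rate),
        "momentum": float(momentum),
        "seed": int(seed),
        "n_walks": int(corpus.n_walks),
        "walk_length": int(corpus.walk_length),
        "walks_per_node": int(corpus.walks_per_node),
    }
    return EmbeddingMatrix(
        vectors=U.astype(np.float32), training_meta=meta
    )


def lookup(
    emb: EmbeddingMatrix,
    gene: str,
    token_map: TokenMap,
    tag: str | None = None,
) -> np.ndarray:
    """Return the embedding vector of a gene.

    ``tag`` names the network the gene belongs to; it may be omitted for
    nodes whose token is shared across networks (dangling nodes, and
    anchors under the ``dangling-anchors`` policy).
    """
    if token_map.is_shared(gene):
        token = token_map.forward[gene]
    else:
        if tag is None:
            raise KeyError(
                f"gene {gene!r} has a network-private token; pass tag="
            )
        token = token_map.token(tag, gene)
    if token >= emb.vectors.shape[0]:
        raise KeyError(f"token {token} for gene {gene!r} has no embedding row")
    return emb.vectors[token]
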