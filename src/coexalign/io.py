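"""File formats: expression tables, edge lists, distances, alignments.

Everything is plain text.  Expression matrices are TSV/CSV with gene IDs in
the first column and sample IDs in the header.  Networks travel as
3-column weighted edge lists plus a sidecar node list (``<path>.nodes``) so
isolated genes survive a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AlignmentResult, DistanceMatrix
from .gcn_build import network_tag, validate_expression

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_alignment",
    "write_corpus",
    "read_corpus",
    "read_embedding",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression table (TSV, or CSV by suffix)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    expr = pd.read_csv(path, sep=sep, index_col=0)
    expr.index = expr.index.map(str)
    expr.columns = expr.columns.map(str)
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    expr.to_csv(path, sep=sep)


def _nodes_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".nodes")


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write ``gene_a TAB gene_b TAB weight`` plus a ``.nodes`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v, attrs in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{attrs.get('weight', 1.0):.10g}\n")
    with open(_nodes_sidecar(path), "w") as fh:
        fh.write(f"# tag: {network_tag(network)}\n")
        for node in sorted(network.nodes):
            fh.write(f"{node}\n")


def read_edge_list(path: str | Path, tag: str | None = None) -> nx.Graph:
    """Read a weighted edge list; the ``.nodes`` sidecar, if present,
    restores isolated nodes and the stored tag."""
    path = Path(path)
    sidecar = _nodes_sidecar(path)
    stored_tag = None
    nodes: list[str] = []
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            line = line.strip()
            if line.startswith("# tag:"):
                stored_tag = line.split(":", 1)[1].strip()
            elif line:
                nodes.append(line)
    graph = nx.Graph(tag=tag or stored_tag or path.stem)
    graph.add_nodes_from(nodes)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        u, v, w = parts[0], parts[1], float(parts[2])
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
        graph.add_edge(u, v, weight=w)
    return graph


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.D, index=dm.row_genes, columns=dm.col_genes).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_distance_matrix(
    path: str | Path, row_tag: str = "network1", col_tag: str = "network2"
) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(
        [str(g) for g in frame.index],
        [str(g) for g in frame.columns],
        frame.to_numpy(dtype=float),
        row_tag,
        col_tag,
    )


def write_corpus(corpus, path: str | Path) -> None:
    """Write walks as TSV: origin network tag, then the space-joined walk."""
    with open(path, "w") as fh:
        for tag, row, ln in zip(
            corpus.origin_network, corpus.tokens, corpus.lengths
        ):
            walk = " ".join(str(int(t)) for t in row[:ln])
            fh.write(f"{tag}\t{walk}\n")


def read_corpus(path: str | Path):
    """Read a corpus written by :func:`write_corpus`."""
    from .walks import PAD, WalkCorpus

    tags, walks = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            tag, toks = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'tag<TAB>walk'") from None
        tags.append(tag)
        walks.append([int(t) for t in toks.split()])
    if not walks:
        raise ValueError(f"{path}: empty corpus")
    lengths = np.array([len(w) for w in walks], dtype=np.int32)
    width = int(lengths.max())
    tokens = np.full((len(walks), width), PAD, dtype=np.int32)
    for i, w in enumerate(walks):
        tokens[i, : len(w)] = w
    return WalkCorpus(
        tokens=tokens,
        lengths=lengths,
        origin_network=np.array(tags, dtype=object),
        walk_length=width,
        walks_per_node=0,
    )


def read_embedding(path: str | Path, token_map) -> "object":
    """Read embeddings.tsv (token key, v1..vN) back into an EmbeddingMatrix."""
    from .embedding import EmbeddingMatrix

    rows = {}
    n_dim = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        key, vec = parts[0], np.array(parts[1:], dtype=np.float32)
        n_dim = len(vec) if n_dim is None else n_dim
        rows[key] = vec
    vectors = np.zeros((len(token_map), n_dim), dtype=np.float32)
    for key, tok in token_map.forward.items():
        if key not in rows:
            raise ValueError(f"token key {key!r} missing from {path}")
        vectors[tok] = rows[key]
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EmbeddingMatrix(vectors=vectors, training_meta=meta)


def write_alignment(
    result: AlignmentResult,
    path: str | Path,
    extra_summary: dict | None = None,
) -> None:
    """Write matched pairs as TSV plus a JSON summary sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tdistance\n")
        for g1, g2, d in result.pairs:
            fh.write(f"{g1}\t{g2}\t{d:.8g}\n")
    summary = {
        "global_distance": result.global_distance,
        "n_matched": len(result.pairs),
        "n_unmatched": len(result.unmatched),
        "unmatched": list(result.unmatched),
    }
    if extra_summary:
        summary.update(extra_summary)
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
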