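"""End-to-end orchestration: build, anchor, walk, embed, align, bicluster.

:func:`compare_networks` is the library entry point: given two weighted
co-expression networks it runs the full joint-embedding comparison and
returns every intermediate product.  :func:`run_pipeline` is its
file-based counterpart used by the command line: it loads inputs named in
a configuration, writes all artifacts into a run directory and records a
JSON manifest capturing every parameter and seed, so any output is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from . import io as cxio
from .alignment import (
    AlignmentResult,
    DistanceMatrix,
    anchor_consistency_test,
    distance_matrix,
    hungarian_match,
    match_fraction,
)
from .anchoring import AnchorSet, attach_danglings, is_artificial, select_anchors
from .biclustering import bicluster_summary, spectral_bicluster
from .embedding import EmbeddingMatrix, train_embeddings
from .gcn_build import build_gcn, network_tag
from .walks import TokenMap, build_token_map, generate_walks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ComparisonResult", "compare_networks", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Hyperparameters of a comparison run.

    Defaults marked (*) follow the published protocol; the rest are
    package defaults exposed for tuning.
    """

    seed: int = 0
    pcc_threshold: float = 0.8      # (*) two-sided threshold on original PCC
    n_anchors: int = 3
    anchor_strategy: str = "spread"
    gamma: int = 8                  # dangling-structure node count
    sparsity: float = 0.15          # (*) fraction of potential dangling edges
    walks_per_node: int = 1000      # (*)
    walk_length: int = 20
    n_dim: int = 6                  # keep <= the rank the landmarks pin
    window: int = 5
    epochs: int = 1                 # (*) single pass over a large corpus
    negative: int = 5
    tying_policy: str = "dangling-only"
    n_row_clusters: int = 5
    n_col_clusters: int = 5
    n_random: int = 1000            # (*) permutation-test null sets

    def stage_seeds(self) -> dict:
        """Independent reproducible sub-seeds for each stochastic stage."""
        seq = np.random.SeedSequence(self.seed)
        names = ("anchors", "danglings", "walks", "training", "permutation")
        children = seq.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }


@dataclass
class ComparisonResult:
    """Everything a two-network comparison produces."""

    anchors: AnchorSet
    structures: list
    augmented: list
    token_map: TokenMap
    embedding: EmbeddingMatrix
    distances: DistanceMatrix
    alignment: AlignmentResult
    config: PipelineConfig
    timings: dict = field(default_factory=dict)

    def real_genes(self, which: int) -> list:
        net = self.augmented[which]
        return sorted(n for n in net.nodes if not is_artificial(n))


def _ensure_distinct_tags(networks: Sequence[nx.Graph]) -> list[nx.Graph]:
    """Self-comparisons need distinct tags so vocabularies stay separate."""
    seen: dict[str, int] = {}
    out = []
    for net in networks:
        tag = network_tag(net)
        seen[tag] = seen.get(tag, 0) + 1
        if seen[tag] > 1 or sum(network_tag(n) == tag for n in networks) > 1:
            relabelled = net.copy()
            relabelled.graph["tag"] = f"{tag}_{seen[tag]}"
            out.append(relabelled)
        else:
            out.append(net)
    return out


def compare_networks(
    net1: nx.Graph,
    net2: nx.Graph,
    anchor_candidates: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
) -> ComparisonResult:
    """Run the full joint-embedding comparison of two networks.

    Anchor candidates default to all genes common to both networks (for
    real data pass a curated conserved-process gene set).  The distance
    matrix and matching cover real genes only; dangling scaffolding is
    excluded.
    """
    config = config or PipelineConfig()
    seeds = config.stage_seeds()
    timings: dict[str, float] = {}

    net1, net2 = _ensure_distinct_tags([net1, net2])
    if anchor_candidates is None:
        anchor_candidates = sorted(set(net1.nodes) & set(net2.nodes))

    t0 = time.perf_counter()
    anchors = select_anchors(
        anchor_candidates, [net1, net2], config.n_anchors, seeds["anchors"],
        strategy=config.anchor_strategy,
    )
    augmented, structures = attach_danglings(
        [net1, net2], anchors,
        gamma=config.gamma, sparsity=config.sparsity, seed=seeds["danglings"],
    )
    timings["anchoring"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    token_map = build_token_map(augmented, config.tying_policy, anchors)
    corpus = generate_walks(
        augmented, config.walks_per_node, config.walk_length,
        token_map, seeds["walks"],
    )
    timings["walks"] = time.perf_counter() - t0
    logger.info(
        "corpus: %d walks, vocabulary %d tokens",
        corpus.n_walks, len(token_map),
    )

    t0 = time.perf_counter()
    emb = train_embeddings(
        corpus,
        n_dim=config.n_dim, window=config.window, epochs=config.epochs,
        seed=seeds["training"], negative=config.negative,
        token_map=token_map,
    )
    timings["training"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    genes1 = sorted(n for n in augmented[0].nodes if not is_artificial(n))
    genes2 = sorted(n for n in augmented[1].nodes if not is_artificial(n))
    dm = distance_matrix(
        emb, genes1, genes2, token_map,
        network_tag(augmented[0]), network_tag(augmented[1]),
    )
    result = hungarian_match(dm)
    timings["alignment"] = time.perf_counter() - t0
    logger.info(
        "matched %d gene pairs, global distance %.4f (stage times: %s)",
        len(result.pairs), result.global_distance,
        {k: f"{v:.1f}s" for k, v in timings.items()},
    )

    return ComparisonResult(
        anchors=anchors,
        structures=structures,
        augmented=augmented,
        token_map=token_map,
        embedding=emb,
        distances=dm,
        alignment=result,
        config=config,
        timings=timings,
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    expression_paths: Sequence[str] | None = None,
    network_paths: Sequence[str] | None = None,
    anchor_file: str | None = None,
    self_compare: bool = False,
    truth: str = "identity",
) -> Path:
    """File-based end-to-end run; returns the run directory.

    Inputs are either two expression matrices (networks are built at
    ``pcc_threshold``) or two pre-built weighted edge lists; with
    ``self_compare`` a single input is compared against a copy of itself.
    ``truth="identity"`` scores the matching against same-name
    correspondence (meaningful for self- and replicate comparisons);
    ``truth="none"`` skips it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    networks: list[nx.Graph] = []
    stage = "input"
    try:
        if expression_paths:
            stage = "gcn_build"
            for k, p in enumerate(expression_paths):
                expr = cxio.read_expression(p)
                networks.append(
                    build_gcn(expr, config.pcc_threshold, tag=Path(p).stem)
                )
        if network_paths:
            stage = "input"
            for p in network_paths:
                networks.append(cxio.read_edge_list(p))
        if self_compare:
            if len(networks) != 1:
                raise ValueError("self_compare needs exactly one input network")
            networks.append(networks[0].copy())
        if len(networks) != 2:
            raise ValueError(
                f"need exactly 2 networks (got {len(networks)}); "
                "pass two inputs or one with self_compare"
            )

        stage = "anchoring"
        candidates = cxio.read_gene_list(anchor_file) if anchor_file else None

        stage = "pipeline"
        result = compare_networks(networks[0], networks[1], candidates, config)

        stage = "outputs"
        for net, name in zip(result.augmented, ("network1", "network2")):
            cxio.write_edge_list(net, outdir / f"{name}.augmented.tsv")
        result.token_map.save(outdir / "token_map.json")
        result.embedding.save(outdir / "embeddings.tsv", result.token_map)
        cxio.write_distance_matrix(result.distances, outdir / "distances.tsv")

        extra = {}
        if truth == "identity":
            shared = set(result.distances.row_genes) & set(result.distances.col_genes)
            if shared:
                extra["match_fraction"] = match_fraction(
                    result.alignment, {g: g for g in shared}
                )
        cxio.write_alignment(result.alignment, outdir / "alignment.tsv", extra)

        stage = "biclustering"
        n_row = min(config.n_row_clusters, len(result.distances.row_genes))
        n_col = min(config.n_col_clusters, len(result.distances.col_genes))
        model = spectral_bicluster(
            result.distances, n_row, n_col, config.stage_seeds()["permutation"]
        )
        records = bicluster_summary(result.distances, model)
        with open(outdir / "biclusters.tsv", "w") as fh:
            fh.write("bicluster_id\trow_cluster\tcol_cluster\tsize\tmean_distance\n")
            for rec in records:
                fh.write(
                    f"{rec['bicluster_id']}\t{rec['row_cluster']}\t"
                    f"{rec['col_cluster']}\t{rec['size']}\t"
                    f"{rec['mean_distance']:.6g}\n"
                )
        genedir = outdir / "bicluster_genes"
        genedir.mkdir(exist_ok=True)
        for rec in records:
            (genedir / f"{rec['bicluster_id']}.txt").write_text(
                "\n".join(
                    [f"# rows ({result.distances.row_tag})"] + rec["row_genes"]
                    + [f"# cols ({result.distances.col_tag})"] + rec["col_genes"]
                ) + "\n"
            )

        manifest = {
            "config": dataclasses.asdict(result.config),
            "stage_seeds": result.config.stage_seeds(),
            "inputs": {
                "expression": list(expression_paths or []),
                "networks": list(network_paths or []),
                "anchor_file": anchor_file,
                "self_compare": self_compare,
            },
            "anchors": list(result.anchors),
            "artificial_prefix": "DANGLE::",
            "n_matched": len(result.alignment.pairs),
            "global_distance": result.alignment.global_distance,
            **extra,
            "timings_sec": {k: round(v, 3) for k, v in result.timings.items()},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir
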