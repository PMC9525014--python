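"""End-to-end binning pipeline.

Stages: read inputs -> contig features (composition + abundance) ->
VAE contig embeddings -> coverage-weighted GraphSAGE graph embeddings ->
cluster the concatenated embeddings -> write bins and metrics.

One integer seed governs every stochastic stage; sub-seeds for the VAE,
the GNN and clustering are derived from it, so a full run is
bit-reproducible at the bins-TSV level on CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, evaluation, features, graph_io
from .gnn import GNNConfig, train_gnn
from .vae import EmbeddingMatrix, VAEConfig, train_vae

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    graph: str | Path
    depth: str | Path
    assembly: str | Path | None = None
    markers: str | Path | None = None
    labels: str | Path | None = None
    outdir: str | Path = "sagebin_out"
    vae: VAEConfig = field(default_factory=VAEConfig)
    gnn: GNNConfig = field(default_factory=GNNConfig)
    distance_threshold: float | None = None
    max_steps: int = 25
    min_contig_length: int = 0
    include_variance: bool = False
    strict_parse: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    bins: clustering.BinAssignment
    vae_embeddings: EmbeddingMatrix
    gnn_embeddings: EmbeddingMatrix
    concat_embeddings: EmbeddingMatrix
    vae_trace: list[float]
    gnn_info: dict
    metrics: dict
    threshold: float


def derive_seeds(seed: int, n: int = 3) -> list[int]:
    """Derive independent stage seeds (< 2**31) from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def filter_graph(graph: graph_io.AssemblyGraph, min_length: int) -> graph_io.AssemblyGraph:
    """Drop contigs shorter than ``min_length`` and their incident edges."""
    if min_length <= 0:
        return graph
    keep = {c for c in graph.contig_ids if len(graph.sequences[c]) >= min_length}
    out = graph_io.AssemblyGraph()
    out.contig_ids = [c for c in graph.contig_ids if c in keep]
    out.sequences = {c: graph.sequences[c] for c in out.contig_ids}
    out.edge_coverage = {e: rc for e, rc in graph.edge_coverage.items() if e <= keep}
    return out


def bin_contigs(
    graph: graph_io.AssemblyGraph,
    depth: graph_io.DepthTable,
    markers: graph_io.MarkerTable | None = None,
    labels: dict[str, str] | None = None,
    vae_config: VAEConfig | None = None,
    gnn_config: GNNConfig | None = None,
    distance_threshold: float | None = None,
    max_steps: int = 25,
    include_variance: bool = False,
    seed: int = 0,
) -> PipelineResult:
    """Run features -> VAE -> GNN -> clustering on in-memory inputs.

    When gold labels are given they are used for checkpoint selection
    (overriding markers) and for the reported metrics; markers alone
    drive checkpoint selection through the marker-based bin quality.
    """
    s_vae, s_gnn, s_cluster = derive_seeds(seed)
    vae_config = dataclasses.replace(vae_config or VAEConfig(), seed=s_vae)
    gnn_config = dataclasses.replace(gnn_config or GNNConfig(), seed=s_gnn)

    t0 = time.time()
    x, comp_dim = features.build_features(graph, depth, include_variance=include_variance)
    logger.info("features: %d contigs x %d dims (%.1fs)", *x.shape, time.time() - t0)

    t0 = time.time()
    vae_emb, vae_trace = train_vae(x, graph.contig_ids, vae_config, comp_dim)
    logger.info("vae: %d epochs, final loss %.4f (%.1fs)", len(vae_trace), vae_trace[-1] if vae_trace else float("nan"), time.time() - t0)

    lengths = graph.contig_length
    scorer = None
    if labels:
        scorer = _label_scorer(vae_emb, labels, lengths, distance_threshold, max_steps, s_cluster)
    elif markers:
        scorer = _marker_checkpoint_scorer(vae_emb, markers, lengths, distance_threshold, max_steps, s_cluster)

    t0 = time.time()
    gnn_emb, gnn_info = train_gnn(graph, vae_emb, gnn_config, checkpoint_scorer=scorer)
    logger.info(
        "gnn: %d epochs, selected epoch %d (%.1fs)",
        len(gnn_info["loss_trace"]), gnn_info["selected_epoch"], time.time() - t0,
    )

    concat = clustering.concat_embeddings(vae_emb, gnn_emb)
    threshold = distance_threshold
    if threshold is None:
        threshold = clustering.estimate_threshold(concat.matrix, seed=s_cluster)
    t0 = time.time()
    bins = clustering.iterative_medoid_cluster(concat, max_steps=max_steps, distance_threshold=threshold, seed=s_cluster)
    bins.lengths = lengths
    logger.info("clustering: %d bins at threshold %.3f (%.1fs)", bins.n_bins, threshold, time.time() - t0)

    metrics: dict = {"n_contigs": len(graph.contig_ids), "n_bins": bins.n_bins, "threshold": threshold}
    if markers and markers.universe:
        quality = evaluation.marker_quality(bins, markers, lengths)
        metrics["marker_hq_bins"] = len(evaluation.hq_call(quality))
    if labels:
        lm = evaluation.label_metrics(bins, labels, lengths)
        metrics.update(
            average_purity_bp=lm.average_purity_bp,
            average_completeness_bp=lm.average_completeness_bp,
            f1=lm.f1,
            hq_count=lm.hq_count,
            mq_count=lm.mq_count,
            ari=evaluation.ari(bins, labels),
        )
    return PipelineResult(bins, vae_emb, gnn_emb, concat, vae_trace, gnn_info, metrics, threshold)


def _cluster_for_checkpoint(vae_emb, gnn_emb, threshold, max_steps, seed):
    concat = clustering.concat_embeddings(vae_emb, gnn_emb)
    return clustering.iterative_medoid_cluster(concat, max_steps=max_steps, distance_threshold=threshold, seed=seed)


def _marker_checkpoint_scorer(vae_emb, markers, lengths, threshold, max_steps, seed):
    def scorer(gnn_emb):
        bins = _cluster_for_checkpoint(vae_emb, gnn_emb, threshold, max_steps, seed)
        return evaluation.checkpoint_score(evaluation.marker_quality(bins, markers, lengths))

    return scorer


def _label_scorer(vae_emb, labels, lengths, threshold, max_steps, seed):
    def scorer(gnn_emb):
        bins = _cluster_for_checkpoint(vae_emb, gnn_emb, threshold, max_steps, seed)
        lm = evaluation.label_metrics(bins, labels, lengths)
        return (lm.hq_count, lm.f1)

    return scorer


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based front end: read inputs, run :func:`bin_contigs`, write
    bins TSV, loss traces, the selected checkpoint and a metrics report
    into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    graph = graph_io.read_gfa(config.graph, strict=config.strict_parse)
    if config.assembly:
        fasta = graph_io.read_fasta(config.assembly)
        for cid in graph.contig_ids:  # GFA sequences win; FASTA fills gaps
            if not graph.sequences.get(cid) and cid in fasta:
                graph.sequences[cid] = fasta[cid]
    missing_seq = [c for c in graph.contig_ids if not graph.sequences.get(c)]
    if missing_seq:
        raise ValueError(f"no sequence for contigs {missing_seq[:5]} (provide --assembly)")
    graph = filter_graph(graph, config.min_contig_length)
    depth = graph_io.read_depth(config.depth)
    depth.require(graph.contig_ids)
    markers = graph_io.read_markers(config.markers) if config.markers else None
    labels = graph_io.read_labels(config.labels) if config.labels else None

    result = bin_contigs(
        graph,
        depth,
        markers=markers,
        labels=labels,
        vae_config=config.vae,
        gnn_config=config.gnn,
        distance_threshold=config.distance_threshold,
        max_steps=config.max_steps,
        include_variance=config.include_variance,
        seed=config.seed,
    )

    graph_io.write_bins(result.bins, outdir / "bins.tsv")
    with open(outdir / "vae_loss.csv", "w") as fh:
        fh.write("epoch,loss\n")
        fh.writelines(f"{i},{v:.6f}\n" for i, v in enumerate(result.vae_trace))
    with open(outdir / "gnn_loss.csv", "w") as fh:
        fh.write("epoch,loss\n")
        fh.writelines(f"{i},{v:.6f}\n" for i, v in enumerate(result.gnn_info["loss_trace"]))
    np.savez(
        outdir / "checkpoint.npz",
        embeddings=result.concat_embeddings.matrix,
        contig_ids=np.array(result.concat_embeddings.contig_ids),
        selected_epoch=result.gnn_info["selected_epoch"],
    )
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, default=float)
    return result


DEFAULT_GRID = {
    "hidden_dim": [128, 256, 512],
    "output_dim": [32, 64, 128],
    "learning_rate": [1e-2, 1e-3, 1e-4, 1e-5],
}


def run_grid(config: RunConfig, grid: dict | None = None, out_tsv: str | Path | None = None):
    """Grid search over GNN hyper-parameters.

    Each cell reruns the pipeline and is scored by the checkpoint score
    (marker-based, or label-based when labels are given); rows come back
    sorted best-first and are optionally written as a TSV.
    """
    grid = grid or DEFAULT_GRID
    import itertools

    keys = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        cell = dataclasses.replace(config, gnn=dataclasses.replace(config.gnn, **params))
        result = run_pipeline(cell)
        score = result.metrics.get("hq_count", result.metrics.get("marker_hq_bins", 0))
        rows.append({**params, "score": score, "n_bins": result.bins.n_bins})
    rows.sort(key=lambda r: r["score"], reverse=True)
    if out_tsv:
        with open(out_tsv, "w") as fh:
            fh.write("\t".join([*keys, "score", "n_bins"]) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[k]) for k in [*keys, "score", "n_bins"]) + "\n")
    return rows
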