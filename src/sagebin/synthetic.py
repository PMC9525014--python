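"""Planted-truth synthetic metagenomic communities.

Genomes are sampled from genome-specific third-order Markov chains so
that genome membership leaves a tetranucleotide signature whose strength
is controlled by ``composition_divergence`` (0: all genomes share one
chain; 1: fully independent chains). Each genome is split into contigs at
random breakpoints; consecutive contigs are linked by high-coverage
"true" assembly-graph edges, and spurious low-coverage inter-genome
edges are planted at a configurable rate. Per-sample contig depths
follow genome-level abundance profiles with 5% relative noise; each
genome carries a shared universe of single-copy markers placed on random
contigs.

This emulates, at desk scale, the joint structure of a long-read
metagenome assembly (composition signal, differential abundance,
coverage-weighted graph) with exact gold labels. It does not emulate
assembler artifacts: chimeric contigs, repeat-collapsed segments, or
strain-level graph tangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graph_io import AssemblyGraph


@dataclass
class CommunityConfig:
    n_genomes: int = 5
    genome_length_bp: int = 50_000
    contigs_per_genome: int = 20
    composition_divergence: float = 0.75
    n_samples: int = 2
    # per-genome per-sample mean depths; None: log-uniform in [5, 50]
    abundance_profile: np.ndarray | None = None
    intra_edge_coverage: float = 20.0
    intra_edge_rate: float = 1.0
    spurious_edge_rate: float = 0.05
    spurious_edge_coverage: float = 2.0
    markers_per_genome: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genomes, self.genome_length_bp, self.contigs_per_genome, self.n_samples) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.composition_divergence <= 1.0 and 0.0 <= self.spurious_edge_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticCommunity:
    config: CommunityConfig
    graph: AssemblyGraph
    gold_labels: dict[str, str]
    depths: dict[str, list[float]]
    depth_vars: dict[str, list[float]]
    markers: dict[str, list[str]]
    files: dict[str, Path] = field(default_factory=dict)


def _markov_chain(rng: np.random.Generator, order: int = 3) -> np.ndarray:
    """Random transition matrix over 4^order contexts."""
    return rng.dirichlet(np.ones(4) * 1.2, size=4**order)


def _sample_genome(rng: np.random.Generator, chain: np.ndarray, length: int, order: int = 3) -> str:
    cum = np.cumsum(chain, axis=1)
    u = rng.random(length)
    bases = np.empty(length, dtype=np.int8)
    ctx = int(rng.integers(4**order))
    mask = 4 ** (order - 1)
    for i in range(length):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        bases[i] = b
        ctx = (ctx % mask) * 4 + b
    return "".join("ACGT"[b] for b in bases)


def _split_contigs(rng: np.random.Generator, genome: str, n_contigs: int, min_len: int = 50) -> list[str]:
    L = len(genome)
    if n_contigs == 1:
        return [genome]
    for _ in range(1000):
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_contigs - 1, replace=False))
        bounds = [0, *cuts.tolist(), L]
        pieces = [genome[bounds[i] : bounds[i + 1]] for i in range(n_contigs)]
        if min(len(p) for p in pieces) >= max(min_len, 4):
            return pieces
    raise RuntimeError("could not split genome into contigs of the requested minimum length")


def _trunc_normal(rng: np.random.Generator, mean: float, rel_sd: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, rel_sd * mean)
        if x > 0:
            return float(x)
    return float(mean)


def generate_community(config: CommunityConfig, outdir=None) -> SyntheticCommunity:
    """Generate a community; if ``outdir`` is given, also write the
    FASTA / GFA / depth-table / marker-CSV / label-TSV files (byte-stable
    for a fixed seed)."""
    rng = np.random.default_rng(config.seed)
    base_chain = _markov_chain(rng)
    d = config.composition_divergence

    graph = AssemblyGraph()
    gold: dict[str, str] = {}
    contigs_by_genome: dict[str, list[str]] = {}
    for g in range(config.n_genomes):
        own_chain = _markov_chain(rng)
        chain = (1.0 - d) * base_chain + d * own_chain
        genome_id = f"genome{g}"
        genome = _sample_genome(rng, chain, config.genome_length_bp)
        pieces = _split_contigs(rng, genome, config.contigs_per_genome)
        ids = []
        for i, seq in enumerate(pieces):
            cid = f"g{g}_c{i}"
            graph.contig_ids.append(cid)
            graph.sequences[cid] = seq
            gold[cid] = genome_id
            ids.append(cid)
        contigs_by_genome[genome_id] = ids
        # true intra-genome adjacencies along the genome
        for i in range(len(ids) - 1):
            if rng.random() < config.intra_edge_rate:
                graph.add_edge(ids[i], ids[i + 1], _trunc_normal(rng, config.intra_edge_coverage, 0.1))

    n_intra = len(graph.edge_coverage)
    n_spurious = round(config.spurious_edge_rate * n_intra) if config.n_genomes > 1 else 0
    genome_ids = sorted(contigs_by_genome)
    attempts = 0
    while n_spurious > 0 and attempts < 100 * n_spurious:
        attempts += 1
        ga, gb = rng.choice(len(genome_ids), size=2, replace=False)
        u = contigs_by_genome[genome_ids[ga]][int(rng.integers(config.contigs_per_genome))]
        v = contigs_by_genome[genome_ids[gb]][int(rng.integers(config.contigs_per_genome))]
        if graph.coverage(u, v) > 0:
            continue
        graph.add_edge(u, v, _trunc_normal(rng, config.spurious_edge_coverage, 0.1))
        n_spurious -= 1

    profile = config.abundance_profile
    if profile is None:
        profile = np.exp(rng.uniform(np.log(5.0), np.log(50.0), size=(config.n_genomes, config.n_samples)))
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (config.n_genomes, config.n_samples):
        raise ValueError("abundance_profile must be (n_genomes, n_samples)")
    depths: dict[str, list[float]] = {}
    depth_vars: dict[str, list[float]] = {}
    for g, genome_id in enumerate(genome_ids):
        for cid in contigs_by_genome[genome_id]:
            mean = [float(profile[g, s] * rng.normal(1.0, 0.05)) for s in range(config.n_samples)]
            mean = [max(m, 0.0) for m in mean]
            depths[cid] = mean
            depth_vars[cid] = [0.2 * m for m in mean]

    universe = [f"marker{m}" for m in range(config.markers_per_genome)]
    markers: dict[str, list[str]] = {}
    for genome_id in genome_ids:
        ids = contigs_by_genome[genome_id]
        for m in universe:
            cid = ids[int(rng.integers(len(ids)))]
            markers.setdefault(cid, []).append(m)

    comm = SyntheticCommunity(config, graph, gold, depths, depth_vars, markers)
    if outdir is not None:
        _write_files(comm, Path(outdir))
    return comm


def _write_files(comm: SyntheticCommunity, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    g = comm.graph
    fasta = outdir / "assembly.fasta"
    with open(fasta, "w") as fh:
        for cid in g.contig_ids:
            fh.write(f">{cid}\n{g.sequences[cid]}\n")
    gfa = outdir / "assembly_graph.gfa"
    with open(gfa, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in g.contig_ids:
            dp = sum(comm.depths[cid]) / len(comm.depths[cid])
            fh.write(f"S\t{cid}\t{g.sequences[cid]}\tdp:f:{dp:.4f}\n")
        for e in sorted(g.edge_coverage, key=sorted):
            u, v = sorted(e)
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\tdp:f:{g.edge_coverage[e]:.4f}\n")
    depth = outdir / "depth.tsv"
    s = comm.config.n_samples
    with open(depth, "w") as fh:
        cols = ["contigName", "contigLen", "totalAvgDepth"]
        for i in range(s):
            cols += [f"sample{i + 1}.bam", f"sample{i + 1}.bam-var"]
        fh.write("\t".join(cols) + "\n")
        for cid in g.contig_ids:
            means, variances = comm.depths[cid], comm.depth_vars[cid]
            row = [cid, str(len(g.sequences[cid])), f"{sum(means) / s:.4f}"]
            for m, v in zip(means, variances):
                row += [f"{m:.4f}", f"{v:.4f}"]
            fh.write("\t".join(row) + "\n")
    marker_csv = outdir / "markers.csv"
    with open(marker_csv, "w") as fh:
        for cid in g.contig_ids:
            for m in comm.markers.get(cid, ()):
                fh.write(f"{cid},{m}\n")
    labels = outdir / "labels.tsv"
    with open(labels, "w") as fh:
        for cid in g.contig_ids:
            fh.write(f"{cid}\t{comm.gold_labels[cid]}\n")
    comm.files = {
        "fasta": fasta,
        "gfa": gfa,
        "depth": depth,
        "markers": marker_csv,
        "labels": labels,
    }


def stress_profile(name: str, seed: int = 0) -> CommunityConfig:
    """Named study conditions.

    * ``easy`` — divergent composition, clean graph, two samples.
    * ``graph_only`` — zero composition divergence and one sample with
      pairs of genomes sharing the same depth, so contig-specific
      features cannot fully separate genomes; only the (clean) assembly
      graph can.
    * ``composition_only`` — no graph edges at all.
    * ``hard`` — weak composition signal plus many spurious inter-genome
      edges at coverage close to the true edges (a noisy, tangled graph).
    """
    base = CommunityConfig(seed=seed)
    if name == "easy":
        return base
    if name == "graph_only":
        # One sample, identical depth for every genome: contig-specific
        # features carry no genome signal at all, only the graph does.
        # Community shaped like a many-strain long-read assembly (many
        # genomes, ~8 graph edges each): with few genomes, uniform
        # negative draws hit same-genome contigs so often that the
        # unsupervised loss stops favoring genome-clustered embeddings,
        # and no graph method could show added signal.
        n_genomes = 20
        return replace(
            base,
            n_genomes=n_genomes,
            genome_length_bp=20_000,
            contigs_per_genome=8,
            composition_divergence=0.0,
            n_samples=1,
            abundance_profile=np.full((n_genomes, 1), 30.0),
            spurious_edge_rate=0.0,
        )
    if name == "composition_only":
        return replace(base, intra_edge_rate=0.0, spurious_edge_rate=0.0)
    if name == "hard":
        return replace(
            base,
            composition_divergence=0.2,
            spurious_edge_rate=0.5,
            spurious_edge_coverage=10.0,
        )
    raise ValueError(f"unknown profile {name!r}; expected easy|graph_only|composition_only|hard")
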