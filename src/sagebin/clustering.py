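"""Iterative medoid clustering of the concatenated embeddings.

Bins are grown around density-optimal medoid contigs in cosine distance,
with no preset number of clusters: a random unassigned contig seeds each
bin, the medoid is moved by local search to the unassigned contig whose
threshold-neighborhood is densest, and the bin collects every unassigned
contig within the distance threshold of the final medoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .vae import EmbeddingMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1


@dataclass
class BinAssignment:
    """Partition of contigs into bins (dense integer ids from 0)."""

    contig_to_bin: dict[str, int]
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def bins(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for c, b in self.contig_to_bin.items():
            out.setdefault(b, []).append(c)
        return {b: sorted(cs) for b, cs in out.items()}

    def bin_bp(self, lengths: dict[str, int] | None = None) -> dict[int, int]:
        lengths = lengths or self.lengths
        out: dict[int, int] = {}
        for c, b in self.contig_to_bin.items():
            out[b] = out.get(b, 0) + lengths[c]
        return out

    @property
    def n_bins(self) -> int:
        return len(set(self.contig_to_bin.values()))


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    out = np.zeros_like(m, dtype=float)
    nz = norms[:, 0] > 0
    out[nz] = m[nz] / norms[nz]
    return out


def concat_embeddings(vae: EmbeddingMatrix, gnn: EmbeddingMatrix) -> EmbeddingMatrix:
    """Concatenate two embedding blocks after L2-normalizing each block.

    Per-block normalization makes the cosine similarity on the
    concatenation the average of per-block cosine similarities, so
    neither block dominates by scale.
    """
    if set(vae.contig_ids) != set(gnn.contig_ids):
        diff = sorted(set(vae.contig_ids) ^ set(gnn.contig_ids))
        raise ValueError(f"embedding contig sets differ; symmetric difference: {diff[:10]}")
    order = list(vae.contig_ids)
    row_of = {c: i for i, c in enumerate(gnn.contig_ids)}
    g = gnn.matrix[[row_of[c] for c in order]]
    mat = np.hstack([_unit_rows(vae.matrix), _unit_rows(g)])
    return EmbeddingMatrix(order, mat, "concat")


def estimate_threshold(matrix: np.ndarray, seed: int = 0, n_pairs: int = 20000) -> float:
    """Pick a cosine-distance threshold at the histogram valley between
    the intra-cluster and inter-cluster pairwise-distance modes.

    Falls back to 0.1 when no bimodal structure is detectable.
    """
    n = matrix.shape[0]
    if n < 20:
        return DEFAULT_THRESHOLD
    rng = np.random.default_rng(seed)
    xn = _unit_rows(np.asarray(matrix, dtype=float))
    i = rng.integers(n, size=n_pairs)
    j = rng.integers(n, size=n_pairs)
    keep = i != j
    d = 1.0 - np.einsum("ij,ij->i", xn[i[keep]], xn[j[keep]])
    hi = float(np.quantile(d, 0.999))
    if hi <= 0:
        return DEFAULT_THRESHOLD
    counts, edges = np.histogram(d, bins=50, range=(0.0, hi))
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    # valley: minimum-density bin between the first local peak and the
    # global inter-cluster mode
    first_peak = int(np.argmax(smooth[: max(2, len(smooth) // 4)]))
    main_peak = first_peak + 1 + int(np.argmax(smooth[first_peak + 1 :])) if first_peak + 1 < len(smooth) else first_peak
    if main_peak <= first_peak + 1 or smooth[main_peak] <= smooth[first_peak] * 0.05:
        return DEFAULT_THRESHOLD
    valley = first_peak + 1 + int(np.argmin(smooth[first_peak + 1 : main_peak + 1]))
    threshold = float((edges[valley] + edges[valley + 1]) / 2)
    if not 0.0 < threshold < 1.0:
        return DEFAULT_THRESHOLD
    return threshold


def iterative_medoid_cluster(
    embeddings: EmbeddingMatrix,
    max_steps: int = 25,
    distance_threshold: float | None = None,
    seed: int = 0,
) -> BinAssignment:
    """Partition contigs into bins by iterative medoid clustering.

    Seeds are visited in a random order drawn once from ``seed``. From
    each unassigned seed the medoid moves, for at most ``max_steps``, to
    the unassigned contig inside the current threshold-ball whose own
    ball holds the most unassigned contigs (ties broken by contig
    order); when stable, all unassigned contigs within
    ``distance_threshold`` of the medoid become one bin. When
    ``distance_threshold`` is None it is estimated from the pairwise
    distance histogram (fallback 0.1).
    """
    ids = list(embeddings.contig_ids)
    n = len(ids)
    if n == 0:
        raise ValueError("cannot cluster zero contigs")
    if distance_threshold is None:
        distance_threshold = estimate_threshold(embeddings.matrix, seed=seed)
    xn = _unit_rows(np.asarray(embeddings.matrix, dtype=float))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    unassigned = np.ones(n, dtype=bool)
    assignment: dict[str, int] = {}
    next_bin = 0
    cursor = 0
    while unassigned.any():
        # next unassigned seed in the fixed random order (the medoid may
        # wander away from its seed, leaving the seed for a later round)
        while not unassigned[order[cursor % n]]:
            cursor += 1
        s = order[cursor % n]
        medoid = int(s)
        d_medoid = 1.0 - xn @ xn[medoid]
        density = int(np.count_nonzero(unassigned & (d_medoid <= distance_threshold)))
        for _ in range(max_steps):
            ball = np.flatnonzero(unassigned & (d_medoid <= distance_threshold))
            best, best_density = medoid, density
            for c in ball:
                if c == medoid:
                    continue
                d_c = 1.0 - xn @ xn[c]
                dens = int(np.count_nonzero(unassigned & (d_c <= distance_threshold)))
                if dens > best_density or (dens == best_density and c < best and best != medoid):
                    best, best_density = int(c), dens
            if best == medoid:
                break
            medoid, density = best, best_density
            d_medoid = 1.0 - xn @ xn[medoid]
        members = np.flatnonzero(unassigned & (d_medoid <= distance_threshold))
        if medoid not in members:  # guard: medoid always binned with itself
            members = np.append(members, medoid)
        for c in members:
            assignment[ids[int(c)]] = next_bin
            unassigned[int(c)] = False
        next_bin += 1
    return BinAssignment(assignment)
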