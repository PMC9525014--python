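"""Contig-specific input features: canonical tetranucleotide composition
and normalized multi-sample abundance.

A k-mer and its reverse complement are the same observation on
double-stranded DNA, so k-mers are collapsed into canonical classes
(lexicographic minimum of the pair). For k=4 this gives 136 classes:
120 complement pairs plus 16 palindromes.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _canonical_classes(k: int) -> tuple[dict[str, int], int]:
    """Map every ACGT k-mer to its canonical class index."""
    bases = "ACGT"
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in bases]
    class_of: dict[str, int] = {}
    n = 0
    for km in kmers:  # lexicographic order fixes class numbering
        if km in class_of:
            continue
        rc = revcomp(km)
        class_of[km] = n
        class_of[rc] = n
        n += 1
    return class_of, n


_CLASS_OF_4, N_CLASSES_4 = _canonical_classes(4)
assert N_CLASSES_4 == 136


def kmer_composition(sequence: str, k: int = 4) -> np.ndarray:
    """Canonical k-mer frequency vector of a sequence.

    Windows containing N are skipped; counts are divided by the number
    of valid windows. A sequence with no valid window (shorter than k,
    or all windows hit an N) yields the zero vector.
    """
    class_of, n_classes = (_CLASS_OF_4, N_CLASSES_4) if k == 4 else _canonical_classes(k)
    counts = np.zeros(n_classes)
    seq = sequence.upper()
    total = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        idx = class_of.get(window)
        if idx is None:  # window contains N (or stray character)
            continue
        counts[idx] += 1
        total += 1
    if total == 0:
        return counts
    return counts / total


def composition_matrix(sequences: dict[str, str], contig_ids: list[str], k: int = 4) -> np.ndarray:
    return np.vstack([kmer_composition(sequences[c], k) for c in contig_ids])


def normalize_composition(matrix: np.ndarray) -> np.ndarray:
    """Z-score each composition dimension across contigs.

    Dimensions with zero spread stay at 0. A single-contig matrix is
    returned unchanged (no spread to estimate).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        logger.warning("normalize_composition: <2 contigs, returning input unchanged")
        return matrix.copy()
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    out = matrix - mean
    # sd below rounding noise counts as constant (z-scoring would blow
    # up float error into O(1) values)
    nz = sd > 1e-12 * (np.abs(mean) + 1.0)
    out[:, ~nz] = 0.0
    out[:, nz] /= sd[nz]
    return out


def normalize_abundance(depth, contig_ids: list[str], include_variance: bool = False) -> np.ndarray:
    """Per-contig abundance vectors from a depth table.

    With multiple samples each contig's mean-depth vector is divided by
    its own sum, keeping only the differential-abundance shape across
    samples (all-zero contigs get the uniform 1/S vector). With a single
    sample the shape carries no information, so depths are log(1+d)
    transformed and min-max scaled over contigs instead.

    ``include_variance`` appends the per-sample variance columns,
    log(1+v) scaled by the same min-max convention.
    """
    depth.require(contig_ids)
    s = depth.n_samples
    means = np.array([depth.means[c] for c in contig_ids], dtype=float)
    if (means < 0).any():
        raise ValueError("negative depth")
    if s > 1:
        sums = means.sum(axis=1, keepdims=True)
        out = np.full_like(means, 1.0 / s)
        nz = sums[:, 0] > 0
        out[nz] = means[nz] / sums[nz]
    else:
        logd = np.log1p(means[:, 0])
        lo, hi = logd.min(), logd.max()
        out = ((logd - lo) / (hi - lo) if hi > lo else np.zeros_like(logd)).reshape(-1, 1)
    if include_variance:
        var = np.array([depth.variances[c] for c in contig_ids], dtype=float)
        logv = np.log1p(var)
        lo, hi = logv.min(), logv.max()
        scaled = (logv - lo) / (hi - lo) if hi > lo else np.zeros_like(logv)
        out = np.hstack([out, scaled])
    return out


def build_features(graph, depth, include_variance: bool = False, k: int = 4):
    """Assemble the (composition | abundance) feature blocks for every
    contig of the graph, in graph contig order.

    Returns ``(features, composition_dim)`` where the first
    ``composition_dim`` columns are z-scored composition and the rest the
    normalized abundance block.
    """
    comp = normalize_composition(composition_matrix(graph.sequences, graph.contig_ids, k))
    ab = normalize_abundance(depth, graph.contig_ids, include_variance)
    return np.hstack([comp, ab]), comp.shape[1]
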