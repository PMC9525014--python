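"""Bin-quality scoring.

Two complementary views:

* **Marker-based** (no ground truth needed): single-copy marker genes are
  expected exactly once per genome, so the fraction of distinct markers
  in a bin estimates completeness and duplicated markers estimate
  contamination. Used to select the best training checkpoint.
* **Label-based** (synthetic/gold data): bp-weighted purity and
  completeness per bin against the true genome of each contig, their
  harmonic mean (F1), and high/medium-quality bin counts.

HQ bins are those with completeness > 90% and contamination < 5%
(strict inequalities); MQ uses completeness >= 50% and contamination
< 10% (bins already HQ are not double-counted as MQ).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from sklearn.metrics import adjusted_rand_score


@dataclass
class BinQuality:
    """bin_id -> (completeness %, contamination %, size bp)."""

    per_bin: dict[int, tuple[float, float, int]]

    def completeness(self, b):
        return self.per_bin[b][0]

    def contamination(self, b):
        return self.per_bin[b][1]


@dataclass
class LabelMetrics:
    average_purity_bp: float
    average_completeness_bp: float
    f1: float
    hq_count: int
    mq_count: int


def marker_quality(bins, markers, lengths: dict[str, int] | None = None) -> BinQuality:
    """Per-bin completeness/contamination from single-copy markers.

    completeness = 100 * distinct markers present / universe size;
    contamination = 100 * duplicated marker observations / universe size.
    """
    universe = markers.universe
    if not universe:
        raise ValueError("marker universe is empty")
    u = len(universe)
    out: dict[int, tuple[float, float, int]] = {}
    for b, members in bins.bins.items():
        counts: Counter = Counter()
        for c in members:
            counts.update(markers.markers.get(c, ()))
        distinct = len(counts)
        total = sum(counts.values())
        size = sum(lengths[c] for c in members) if lengths else 0
        out[b] = (100.0 * distinct / u, 100.0 * (total - distinct) / u, size)
    return BinQuality(out)


def hq_call(quality: BinQuality) -> set[int]:
    """Bins with completeness > 90 and contamination < 5, both strict."""
    return {b for b, (comp, cont, _) in quality.per_bin.items() if comp > 90.0 and cont < 5.0}


def checkpoint_score(quality: BinQuality) -> tuple:
    """Score used to rank training checkpoints.

    Primarily the number of HQ bins, ties broken by their summed
    completeness; remaining ties (common early in training, when no bin
    is HQ yet) fall through to the analogous medium-quality ladder
    (completeness >= 50, contamination < 10), so selection still sees a
    gradient before the first HQ bin appears.
    """
    hq = hq_call(quality)
    mq = {
        b
        for b, (comp, cont, _) in quality.per_bin.items()
        if comp >= 50.0 and cont < 10.0 and b not in hq
    }
    # final, continuous tie-break: squared completeness concentrated in
    # low-contamination bins (fragmenting a genome across bins lowers it,
    # merging genomes trips the contamination gate)
    concentration = sum(
        comp**2 for comp, cont, _ in quality.per_bin.values() if cont < 10.0
    )
    return (
        len(hq),
        sum(quality.completeness(b) for b in hq),
        len(mq),
        sum(quality.completeness(b) for b in mq),
        concentration,
    )


def label_metrics(bins, gold: dict[str, str], lengths: dict[str, int]) -> LabelMetrics:
    """bp-weighted purity/completeness/F1 against gold contig labels.

    Bin purity = bp of the bin's majority genome / bin bp (contamination
    is 1 - purity). Bin completeness = bp of that genome inside the bin /
    total bp of the genome. The purity average is weighted by bin bp, the
    completeness average by the majority genome's total bp.
    """
    missing = [c for c in bins.contig_to_bin if c not in gold]
    if missing:
        raise ValueError(f"unlabeled contigs: {missing[:10]}")
    genome_bp: dict[str, int] = {}
    for c, g in gold.items():
        if c in lengths:
            genome_bp[g] = genome_bp.get(g, 0) + lengths[c]
    p_num = p_den = c_num = c_den = 0.0
    hq = mq = 0
    for b, members in bins.bins.items():
        by_genome: dict[str, int] = {}
        bin_bp = 0
        for c in members:
            bp = lengths[c]
            bin_bp += bp
            by_genome[gold[c]] = by_genome.get(gold[c], 0) + bp
        g_star = max(sorted(by_genome), key=by_genome.get)
        purity = by_genome[g_star] / bin_bp
        completeness = by_genome[g_star] / genome_bp[g_star]
        p_num += purity * bin_bp
        p_den += bin_bp
        c_num += completeness * genome_bp[g_star]
        c_den += genome_bp[g_star]
        if completeness > 0.9 and (1.0 - purity) < 0.05:
            hq += 1
        elif completeness >= 0.5 and (1.0 - purity) < 0.1:
            mq += 1
    p = p_num / p_den
    c = c_num / c_den
    f1 = 2 * p * c / (p + c) if p + c else 0.0
    return LabelMetrics(p, c, f1, hq, mq)


def ari(bins, gold: dict[str, str]) -> float:
    """Adjusted Rand index between a bin assignment and gold labels."""
    contigs = sorted(bins.contig_to_bin)
    return float(adjusted_rand_score([gold[c] for c in contigs], [bins.contig_to_bin[c] for c in contigs]))
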