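from collections import Counter

import numpy as np
import pytest

from sagebin.clustering import BinAssignment
from sagebin.evaluation import checkpoint_score, hq_call, label_metrics, marker_quality
from sagebin.graph_io import MarkerTable


def quality(per_bin):
    from sagebin.evaluation import BinQuality

    return BinQuality(per_bin)


class TestMarkerQuality:
    def test_complete_single_copy_bin(self):
        markers = MarkerTable({"c1": Counter({"m1": 1, "m2": 1})})
        bins = BinAssignment({"c1": 0})
        q = marker_quality(bins, markers)
        assert q.per_bin[0][:2] == (100.0, 0.0)

    def test_half_complete_with_one_duplicate(self):
        universe = {f"m{i}": 1 for i in range(100)}
        markers = MarkerTable(
            {
                "c1": Counter({f"m{i}": 1 for i in range(50)}),
                "c2": Counter({"m0": 1}),
                "rest": Counter({f"m{i}": 1 for i in range(50, 100)}),
            }
        )
        bins = BinAssignment({"c1": 0, "c2": 0, "rest": 1})
        q = marker_quality(bins, markers)
        assert q.per_bin[0][:2] == (50.0, 1.0)

    def test_matches_multiset_oracle_on_random_assignment(self, rng):
        contigs = [f"c{i}" for i in range(30)]
        universe = [f"m{i}" for i in range(12)]
        tbl = {}
        for c in contigs:
            k = int(rng.integers(0, 4))
            tbl[c] = Counter(rng.choice(universe, size=k).tolist())
        markers = MarkerTable({c: v for c, v in tbl.items() if v})
        assign = {c: int(rng.integers(0, 5)) for c in contigs}
        q = marker_quality(BinAssignment(assign), markers)
        u = len({m for v in tbl.values() for m in v})
        for b in set(assign.values()):
            pooled = Counter()
            for c in contigs:
                if assign[c] == b:
                    pooled.update(tbl[c])
            comp = 100.0 * len(set(pooled)) / u
            cont = 100.0 * (sum(pooled.values()) - len(set(pooled))) / u
            assert q.per_bin[b][0] == pytest.approx(comp)
            assert q.per_bin[b][1] == pytest.approx(cont)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="empty"):
            marker_quality(BinAssignment({"c": 0}), MarkerTable({}))

    def test_permutation_invariance(self, rng):
        markers = MarkerTable({"a": Counter({"m": 1}), "b": Counter({"m": 1, "n": 2})})
        b1 = BinAssignment({"a": 0, "b": 1})
        b2 = BinAssignment(dict(reversed(list(b1.contig_to_bin.items()))))
        q1, q2 = marker_quality(b1, markers), marker_quality(b2, markers)
        assert q1.per_bin == q2.per_bin


class TestHqCall:
    @pytest.mark.parametrize(
        "comp,cont,expected",
        [
            (90.0, 4.0, False),  # completeness must be strictly > 90
            (95.0, 5.0, False),  # contamination must be strictly < 5
            (95.0, 0.0, True),
            (90.0001, 4.9999, True),
            (100.0, 5.0001, False),
        ],
    )
    def test_strict_inequalities(self, comp, cont, expected):
        q = quality({0: (comp, cont, 1000)})
        assert (0 in hq_call(q)) is expected


class TestCheckpointScore:
    def test_no_hq_bins_scores_zero_head(self):
        q = quality({0: (10.0, 0.0, 1)})
        assert checkpoint_score(q)[:2] == (0, 0.0)

    def test_more_hq_bins_wins(self):
        q3 = quality({i: (95.0, 1.0, 1) for i in range(3)})
        q2 = quality({i: (99.0, 0.0, 1) for i in range(2)})
        assert checkpoint_score(q3) > checkpoint_score(q2)

    def test_completeness_sum_breaks_ties(self):
        a = quality({0: (95.0, 1.0, 1), 1: (95.0, 1.0, 1), 2: (95.0, 1.0, 1)})  # sum 285
        b = quality({0: (95.0, 1.0, 1), 1: (95.0, 1.0, 1), 2: (90.0, 1.0, 1)})  # 2 HQ
        assert checkpoint_score(a) > checkpoint_score(b)
        c = quality({0: (95.0, 1.0, 1), 1: (95.0, 1.0, 1), 2: (90.5, 1.0, 1)})  # sum 280.5
        assert checkpoint_score(a) > checkpoint_score(c)

    def test_monotone_adding_hq_bin(self):
        base = {0: (95.0, 1.0, 1)}
        more = {**base, 1: (92.0, 2.0, 1)}
        assert checkpoint_score(quality(more)) > checkpoint_score(quality(base))


class TestLabelMetrics:
    def test_perfect_binning(self):
        gold = {"a": "g1", "b": "g1", "c": "g2"}
        lengths = {"a": 100, "b": 50, "c": 80}
        bins = BinAssignment({"a": 0, "b": 0, "c": 1})
        m = label_metrics(bins, gold, lengths)
        assert (m.average_purity_bp, m.average_completeness_bp, m.f1) == (1.0, 1.0, 1.0)

    def test_mixed_bin_purity_and_completeness(self):
        gold = {"a": "A", "b": "B"}
        lengths = {"a": 800, "b": 200}
        bins = BinAssignment({"a": 0, "b": 0})
        m = label_metrics(bins, gold, lengths)
        assert m.average_purity_bp == pytest.approx(0.8)
        assert m.average_completeness_bp == pytest.approx(1.0)  # all of A is in its bin

    def test_matches_hand_computed_confusion_matrix(self):
        # 3 genomes, 6 contigs; hand-derived below
        gold = {"a": "A", "b": "A", "c": "B", "d": "B", "e": "C", "f": "C"}
        lengths = {"a": 100, "b": 100, "c": 100, "d": 100, "e": 100, "f": 100}
        bins = BinAssignment({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 2})
        # bin0: 300bp, majority A (200) -> purity 2/3, completeness A = 1.0
        # bin1: 200bp, majority B or C (100 each; lexicographic majority B)
        #        purity 1/2, completeness B in bin / B total = 100/200 = 0.5
        # bin2: 100bp, majority C -> purity 1, completeness 100/200 = 0.5
        m = label_metrics(bins, gold, lengths)
        p = (2 / 3 * 300 + 0.5 * 200 + 1.0 * 100) / 600
        c = (1.0 * 200 + 0.5 * 200 + 0.5 * 200) / 600
        assert m.average_purity_bp == pytest.approx(p)
        assert m.average_completeness_bp == pytest.approx(c)
        assert m.f1 == pytest.approx(2 * p * c / (p + c))
        assert m.hq_count == 0

    def test_unlabeled_contig_raises(self):
        bins = BinAssignment({"a": 0})
        with pytest.raises(ValueError, match="unlabeled"):
            label_metrics(bins, {}, {"a": 10})

    @pytest.mark.parametrize("seed", range(5))
    def test_both_metrics_one_iff_partitions_match(self, seed):
        rng = np.random.default_rng(seed)
        contigs = [f"c{i}" for i in range(12)]
        gold = {c: f"g{int(rng.integers(0, 3))}" for c in contigs}
        lengths = {c: int(rng.integers(50, 500)) for c in contigs}
        assign = {c: int(rng.integers(0, 4)) for c in contigs}
        m = label_metrics(BinAssignment(assign), gold, lengths)
        bins_partition = {}
        for c, b in assign.items():
            bins_partition.setdefault(b, set()).add(c)
        gold_partition = {}
        for c, g in gold.items():
            gold_partition.setdefault(g, set()).add(c)
        same = set(map(frozenset, bins_partition.values())) == set(map(frozenset, gold_partition.values()))
        both_one = m.average_purity_bp == pytest.approx(1.0) and m.average_completeness_bp == pytest.approx(1.0)
        assert both_one == same
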