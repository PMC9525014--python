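import numpy as np
import pytest

from sagebin.graph_io import AssemblyGraph, DepthTable, MarkerTable
from sagebin.synthetic import CommunityConfig, generate_community


@pytest.fixture
def toy_graph() -> AssemblyGraph:
    """Two linked contigs plus a disconnected one."""
    g = AssemblyGraph()
    for cid, seq in [("a", "ACGTACGTAC"), ("b", "TTTTGGGGCC"), ("c", "ACACACACAC")]:
        g.contig_ids.append(cid)
        g.sequences[cid] = seq
    g.add_edge("a", "b", 10.0)
    return g


@pytest.fixture
def small_community():
    """A fast 3-genome community for integration-style unit tests."""
    cfg = CommunityConfig(
        n_genomes=3,
        genome_length_bp=12_000,
        contigs_per_genome=8,
        seed=7,
    )
    return generate_community(cfg)


def depth_of(community) -> DepthTable:
    return DepthTable(
        means=community.depths,
        variances=community.depth_vars,
        n_samples=community.config.n_samples,
    )


def markers_of(community) -> MarkerTable:
    from collections import Counter

    return MarkerTable({c: Counter(m) for c, m in community.markers.items()})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
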