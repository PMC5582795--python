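import numpy as np
import pytest

from paradiverge import Alignment, ClusterPair, SimConfig, simulate_family


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Six sequences, two clusters of three, eight hand-designed columns.

    Columns: 1 conserved F; 2 radical fixed difference F/S; 3 conserved-group
    difference D/E; 4 within-cluster polymorphism in cluster 2 only;
    5 conserved K; 6 gap in a cluster-1 member; 7 X in a cluster-2 member;
    8 radical fixed difference K/Q.
    """
    rows = {
        "a1": "FFDAK-AK",
        "a2": "FFDAKAAK",
        "a3": "FFDAKAAK",
        "b1": "FSEGKAAQ",
        "b2": "FSEGKAAQ",
        "b3": "FSECKAXQ",
    }
    return Alignment(list(rows), list(rows.values()))


@pytest.fixture
def tiny_clusters() -> ClusterPair:
    return ClusterPair("A", "B", {"a1", "a2", "a3"}, {"b1", "b2", "b3"})


@pytest.fixture(scope="session")
def sim_family_theta2():
    """One seeded family with substantial type-II divergence, shared by tests."""
    cfg = SimConfig(L=800, theta2=0.25, seed=20240)
    aln, tree, clusters, truth = simulate_family(cfg)
    return cfg, aln, tree, clusters, truth
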