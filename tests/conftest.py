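import numpy as np
import pytest

from stemsig import (
    ClusterAssignment,
    CountMatrix,
    SimConfig,
    normalize_log,
    scale_genes,
    simulate_counts,
)


@pytest.fixture
def hand_counts():
    """5-gene x 4-cell matrix with one mito gene, small enough to check by hand."""
    values = np.array(
        [
            [5, 0, 2, 1],   # MT-X
            [10, 3, 0, 4],
            [0, 7, 1, 2],
            [2, 2, 2, 2],
            [1, 0, 9, 3],
        ]
    )
    return CountMatrix(
        values=values,
        gene_names=["MT-X", "G1", "G2", "G3", "G4"],
        barcodes=["c1", "c2", "c3", "c4"],
    )


@pytest.fixture(scope="session")
def planted_sim():
    """Two-cluster simulation with a strongly planted program in cluster 1."""
    cfg = SimConfig(
        n_genes=600,
        n_cells=800,
        n_clusters=2,
        program_assignments={1: ["prog"]},
        program_log2_effect={"prog": 2.0},
        program_size=60,
        qc_min_genes=100,
        seed=11,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def planted_scaled(planted_sim):
    cm, gt = planted_sim
    scaled = scale_genes(normalize_log(cm))
    clusters = ClusterAssignment(labels=gt.true_cluster, barcodes=gt.barcodes)
    return scaled, clusters, gt
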