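"""QC filtering, normalization, scaling, clustering and batch combination."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stemsig import (
    ClusterAssignment,
    CountMatrix,
    GeneSignature,
    SimConfig,
    cluster_cells,
    combine_batches,
    normalize_log,
    qc_filter,
    scale_genes,
    simulate_counts,
)
from stemsig.fea import auc_enrichment, score_signature


class TestQCFilter:
    def test_all_passing_matrix_is_identity(self):
        cm = CountMatrix(
            values=np.array([[3, 4], [5, 6], [7, 8]]),
            gene_names=["a", "b", "c"],
            barcodes=["c1", "c2"],
            mito_flag=[False, False, False],
        )
        out, report = qc_filter(cm, min_genes=2, max_mito_frac=0.15)
        assert out.n_cells == 2
        assert report.n_retained == 2 and not report.removed_barcodes

    def test_planted_failures_removed_exactly(self):
        cfg = SimConfig(
            n_genes=500, n_cells=300, n_clusters=2, qc_min_genes=100,
            n_lowdepth_cells=10, n_highmito_cells=5, seed=4,
        )
        cm, gt = simulate_counts(cfg)
        out, report = qc_filter(cm, min_genes=100, max_mito_frac=0.15)
        assert set(report.removed_barcodes) == gt.expected_removed()
        assert report.n_low_genes == 10 and report.n_high_mito == 5

    def test_doublet_labels_respected(self):
        cfg = SimConfig(
            n_genes=400, n_cells=150, qc_min_genes=80, n_doublets=7, seed=5
        )
        cm, gt = simulate_counts(cfg)
        out, report = qc_filter(
            cm, min_genes=80, max_mito_frac=0.15,
            doublet_labels=gt.doublet_labels(),
        )
        assert report.n_doublet == 7
        assert set(report.removed_barcodes) == gt.expected_removed()

    def test_idempotent(self):
        cfg = SimConfig(
            n_genes=400, n_cells=200, qc_min_genes=80,
            n_lowdepth_cells=6, n_highmito_cells=4, seed=6,
        )
        cm, _ = simulate_counts(cfg)
        once, _ = qc_filter(cm, min_genes=80, max_mito_frac=0.15)
        twice, report = qc_filter(once, min_genes=80, max_mito_frac=0.15)
        assert twice.n_cells == once.n_cells
        assert not report.removed_barcodes

    def test_no_survivors_names_dominant_reason(self):
        cm = CountMatrix(
            values=np.array([[1, 1], [0, 1]]),
            gene_names=["a", "b"],
            barcodes=["c1", "c2"],
            mito_flag=[False, False],
        )
        with pytest.raises(ValueError, match="lowdepth"):
            qc_filter(cm, min_genes=100, max_mito_frac=0.15)


class TestNormalizeLog:
    def test_closed_form_single_cell(self):
        cm = CountMatrix(
            values=np.array([[10], [0]]),
            gene_names=["a", "b"],
            barcodes=["c1"],
            mito_flag=[False, False],
        )
        norm = normalize_log(cm, scale=1e4)
        np.testing.assert_allclose(norm.values[:, 0], [np.log(1 + 1e4), 0.0])

    def test_depth_invariance(self, hand_counts):
        norm1 = normalize_log(hand_counts)
        doubled = CountMatrix(
            values=hand_counts.dense() * np.array([2, 1, 1, 1]),
            gene_names=hand_counts.gene_names,
            barcodes=hand_counts.barcodes,
            mito_flag=hand_counts.mito_flag,
        )
        norm2 = normalize_log(doubled)
        np.testing.assert_allclose(norm1.values[:, 0], norm2.values[:, 0])

    def test_hand_matrix_oracle(self):
        # spreadsheet oracle: 3x2 matrix, totals 6 and 3, scale 100
        cm = CountMatrix(
            values=np.array([[1, 0], [2, 1], [3, 2]]),
            gene_names=["a", "b", "c"],
            barcodes=["c1", "c2"],
            mito_flag=[False] * 3,
        )
        norm = normalize_log(cm, scale=100)
        expected = np.log1p(
            np.array([[100 / 6, 0], [200 / 6, 100 / 3], [300 / 6, 200 / 3]])
        )
        np.testing.assert_allclose(norm.values, expected)

    def test_cell_totals_restored(self, hand_counts):
        norm = normalize_log(hand_counts, scale=1e4)
        totals = (np.expm1(norm.values)).sum(axis=0)
        np.testing.assert_allclose(totals, 1e4, rtol=1e-6)

    def test_all_zero_cell_rejected(self):
        cm = CountMatrix(
            values=np.array([[1, 0], [1, 0]]),
            gene_names=["a", "b"],
            barcodes=["c1", "c2"],
            mito_flag=[False, False],
        )
        with pytest.raises(ValueError, match="all-zero"):
            normalize_log(cm)


class TestScaleGenes:
    def test_constant_gene_row_maps_to_zero(self, hand_counts):
        norm = normalize_log(hand_counts)
        norm.values[3, :] = 2.5
        z = scale_genes(norm)
        np.testing.assert_array_equal(z.values[3], 0.0)

    def test_rows_standardized(self, hand_counts):
        z = scale_genes(normalize_log(hand_counts))
        nonconst = np.ptp(z.values, axis=1) > 0
        np.testing.assert_allclose(z.values[nonconst].mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(
            z.values[nonconst].std(axis=1, ddof=1), 1, atol=1e-6
        )

    def test_outlier_clipped_to_bound(self):
        from stemsig import NormalizedMatrix

        vals = np.zeros((1, 50))
        vals[0, 0] = 100.0  # one extreme outlier, z far beyond the bound
        norm = NormalizedMatrix(
            values=vals, gene_names=["g"], barcodes=[f"c{i}" for i in range(50)]
        )
        z = scale_genes(norm, clip=3.0)
        assert z.values[0, 0] == 3.0

    def test_idempotent_up_to_clipping(self, hand_counts):
        from stemsig import NormalizedMatrix

        z1 = scale_genes(normalize_log(hand_counts), clip=None)
        z2 = scale_genes(
            NormalizedMatrix(
                values=z1.values, gene_names=z1.gene_names, barcodes=z1.barcodes
            ),
            clip=None,
        )
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)


class TestClusterCells:
    def test_recovers_planted_clusters(self, planted_sim):
        cm, gt = planted_sim
        scaled = scale_genes(normalize_log(cm))
        assign = cluster_cells(scaled, n_clusters=2, n_pcs=10, seed=0)
        assert adjusted_rand_score(gt.true_cluster, assign.labels) >= 0.9

    def test_deterministic_under_seed(self, planted_sim):
        cm, _ = planted_sim
        scaled = scale_genes(normalize_log(cm))
        a = cluster_cells(scaled, n_clusters=3, n_pcs=10, seed=7)
        b = cluster_cells(scaled, n_clusters=3, n_pcs=10, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_singleton_clusters(self):
        rng = np.random.default_rng(0)
        from stemsig import ScaledMatrix

        scaled = ScaledMatrix(
            values=rng.normal(size=(20, 6)),
            gene_names=[f"g{i}" for i in range(20)],
            barcodes=[f"c{i}" for i in range(6)],
        )
        assign = cluster_cells(scaled, n_clusters=6, n_pcs=3, seed=0)
        assert len(np.unique(assign.labels)) == 6

    def test_more_clusters_than_cells_rejected(self):
        from stemsig import ScaledMatrix

        scaled = ScaledMatrix(
            values=np.random.default_rng(1).normal(size=(10, 4)),
            gene_names=[f"g{i}" for i in range(10)],
            barcodes=[f"c{i}" for i in range(4)],
        )
        with pytest.raises(ValueError):
            cluster_cells(scaled, n_clusters=5, n_pcs=2, seed=0)


class TestCombineBatches:
    def test_copies_have_zero_mean_per_half(self, hand_counts):
        combined = combine_batches([hand_counts, hand_counts])
        n = hand_counts.n_cells
        np.testing.assert_allclose(
            combined.values[:, :n].mean(axis=1), 0, atol=1e-8
        )
        np.testing.assert_allclose(
            combined.values[:, n:].mean(axis=1), 0, atol=1e-8
        )

    def test_single_batch_reduces_to_scale_of_normalize(self, hand_counts):
        combined = combine_batches([hand_counts])
        direct = scale_genes(normalize_log(hand_counts))
        np.testing.assert_allclose(combined.values, direct.values)

    def test_shared_planted_program_enriched_after_combination(self):
        sigs = []
        mats = []
        for seed in (21, 22):
            cfg = SimConfig(
                n_genes=400, n_cells=400, n_clusters=2,
                program_assignments={1: ["prog"]},
                program_log2_effect={"prog": 2.0},
                program_size=40, qc_min_genes=80, seed=seed,
            )
            cm, gt = simulate_counts(cfg)
            mats.append(cm)
            sigs.append(gt)
        combined = combine_batches(mats)
        labels = np.concatenate([g.true_cluster for g in sigs])
        clusters = ClusterAssignment(labels=labels, barcodes=combined.barcodes)
        sc = score_signature(combined, sigs[0].signature("prog"))
        res = auc_enrichment(sc, clusters, 1)
        assert res.auc > 0.6 and res.enriched

    def test_empty_intersection_rejected(self, hand_counts):
        other = CountMatrix(
            values=np.array([[1, 2], [3, 4]]),
            gene_names=["x", "y"],
            barcodes=["d1", "d2"],
            mito_flag=[False, False],
        )
        with pytest.raises(ValueError, match="intersection"):
            combine_batches([hand_counts, other])
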