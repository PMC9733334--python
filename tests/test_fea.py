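"""Signature scoring, AUC enrichment and association statistics.

The AUC implementation is checked against an independent brute-force pair
count, and the exact rank-sum p-value against full enumeration of all
in-group subsets of the pooled scores.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemsig import (
    ClusterAssignment,
    GeneSignature,
    NormalizedMatrix,
    ScaledMatrix,
    enrichment_table,
    scale_genes,
    score_signature,
    signature_correlation,
    signature_regression,
)
from stemsig.fea import SignatureScores, auc_enrichment, correlation_band, rank_sum_test


def brute_force_auc_p(x_in, x_out):
    """Oracle: AUC as the fraction of (in, out) pairs won (ties half), and
    the two-sided p from enumerating every assignment of the pooled scores
    to the in-group."""
    x_in, x_out = list(x_in), list(x_out)
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in x_in for b in x_out)
    auc = wins / (len(x_in) * len(x_out))
    pooled = x_in + x_out
    n, N = len(x_in), len(pooled)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    mean = n * (N + 1) / 2.0
    dev = abs(obs - mean) - 1e-9
    hits = total = 0
    for comb in itertools.combinations(range(N), n):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mean) >= dev:
            hits += 1
    return auc, hits / total


def _scores(vals, name="s"):
    vals = np.asarray(vals, dtype=float)
    return SignatureScores(
        signature_name=name,
        scores=vals,
        barcodes=np.array([f"c{i}" for i in range(len(vals))], dtype=object),
        n_genes_used=1,
        n_genes_missing=0,
    )


def _clusters(labels):
    labels = np.asarray(labels)
    return ClusterAssignment(
        labels=labels,
        barcodes=np.array([f"c{i}" for i in range(len(labels))], dtype=object),
    )


class TestScoreSignature:
    def make_scaled(self, values, genes):
        values = np.asarray(values, dtype=float)
        return ScaledMatrix(
            values=values,
            gene_names=genes,
            barcodes=[f"c{i}" for i in range(values.shape[1])],
        )

    def test_single_gene_signature_equals_gene_z_row(self):
        rng = np.random.default_rng(0)
        norm = NormalizedMatrix(
            values=rng.random((5, 8)),
            gene_names=[f"g{i}" for i in range(5)],
            barcodes=[f"c{i}" for i in range(8)],
        )
        scaled = scale_genes(norm)
        sc = score_signature(scaled, GeneSignature("one", ["g2"]))
        np.testing.assert_allclose(sc.scores, scaled.values[2])

    def test_all_gene_signature_has_zero_mean_score(self):
        rng = np.random.default_rng(1)
        norm = NormalizedMatrix(
            values=rng.random((6, 10)),
            gene_names=[f"g{i}" for i in range(6)],
            barcodes=[f"c{i}" for i in range(10)],
        )
        scaled = scale_genes(norm)
        sc = score_signature(scaled, GeneSignature("all", [f"g{i}" for i in range(6)]))
        assert abs(sc.scores.mean()) < 1e-8

    def test_hand_computed_mean_of_z_rows(self):
        z = np.array(
            [
                [1.0, -1.0, 0.5, -0.5],
                [0.0, 2.0, -2.0, 0.0],
                [1.0, 1.0, -1.0, -1.0],
                [0.3, 0.3, 0.3, 0.3],
                [-2.0, 0.0, 2.0, 0.0],
            ]
        )
        scaled = self.make_scaled(z, [f"g{i}" for i in range(5)])
        sc = score_signature(scaled, GeneSignature("three", ["g0", "g2", "g4"]))
        expected = z[[0, 2, 4]].mean(axis=0)  # hand: column means of rows 0,2,4
        np.testing.assert_allclose(sc.scores, expected)
        assert sc.n_genes_used == 3

    def test_missing_genes_recorded_and_zero_overlap_errors(self):
        z = np.zeros((2, 4))
        z[0] = [1, 2, 3, 4]
        scaled = self.make_scaled(z, ["g0", "g1"])
        with pytest.warns(UserWarning, match="present"):
            sc = score_signature(
                scaled, GeneSignature("s", ["g0", "x1", "x2", "x3", "x4", "x5"])
            )
        assert sc.n_genes_missing == 5
        with pytest.raises(ValueError, match="no genes"):
            score_signature(scaled, GeneSignature("s", ["nope"]))


class TestAUC:
    def test_perfect_separation(self):
        sc = _scores([5, 6, 7, 0, 1, 2])
        res = auc_enrichment(sc, _clusters([0, 0, 0, 1, 1, 1]), 0)
        assert res.auc == 1.0
        res_other = auc_enrichment(sc, _clusters([0, 0, 0, 1, 1, 1]), 1)
        assert res_other.auc == 0.0

    def test_all_ties_gives_half_and_p_one(self):
        sc = _scores([3.0] * 8)
        res = auc_enrichment(sc, _clusters([0] * 4 + [1] * 4), 0)
        assert res.auc == 0.5
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_in = int(rng.integers(2, 9))
        n_out = int(rng.integers(2, 9))
        if seed % 3 == 0:  # force ties in a third of instances
            pool = rng.integers(0, 4, size=n_in + n_out).astype(float)
        else:
            pool = rng.normal(size=n_in + n_out)
        auc, p, method = rank_sum_test(pool[:n_in], pool[n_in:])
        auc_o, p_o = brute_force_auc_p(pool[:n_in], pool[n_in:])
        assert method == "exact"
        assert auc == pytest.approx(auc_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_label_swap_antisymmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        sc = _scores(rng.normal(size=40))
        labels = _clusters(rng.integers(0, 2, size=40))
        a0 = auc_enrichment(sc, labels, 0)
        a1 = auc_enrichment(sc, labels, 1)
        assert a0.auc + a1.auc == pytest.approx(1.0, abs=1e-12)
        transformed = _scores(np.exp(3 * sc.scores))  # strictly monotone
        assert auc_enrichment(transformed, labels, 0).auc == pytest.approx(a0.auc)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x_in=st.lists(st.integers(-3, 3), min_size=2, max_size=7),
        x_out=st.lists(st.integers(-3, 3), min_size=2, max_size=7),
    )
    def test_property_exact_matches_enumeration(self, x_in, x_out):
        auc, p, _ = rank_sum_test(x_in, x_out)
        auc_o, p_o = brute_force_auc_p(x_in, x_out)
        assert auc == pytest.approx(auc_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_degenerate_cluster_sizes_rejected(self):
        sc = _scores([1, 2, 3, 4])
        with pytest.raises(ValueError, match="degenerate"):
            auc_enrichment(sc, _clusters([0, 1, 1, 1]), 0)


class TestEnrichmentTable:
    def test_planted_program_enriched_only_in_carrier_cluster(self, planted_scaled):
        scaled, clusters, gt = planted_scaled
        table = enrichment_table(scaled, [gt.signature("prog")], clusters)
        enriched = table[table["enriched"]]
        assert list(enriched["cluster"]) == [1]
        assert enriched["auc"].iloc[0] > 0.9

    def test_cluster_relabeling_permutes_rows_only(self, planted_scaled):
        scaled, clusters, gt = planted_scaled
        sig = gt.signature("prog")
        t1 = enrichment_table(scaled, [sig], clusters)
        swapped = clusters.relabeled({0: 1, 1: 0})
        t2 = enrichment_table(scaled, [sig], swapped)
        merged = t1.merge(
            t2, left_on="cluster", right_on=t2["cluster"].map({0: 1, 1: 0}),
            suffixes=("_a", "_b"),
        )
        np.testing.assert_allclose(merged["auc_a"], merged["auc_b"])

    def test_single_cluster_rejected(self, planted_scaled):
        scaled, clusters, gt = planted_scaled
        one = ClusterAssignment(
            labels=np.zeros(len(clusters.labels), dtype=int),
            barcodes=clusters.barcodes,
        )
        with pytest.raises(ValueError, match="2 clusters"):
            enrichment_table(scaled, [gt.signature("prog")], one)


class TestAssociations:
    def test_self_correlation_is_one(self):
        sc = _scores(np.random.default_rng(2).normal(size=50))
        res = signature_correlation(sc, sc)
        assert res.pearson_r == pytest.approx(1.0)

    def test_independent_scores_uncorrelated(self):
        rng = np.random.default_rng(3)
        a = _scores(rng.normal(size=1000), "a")
        b = _scores(rng.normal(size=1000), "b")
        res = signature_correlation(a, b)
        assert abs(res.pearson_r) < 0.1
        assert res.band_label == "none"

    @pytest.mark.parametrize(
        "r,band",
        [(0.1, "none"), (0.3, "moderate"), (0.49, "moderate"), (0.5, "strong"),
         (0.9, "strong"), (-0.4, "moderate"), (-0.7, "strong")],
    )
    def test_band_convention(self, r, band):
        assert correlation_band(r) == band

    def test_regression_recovers_planted_coefficients(self):
        rng = np.random.default_rng(7)
        x1 = _scores(rng.normal(size=500), "x1")
        x2 = _scores(rng.normal(size=500), "x2")
        y = _scores(2 * x1.scores - 1 * x2.scores + rng.normal(0, 0.1, 500), "y")
        res = signature_regression(y, [x1, x2])
        coef = res.coefficients.set_index("term")
        for term, truth in (("x1", 2.0), ("x2", -1.0)):
            est, se = coef.loc[term, "coef"], coef.loc[term, "se"]
            assert abs(est - truth) < 3 * se

    def test_perfect_fit(self):
        rng = np.random.default_rng(8)
        x1 = _scores(rng.normal(size=100), "x1")
        y = _scores(x1.scores.copy(), "y")
        res = signature_regression(y, [x1])
        assert res.r_squared == pytest.approx(1.0)
        coef = res.coefficients.set_index("term")
        assert coef.loc["x1", "coef"] == pytest.approx(1.0)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(9)
        x1 = _scores(rng.normal(size=100), "x1")
        dup = _scores(x1.scores.copy(), "x1b")
        y = _scores(rng.normal(size=100), "y")
        with pytest.raises(ValueError, match="collinear"):
            signature_regression(y, [x1, dup])

    def test_zero_variance_subset_rejected(self):
        a = _scores(np.ones(10), "a")
        b = _scores(np.arange(10.0), "b")
        with pytest.raises(ValueError, match="variance"):
            signature_correlation(a, b)
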