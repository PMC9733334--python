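"""Functional enrichment analysis: per-cell signature scores, cluster ROC-AUC.

A signature score is the mean of the gene-wise z-scores over the signature's
genes, computed per cell.  Enrichment of a signature in a cluster is scored
by the area under the ROC curve for separating in-cluster from out-of-cluster
cells on the score (equivalently the Mann-Whitney probability that a random
in-cluster cell outscores a random out-of-cluster cell), with a Wilcoxon
rank-sum p-value.  A cluster is called enriched when AUC > 0.6 and p < 0.01.

The rank-sum p-value is exact (full enumeration of the null distribution of
the rank sum) when the two groups together hold at most ``EXACT_MAX`` cells,
and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import ClusterAssignment, ScaledMatrix
from .signatures import GeneSignature

__all__ = [
    "SignatureScores",
    "EnrichmentResult",
    "AssociationResult",
    "score_signature",
    "auc_enrichment",
    "enrichment_table",
    "signature_correlation",
    "signature_regression",
    "AUC_THRESHOLD",
    "P_THRESHOLD",
    "EXACT_MAX",
]

AUC_THRESHOLD = 0.6
P_THRESHOLD = 0.01
EXACT_MAX = 20  # total cells at or below which the exact rank-sum null is used


@dataclass
class SignatureScores:
    signature_name: str
    scores: np.ndarray
    barcodes: np.ndarray
    n_genes_used: int
    n_genes_missing: int
    missing_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.n_genes_used < 1:
            raise ValueError("signature score needs >= 1 gene present")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class EnrichmentResult:
    signature_name: str
    cluster_id: int
    auc: float
    p_value: float
    enriched: bool
    n_in: int
    n_out: int
    method: str = ""


@dataclass
class AssociationResult:
    label: str
    pearson_r: Optional[float] = None
    r_p_value: Optional[float] = None
    band_label: Optional[str] = None
    coefficients: Optional[pd.DataFrame] = None
    r_squared: Optional[float] = None
    n: int = 0


def score_signature(
    scaled: ScaledMatrix,
    sig: GeneSignature,
    min_overlap_frac: float = 0.2,
) -> SignatureScores:
    """Per-cell z-scored signature score: mean over present signature genes
    of each cell's gene-wise z-score."""
    present = [g for g in sig.genes if g in set(scaled.gene_names)]
    missing = [g for g in sig.genes if g not in set(scaled.gene_names)]
    if not present:
        raise ValueError(
            f"signature {sig.name!r}: no genes found in matrix; missing {missing}"
        )
    frac = len(present) / len(sig.genes)
    if frac < min_overlap_frac:
        warnings.warn(
            f"signature {sig.name!r}: only {len(present)}/{len(sig.genes)} genes "
            f"present ({frac:.0%} < {min_overlap_frac:.0%})"
        )
    idx = scaled.gene_index(present)
    scores = scaled.values[idx, :].mean(axis=0)
    return SignatureScores(
        signature_name=sig.name,
        scores=scores,
        barcodes=scaled.barcodes,
        n_genes_used=len(present),
        n_genes_missing=len(missing),
        missing_genes=missing,
    )


def _rank_sum_auc(x_in: np.ndarray, x_out: np.ndarray) -> tuple[float, float]:
    """AUC via the Mann-Whitney identity with midranks; returns (auc, R_in)."""
    n_in, n_out = len(x_in), len(x_out)
    ranks = rankdata(np.concatenate([x_in, x_out]))
    r_in = ranks[:n_in].sum()
    u = r_in - n_in * (n_in + 1) / 2.0
    return u / (n_in * n_out), r_in


def _exact_ranksum_p_no_ties(n_in: int, n_out: int, r_in: float) -> float:
    """Exact two-sided p for the rank sum of the in-group, no ties.

    Dynamic program over the null distribution of the sum of ``n_in`` ranks
    drawn without replacement from {1..N}.
    """
    N = n_in + n_out
    max_sum = N * (N + 1) // 2
    # dp[k][s] = number of size-k subsets of ranks seen so far with sum s
    dp = np.zeros((n_in + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n_in), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    dist = dp[n_in]
    total = dist.sum()
    mean = n_in * (N + 1) / 2.0
    dev = abs(r_in - mean) - 1e-9
    sums = np.arange(max_sum + 1)
    p = dist[np.abs(sums - mean) >= dev].sum() / total
    return min(1.0, float(p))


def _exact_ranksum_p_ties(ranks: np.ndarray, n_in: int, r_in: float) -> float:
    """Exact two-sided p under ties: enumerate all in-group assignments of
    the pooled midranks."""
    N = len(ranks)
    mean = n_in * (N + 1) / 2.0
    dev = abs(r_in - mean) - 1e-9
    count = 0
    total = 0
    for comb in itertools.combinations(range(N), n_in):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= dev:
            count += 1
    return count / total


def _asymptotic_ranksum_p(ranks: np.ndarray, n_in: int, r_in: float) -> float:
    """Tie-corrected normal approximation, no continuity correction."""
    N = len(ranks)
    n_out = N - n_in
    mean = n_in * (N + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n_in * n_out / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (r_in - mean) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def rank_sum_test(x_in: Sequence[float], x_out: Sequence[float]) -> tuple[float, float, str]:
    """AUC and two-sided Wilcoxon rank-sum p for in vs out scores.

    Returns (auc, p_value, method) where method is "exact" or "asymptotic".
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    n_in, n_out = len(x_in), len(x_out)
    auc, r_in = _rank_sum_auc(x_in, x_out)
    pooled = np.concatenate([x_in, x_out])
    ranks = rankdata(pooled)
    if np.ptp(pooled) == 0:
        return 0.5, 1.0, "degenerate"
    if n_in + n_out <= EXACT_MAX:
        if len(np.unique(pooled)) == len(pooled):
            p = _exact_ranksum_p_no_ties(n_in, n_out, r_in)
        else:
            p = _exact_ranksum_p_ties(ranks, n_in, r_in)
        return auc, p, "exact"
    return auc, _asymptotic_ranksum_p(ranks, n_in, r_in), "asymptotic"


def auc_enrichment(
    scores: SignatureScores,
    clusters: ClusterAssignment,
    cluster_id: int,
) -> EnrichmentResult:
    """ROC-AUC enrichment of a signature score in one cluster vs the rest."""
    if cluster_id not in clusters.cluster_ids:
        raise ValueError(f"cluster {cluster_id} not present")
    mask = clusters.mask(cluster_id)
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError(
            f"degenerate cluster sizes for AUC: in={n_in}, out={n_out} (need >= 2 each)"
        )
    auc, p, method = rank_sum_test(scores.scores[mask], scores.scores[~mask])
    return EnrichmentResult(
        signature_name=scores.signature_name,
        cluster_id=int(cluster_id),
        auc=float(auc),
        p_value=float(p),
        enriched=bool(auc > AUC_THRESHOLD and p < P_THRESHOLD),
        n_in=n_in,
        n_out=n_out,
        method=method,
    )


def enrichment_table(
    scaled: ScaledMatrix,
    signatures: Sequence[GeneSignature],
    clusters: ClusterAssignment,
    min_overlap_frac: float = 0.2,
) -> pd.DataFrame:
    """One enrichment row per (signature, cluster); BH-adjusted p alongside.

    The ``enriched`` flag uses the raw p < 0.01 rule; the ``bh_p`` column is
    reported for transparency only.
    """
    if len(signatures) == 0:
        raise ValueError("no signatures supplied")
    ids = clusters.cluster_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 clusters for enrichment")
    rows = []
    for sig in signatures:
        sc = score_signature(scaled, sig, min_overlap_frac=min_overlap_frac)
        for cid in ids:
            r = auc_enrichment(sc, clusters, cid)
            rows.append(
                {
                    "signature": r.signature_name,
                    "cluster": r.cluster_id,
                    "auc": r.auc,
                    "p_value": r.p_value,
                    "enriched": r.enriched,
                    "n_in": r.n_in,
                    "n_out": r.n_out,
                }
            )
    table = pd.DataFrame(rows)
    table["bh_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def auc_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long enrichment table into a signature x cluster AUC matrix."""
    return table.pivot(index="signature", columns="cluster", values="auc")


def correlation_band(r: float) -> str:
    """Band label for a Pearson coefficient: |r| in [0.3, 0.5) is moderate,
    [0.5, 0.9] is strong, anything else none."""
    a = abs(r)
    if 0.3 <= a < 0.5:
        return "moderate"
    if 0.5 <= a <= 0.9:
        return "strong"
    return "none"


def signature_correlation(
    a: SignatureScores,
    b: SignatureScores,
    cell_subset=None,
) -> AssociationResult:
    """Pearson correlation between two signature score vectors, optionally on
    a cell subset (boolean mask over the shared cell universe)."""
    if len(a.scores) != len(b.scores) or not np.array_equal(a.barcodes, b.barcodes):
        raise ValueError("score vectors must share the same cell universe")
    xs, ys = a.scores, b.scores
    if cell_subset is not None:
        m = np.asarray(cell_subset, dtype=bool)
        xs, ys = xs[m], ys[m]
    if len(xs) < 3:
        raise ValueError("subset too small for correlation (need >= 3 cells)")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in a score vector on the subset")
    r, p = stats.pearsonr(xs, ys)
    return AssociationResult(
        label=f"{a.signature_name}~{b.signature_name}",
        pearson_r=float(r),
        r_p_value=float(p),
        band_label=correlation_band(r),
        n=len(xs),
    )


def signature_regression(
    y: SignatureScores,
    xs: Sequence[SignatureScores],
    cell_subset=None,
    cond_max: float = 1e8,
) -> AssociationResult:
    """OLS fit of one signature score on others (with intercept).

    Raises on a numerically collinear design (condition number above
    ``cond_max``).
    """
    if not xs:
        raise ValueError("no predictors")
    for x in xs:
        if not np.array_equal(x.barcodes, y.barcodes):
            raise ValueError("score vectors must share the same cell universe")
    yy = y.scores
    X = np.column_stack([x.scores for x in xs])
    if cell_subset is not None:
        m = np.asarray(cell_subset, dtype=bool)
        yy, X = yy[m], X[m]
    if len(yy) <= X.shape[1] + 1:
        raise ValueError("subset too small for regression")
    design = sm.add_constant(X)
    if np.linalg.cond(design) > cond_max:
        raise ValueError("collinear predictors (design condition number too large)")
    fit = sm.OLS(yy, design).fit()
    names = ["intercept"] + [x.signature_name for x in xs]
    coef = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    return AssociationResult(
        label=f"{y.signature_name}~" + "+".join(x.signature_name for x in xs),
        coefficients=coef,
        r_squared=float(fit.rsquared),
        n=len(yy),
    )
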