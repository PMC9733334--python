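"""Cell-cycle phase scoring and regression.

Phase scoring follows the expression-matched control-gene scheme: genes are
binned by their mean expression across cells, and each program gene draws
``n_ctrl`` control genes from its own bin; the raw program score of a cell
is its mean program-gene expression minus its mean control-gene expression,
and the stored score is null-calibrated against random bin-matched gene
sets (see ``cc_score``).  Cells scoring non-positive on both programs are
called G1, otherwise the higher of the S and G2M scores decides the phase.

Cell-cycle regression residualizes each gene on the two phase scores by
least squares and re-standardizes, removing proliferation signal before
re-clustering or re-scoring.

The packaged S (43 genes) and G2M (54 genes) lists are the standard human
cell-cycle program symbols widely used for this purpose; users may
substitute their own lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, NormalizedMatrix, ScaledMatrix
from .preprocess import scale_genes

__all__ = [
    "S_GENES",
    "G2M_GENES",
    "CellCycleScores",
    "cc_score",
    "cc_regress",
    "phase_composition",
]

S_GENES = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "MLF1IP", "HELLS", "RFC2",
    "RPA2", "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7",
    "POLD3", "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1",
    "TIPIN", "DSCC1", "BLM", "CASP8AP2", "USP1", "CLSPN", "POLA1", "CHAF1B",
    "BRIP1", "E2F8",
]

G2M_GENES = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "FAM64A",
    "SMC4", "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "HN1", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "CTCF", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
]


@dataclass
class CellCycleScores:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "G1" | "S" | "G2M" per cell
    barcodes: np.ndarray
    n_bins: int
    n_ctrl: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "s_score": self.s_score,
                "g2m_score": self.g2m_score,
                "phase": self.phase,
            }
        )


def _random_bin_matched_set(
    bins: np.ndarray, gene_bins: np.ndarray, rng: np.random.Generator,
    exclude: np.ndarray,
) -> np.ndarray:
    """Random gene set with the same bin profile as the program."""
    out = np.empty(len(gene_bins), dtype=int)
    for j, b in enumerate(gene_bins):
        pool = np.flatnonzero((bins == b) & ~exclude)
        if len(pool) == 0:
            pool = np.flatnonzero((np.abs(bins - b) <= 1) & ~exclude)
        out[j] = rng.choice(pool)
    return out


def _calibrated_score(
    X: np.ndarray,
    gene_idx: np.ndarray,
    bins: np.ndarray,
    rng: np.random.Generator,
    n_ctrl: int,
    exclude: np.ndarray,
    n_null: int,
    null_sd_factor: float,
) -> np.ndarray:
    """Null-calibrated program score.

    Raw score minus (mean + ``null_sd_factor`` SD) of the scores of
    ``n_null`` random bin-matched gene sets, computed per cell against the
    same control set.  Program genes of either program are excluded from
    control and null pools: in compact gene universes they can dominate the
    top expression bins and would cancel the signal.
    """
    ctrl_idx = set()
    for gi in gene_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~exclude)
        if len(pool) == 0:
            pool = np.flatnonzero((np.abs(bins - bins[gi]) <= 1) & ~exclude)
        if len(pool) == 0:
            raise ValueError("no candidate control genes outside the programs")
        k = min(n_ctrl, len(pool))
        ctrl_idx.update(rng.choice(pool, size=k, replace=False).tolist())
    ctrl = np.array(sorted(ctrl_idx), dtype=int)
    ctrl_mean = X[ctrl, :].mean(axis=0)
    raw = X[gene_idx, :].mean(axis=0) - ctrl_mean

    gene_bins = bins[gene_idx]
    null = np.empty((n_null, X.shape[1]))
    for j in range(n_null):
        rs = _random_bin_matched_set(bins, gene_bins, rng, exclude)
        null[j] = X[rs, :].mean(axis=0) - ctrl_mean
    return raw - (null.mean(axis=0) + null_sd_factor * null.std(axis=0, ddof=1))


def cc_score(
    norm: NormalizedMatrix,
    s_genes=None,
    g2m_genes=None,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    n_null: int = 50,
    null_sd_factor: float = 2.5,
) -> CellCycleScores:
    """Score each cell for S and G2M programs and assign a phase.

    The raw program score (program mean minus expression-matched control
    mean) is symmetric noise in cells that express neither program, so its
    sign alone cannot separate quiescent cells from cycling ones.  Each
    score is therefore null-calibrated: ``n_null`` random bin-matched gene
    sets of the same size are scored per cell, and the stored score is the
    raw score minus (null mean + ``null_sd_factor`` null SDs).  The default
    factor of 2.5 keeps the joint false-call rate over the two programs to
    a few percent, so non-cycling cells score non-positive on both programs
    with high probability while program-on cells remain clearly positive.

    G1 iff both calibrated scores are <= 0; otherwise the larger score
    wins.  Control and null sets are drawn with a fixed seed, so scoring is
    reproducible.
    """
    s_genes = S_GENES if s_genes is None else list(s_genes)
    g2m_genes = G2M_GENES if g2m_genes is None else list(g2m_genes)
    if not s_genes or not g2m_genes:
        raise ValueError("S and G2M gene lists must be nonempty")
    if set(s_genes) & set(g2m_genes):
        raise ValueError("S and G2M gene lists overlap")
    universe = {g: i for i, g in enumerate(norm.gene_names)}
    s_idx = np.array([universe[g] for g in s_genes if g in universe], dtype=int)
    g2m_idx = np.array([universe[g] for g in g2m_genes if g in universe], dtype=int)
    if len(s_idx) == 0 or len(g2m_idx) == 0:
        raise ValueError("program genes entirely absent from the matrix")

    X = norm.values
    mean_expr = X.mean(axis=1)
    # equal-occupancy bins over the mean-expression ranking
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    bins[order] = np.floor(
        np.arange(len(mean_expr)) * n_bins / len(mean_expr)
    ).astype(int)

    rng = np.random.default_rng(seed)
    exclude = np.zeros(X.shape[0], dtype=bool)
    exclude[s_idx] = True
    exclude[g2m_idx] = True
    s_score = _calibrated_score(X, s_idx, bins, rng, n_ctrl, exclude, n_null,
                                null_sd_factor)
    g2m_score = _calibrated_score(X, g2m_idx, bins, rng, n_ctrl, exclude,
                                  n_null, null_sd_factor)

    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return CellCycleScores(
        s_score=s_score,
        g2m_score=g2m_score,
        phase=phase,
        barcodes=norm.barcodes,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def cc_regress(scaled: ScaledMatrix, scores: CellCycleScores) -> ScaledMatrix:
    """Residualize each gene on (s_score, g2m_score, intercept), then
    re-standardize gene-wise.

    When both score vectors are constant there is nothing to remove; the
    input is returned (re-standardized) with a warning.
    """
    if len(scores.s_score) != scaled.shape[1]:
        raise ValueError("scores do not cover the matrix's cells")
    s, g = scores.s_score, scores.g2m_score
    if np.ptp(s) == 0 and np.ptp(g) == 0:
        warnings.warn("constant cell-cycle scores; regression skipped")
        resid = scaled.values
    else:
        cols = [np.ones_like(s)]
        for v in (s, g):
            if np.ptp(v) > 0:
                cols.append(v)
        design = np.column_stack(cols)  # cells x p
        beta, *_ = np.linalg.lstsq(design, scaled.values.T, rcond=None)
        resid = (scaled.values.T - design @ beta).T
    # re-standardize so downstream scoring sees a valid z matrix
    tmp = NormalizedMatrix(
        values=resid,
        gene_names=scaled.gene_names,
        barcodes=scaled.barcodes,
        batch=scaled.batch,
    )
    return scale_genes(tmp, clip=scaled.clip_bound)


def phase_composition(
    clusters: ClusterAssignment, scores: CellCycleScores
) -> pd.DataFrame:
    """Percent of cells in each phase, per cluster (rows sum to 100)."""
    df = pd.DataFrame({"cluster": clusters.labels, "phase": scores.phase})
    table = (
        df.groupby("cluster")["phase"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        * 100.0
    )
    for ph in ("G1", "S", "G2M"):
        if ph not in table.columns:
            table[ph] = 0.0
    return table[["G1", "S", "G2M"]]
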