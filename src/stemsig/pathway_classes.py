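"""Four-way per-cell pathway-activity classification.

Each cell is classified on two signature score vectors (e.g. an estrogen
receptor program and an NF-kB program) by strict thresholding:
dual-positive when both exceed their thresholds, singly active when exactly
one does, dual-negative otherwise.  This is the computational analogue of a
dual-reporter sort.  Cluster-level abundance shifts and per-class marker
expression complete the readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClusterAssignment, NormalizedMatrix
from .fea import SignatureScores

__all__ = [
    "CLASS_NAMES",
    "PathwayClassLabels",
    "classify_cells",
    "class_abundance",
    "class_marker_expression",
]

CLASS_NAMES = ("dual_negative", "a_active", "b_active", "dual_positive")


@dataclass
class PathwayClassLabels:
    labels: np.ndarray  # one of CLASS_NAMES per cell
    barcodes: np.ndarray
    t_a: float
    t_b: float
    name_a: str = "a"
    name_b: str = "b"

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().reindex(CLASS_NAMES, fill_value=0)


def classify_cells(
    a: SignatureScores,
    b: SignatureScores,
    t_a: float = 0.0,
    t_b: float = 0.0,
) -> PathwayClassLabels:
    """Strict-threshold four-way classification on two score vectors.

    A score exactly at its threshold counts as inactive.
    """
    if len(a.scores) != len(b.scores) or not np.array_equal(a.barcodes, b.barcodes):
        raise ValueError("score vectors must share the same cell universe")
    a_on = a.scores > t_a
    b_on = b.scores > t_b
    labels = np.where(
        a_on & b_on,
        "dual_positive",
        np.where(a_on, "a_active", np.where(b_on, "b_active", "dual_negative")),
    )
    return PathwayClassLabels(
        labels=labels,
        barcodes=a.barcodes,
        t_a=t_a,
        t_b=t_b,
        name_a=a.signature_name,
        name_b=b.signature_name,
    )


def class_abundance(
    labels: PathwayClassLabels,
    clusters: ClusterAssignment,
    cluster_id: int,
    mode: str = "relative",
) -> pd.DataFrame:
    """Abundance of each class inside one cluster vs the whole population.

    percent_change is 100 * (f_cluster - f_overall) / f_overall in
    ``relative`` mode (NaN when a class is absent overall), or the absolute
    difference in percentage points in ``absolute`` mode.  The p-value is a
    two-sided two-proportion test (chi-squared without continuity
    correction) of in-cluster vs out-of-cluster class membership.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    mask = clusters.mask(cluster_id)
    if mask.sum() == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    n_in = int(mask.sum())
    n_all = len(labels.labels)
    rows = []
    for cls in CLASS_NAMES:
        is_cls = labels.labels == cls
        k_in = int((is_cls & mask).sum())
        k_all = int(is_cls.sum())
        f_in = k_in / n_in
        f_all = k_all / n_all
        if mode == "relative":
            pc = np.nan if k_all == 0 else 100.0 * (f_in - f_all) / f_all
        else:
            pc = 100.0 * (f_in - f_all)
        k_out = k_all - k_in
        n_out = n_all - n_in
        table = np.array([[k_in, n_in - k_in], [k_out, n_out - k_out]])
        if table.sum(axis=1).min() == 0 or k_all in (0, n_all):
            p = np.nan
        else:
            p = stats.chi2_contingency(table, correction=False)[1]
        rows.append(
            {
                "class": cls,
                "n_in_cluster": k_in,
                "fraction_in_cluster": f_in,
                "fraction_overall": f_all,
                "percent_change": pc,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def class_marker_expression(
    norm: NormalizedMatrix,
    labels: PathwayClassLabels,
    genes,
    reference: str = "dual_negative",
) -> pd.DataFrame:
    """Per-class mean expression of the given genes and fold change vs a
    reference class (on de-logged means with a pseudocount), with a rank-sum
    p-value against the reference."""
    genes = list(genes)
    universe = {g: i for i, g in enumerate(norm.gene_names)}
    missing = [g for g in genes if g not in universe]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    ref_mask = labels.labels == reference
    if ref_mask.sum() == 0:
        raise ValueError(f"reference class {reference!r} is empty")
    eps = 1e-9
    rows = []
    for g in genes:
        expr = norm.values[universe[g], :]
        ref_expr = expr[ref_mask]
        ref_mean = np.expm1(ref_expr).mean()
        for cls in CLASS_NAMES:
            m = labels.labels == cls
            if m.sum() == 0:
                rows.append(
                    {"gene": g, "class": cls, "n_cells": 0, "mean_norm": np.nan,
                     "fold_change_vs_ref": np.nan, "p_value": np.nan}
                )
                continue
            cls_expr = expr[m]
            fc = (np.expm1(cls_expr).mean() + eps) / (ref_mean + eps)
            if cls == reference or np.ptp(np.concatenate([cls_expr, ref_expr])) == 0:
                p = 1.0
            else:
                p = stats.mannwhitneyu(cls_expr, ref_expr, alternative="two-sided").pvalue
            rows.append(
                {
                    "gene": g,
                    "class": cls,
                    "n_cells": int(m.sum()),
                    "mean_norm": float(cls_expr.mean()),
                    "fold_change_vs_ref": float(fc),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)
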