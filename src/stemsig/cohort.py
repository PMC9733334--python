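"""Bulk-cohort signature stratification and outcome association.

Tumors are stratified on per-gene expression z-scores: a tumor is
signature-positive when at least ``min_altered_genes`` signature genes
exceed the alteration threshold (default 2 standard deviations above the
cohort mean, matching the cBioPortal convention for signatures built from
up-regulated genes).  Group differences in clinical categories use the
Pearson chi-squared test; survival endpoints use the two-group log-rank
test with Kaplan-Meier tables; continuous signature scores are compared by
Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .signatures import GeneSignature

__all__ = [
    "CohortTable",
    "StratificationResult",
    "zscore_cohort",
    "stratify_by_signature",
    "categorical_association",
    "survival_compare",
    "cohort_signature_score",
]


@dataclass
class CohortTable:
    """Bulk expression plus clinical annotation for a tumor cohort.

    expression: gene x tumor DataFrame (raw or z-scored values).
    clinical: tumor-indexed DataFrame with columns grade, subtype,
    rfs_months, rfs_event, os_months, os_event (events binary 0/1).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self):
        if not self.expression.columns.equals(self.clinical.index):
            if set(self.expression.columns) != set(self.clinical.index):
                raise ValueError("expression columns and clinical index differ")
            self.clinical = self.clinical.loc[self.expression.columns]
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate tumor ids")
        for col in ("rfs_months", "os_months"):
            if col in self.clinical and (self.clinical[col] < 0).any():
                raise ValueError(f"negative times in {col}")

    @property
    def n_tumors(self) -> int:
        return self.expression.shape[1]


@dataclass
class StratificationResult:
    positive: pd.Series  # tumor -> bool
    altered_genes: dict  # tumor -> list of altered signature genes
    threshold: float
    mode: str
    min_altered_genes: int
    signature_name: str
    n_genes_used: int

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.positive).sum())


def zscore_cohort(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across tumors (ddof=1); zero-variance genes map to
    zero rows with a warning."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 tumors to z-score")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to zero z")
    z = expr.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def stratify_by_signature(
    z: pd.DataFrame,
    sig: GeneSignature,
    threshold: float = 2.0,
    mode: str = "up",
    min_altered_genes: int = 1,
) -> StratificationResult:
    """Label each tumor signature-positive on its altered signature genes.

    A gene is altered in a tumor when z >= threshold (mode "up") or
    |z| >= threshold (mode "both").
    """
    if mode not in ("up", "both"):
        raise ValueError("mode must be 'up' or 'both'")
    genes = [g for g in sig.genes if g in z.index]
    if not genes:
        raise ValueError(f"no signature genes present in cohort: {sig.name}")
    zz = z.loc[genes]
    altered = zz >= threshold if mode == "up" else zz.abs() >= threshold
    positive = altered.sum(axis=0) >= min_altered_genes
    altered_genes = {
        t: altered.index[altered[t]].tolist() for t in altered.columns
    }
    return StratificationResult(
        positive=positive,
        altered_genes=altered_genes,
        threshold=threshold,
        mode=mode,
        min_altered_genes=min_altered_genes,
        signature_name=sig.name,
        n_genes_used=len(genes),
    )


def categorical_association(labels: pd.Series, clinical_column: pd.Series) -> dict:
    """Pearson chi-squared (no continuity correction) of the stratification
    labels against a categorical clinical column."""
    table = pd.crosstab(labels, clinical_column)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 levels on each margin")
    chi2, p, df, expected = stats.chi2_contingency(table.values, correction=False)
    if (expected == 0).any():
        raise ValueError("expected cell count of 0; merge sparse levels")
    return {"chi2": float(chi2), "df": int(df), "p_value": float(p),
            "table": table}


def survival_compare(labels: pd.Series, time: pd.Series, event: pd.Series) -> dict:
    """Two-group log-rank test with Kaplan-Meier survival tables."""
    labels = labels.astype(bool)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need both positive and negative tumors")
    if event.sum() == 0:
        raise ValueError("no events observed (all censored)")
    for g in (True, False):
        if event[labels == g].sum() == 0:
            warnings.warn(f"group positive={g} has no events")
    res = logrank_test(
        time[labels], time[~labels], event_observed_A=event[labels],
        event_observed_B=event[~labels],
    )
    km_tables = {}
    for name, mask in (("positive", labels), ("negative", ~labels)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        km_tables[name] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time"}
        )
    return {
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
        "km_tables": km_tables,
        "n_positive": int(labels.sum()),
        "n_negative": int((~labels).sum()),
    }


def cohort_signature_score(
    z: pd.DataFrame,
    sig: GeneSignature,
    strata: pd.Series | None = None,
    equal_var: bool = False,
) -> dict:
    """Per-tumor signature score (mean z over signature genes) and, when a
    stratum column is supplied, pairwise Welch t-tests between strata."""
    genes = [g for g in sig.genes if g in z.index]
    if not genes:
        raise ValueError(f"no signature genes present in cohort: {sig.name}")
    score = z.loc[genes].mean(axis=0)
    out = {"score": score, "n_genes_used": len(genes)}
    if strata is not None:
        strata = strata.loc[score.index]
        levels = [l for l in pd.unique(strata.dropna())]
        comps = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = score[strata == levels[i]]
                b = score[strata == levels[j]]
                if len(a) < 2 or len(b) < 2:
                    raise ValueError(
                        f"stratum with < 2 tumors: {levels[i]!r} or {levels[j]!r}"
                    )
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                comps.append(
                    {
                        "level_a": levels[i],
                        "level_b": levels[j],
                        "mean_a": float(a.mean()),
                        "mean_b": float(b.mean()),
                        "t": float(t),
                        "p_value": float(p),
                    }
                )
        out["comparisons"] = pd.DataFrame(comps)
    return out
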