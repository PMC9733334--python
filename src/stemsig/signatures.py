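"""Gene signatures: GMT I/O, DEG-derived cluster signatures, set overlap.

A signature is a named, directed gene list.  Custom cluster signatures are
derived from differentially expressed genes (in-cluster vs rest, rank-sum
test with BH correction and a log2 fold-change floor) the way marker genes
are conventionally called in single-cell workflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ClusterAssignment, NormalizedMatrix

__all__ = [
    "GeneSignature",
    "derive_cluster_signature",
    "signature_overlap",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSignature:
    """Named, directed gene list."""

    name: str
    genes: list
    direction: str = "up"  # up | down | mixed
    provenance: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        seen, out = set(), []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        if len(out) != len(self.genes):
            warnings.warn(f"signature {self.name!r}: duplicate genes removed")
        self.genes = out
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in self.genes


def derive_cluster_signature(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment,
    cluster_id: int,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    min_pct: float = 0.1,
    direction: str = "up",
) -> tuple[pd.DataFrame, GeneSignature | None]:
    """Differential expression of one cluster vs the rest; genes passing the
    thresholds form the cluster's custom signature.

    Per gene: two-sided Wilcoxon rank-sum on normalized expression,
    BH-adjusted over tested genes; log2 fold change computed on de-logged
    per-group means with a pseudocount for sparse stability.

    Returns the full DEG table and the signature (None if no gene passes;
    a warning is emitted in that case).
    """
    in_mask = clusters.mask(cluster_id)
    if cluster_id not in clusters.cluster_ids:
        raise ValueError(f"cluster {cluster_id} not present")
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError(
            f"cluster sizes too small for DE: in={n_in}, out={n_out} (need >= 3 each)"
        )

    X = norm.values
    x_in = X[:, in_mask]
    x_out = X[:, ~in_mask]

    # de-logged means: mean of (exp(x)-1)/scale is the depth-normalized mean
    eps = 1e-9
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log2_fc = np.log2((mean_in + eps) / (mean_out + eps))
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)

    pvals = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        a, b = x_in[i], x_out[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    bh = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": norm.gene_names,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "bh_adjusted_p": bh,
            "pct_in": pct_in,
            "pct_out": pct_out,
        }
    )
    table["direction"] = np.where(table["log2_fc"] > 0, "up", "down")

    if direction == "up":
        keep = (bh < alpha) & (log2_fc > lfc_min) & (pct_in >= min_pct)
    elif direction == "down":
        keep = (bh < alpha) & (log2_fc < -lfc_min) & (pct_out >= min_pct)
    else:
        keep = (bh < alpha) & (np.abs(log2_fc) > lfc_min)
    genes = [str(g) for g in np.asarray(norm.gene_names)[keep]]
    prov = (
        f"derived from cluster {cluster_id} DEGs "
        f"(lfc_min={lfc_min}, alpha={alpha}, min_pct={min_pct}, direction={direction})"
    )
    if not genes:
        warnings.warn(f"no DEGs pass thresholds for cluster {cluster_id}; empty signature")
        return table, None
    sig = GeneSignature(
        name=f"cluster{cluster_id}_signature",
        genes=genes,
        direction=direction if direction != "both" else "mixed",
        provenance=prov,
    )
    return table, sig


def signature_overlap(a: GeneSignature, b: GeneSignature) -> dict:
    """Exact set overlap between two signatures.

    Returns |a n b|, percent of a's genes found in b, and vice versa.
    """
    sa, sb = set(a.genes), set(b.genes)
    inter = sa & sb
    return {
        "n_intersection": len(inter),
        "pct_a_in_b": 100.0 * len(inter) / len(sa),
        "pct_b_in_a": 100.0 * len(inter) / len(sb),
        "genes": sorted(inter),
    }


def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT gene-set file (name <tab> description <tab> genes...)."""
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and >= 1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sigs.append(GeneSignature(name=name, genes=genes, provenance=desc))
    return sigs


def write_gmt(signatures, path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.provenance or "na"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")
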