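"""QC filtering, normalization, gene-wise scaling, clustering, batch combination.

The QC rules follow the standard droplet scRNA-seq conventions: cells with
fewer than ``min_genes`` expressed genes or more than ``max_mito_frac`` of
reads mapping to mitochondrial genes are removed, along with externally
labelled doublets.  Normalization is depth normalization to a fixed scale
factor followed by log1p; scaling is a per-gene z-score with clipping.
Batch combination is a within-batch standardization: each batch is
normalized and z-scored independently on the shared gene universe, which by
construction removes per-batch location effects before concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import ClusterAssignment, CountMatrix, NormalizedMatrix, ScaledMatrix

__all__ = [
    "QCReport",
    "qc_filter",
    "normalize_log",
    "scale_genes",
    "cluster_cells",
    "combine_batches",
]


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_low_genes: int
    n_high_mito: int
    n_doublet: int
    min_genes: int
    max_mito_frac: float
    removed_barcodes: dict = field(default_factory=dict)  # barcode -> reason

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.removed_barcodes.items()), columns=["barcode", "reason"]
        )


def qc_filter(
    counts: CountMatrix,
    min_genes: int = 2000,
    max_mito_frac: float = 0.15,
    doublet_labels=None,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-complexity cells, high-mitochondrial cells and labelled doublets.

    A cell is removed when its expressed-gene count is < ``min_genes``, its
    mitochondrial read fraction is > ``max_mito_frac``, or its doublet label
    is True.  Reasons are recorded per removed barcode with precedence
    doublet > lowdepth > highmito when several apply.
    """
    if min_genes <= 0 or not (0 < max_mito_frac <= 1):
        raise ValueError("thresholds must be positive (mito fraction in (0, 1])")
    gpc = counts.genes_per_cell()
    mito = counts.mito_fraction()
    low = gpc < min_genes
    high = mito > max_mito_frac
    if doublet_labels is None:
        doub = np.zeros(counts.n_cells, dtype=bool)
    else:
        doub = np.asarray(doublet_labels, dtype=bool)
        if len(doub) != counts.n_cells:
            raise ValueError("doublet_labels length mismatch")
    remove = low | high | doub
    reasons = {}
    for i in np.flatnonzero(remove):
        if doub[i]:
            reasons[str(counts.barcodes[i])] = "doublet"
        elif low[i]:
            reasons[str(counts.barcodes[i])] = "lowdepth"
        else:
            reasons[str(counts.barcodes[i])] = "highmito"
    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int((~remove).sum()),
        n_low_genes=int(low.sum()),
        n_high_mito=int(high.sum()),
        n_doublet=int(doub.sum()),
        min_genes=min_genes,
        max_mito_frac=max_mito_frac,
        removed_barcodes=reasons,
    )
    if report.n_retained == 0:
        dominant = max(
            [("lowdepth", low.sum()), ("highmito", high.sum()), ("doublet", doub.sum())],
            key=lambda t: t[1],
        )[0]
        raise ValueError(
            f"no cells survive QC (dominant removal reason: {dominant})"
        )
    return counts.subset_cells(~remove), report


def normalize_log(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize each cell to ``scale`` total counts, then log1p."""
    X = counts.dense().astype(float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        bad = counts.barcodes[totals <= 0]
        raise ValueError(
            f"{len(bad)} all-zero cell(s) (e.g. {bad[0]}); run qc_filter first"
        )
    vals = np.log1p(scale * X / totals)
    return NormalizedMatrix(
        values=vals,
        gene_names=counts.gene_names,
        barcodes=counts.barcodes,
        batch=counts.batch,
        scale=scale,
    )


def scale_genes(norm: NormalizedMatrix, clip: float | None = 10.0) -> ScaledMatrix:
    """Per-gene z-score across cells, clipped to +/- ``clip``.

    Zero-variance genes become all-zero rows so that downstream signature
    scores stay finite.  Standard deviation uses ddof=1.
    """
    X = norm.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[(sd == 0).ravel(), :] = 0.0
    Z = np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0)
    if clip is not None:
        Z = np.clip(Z, -clip, clip)
    return ScaledMatrix(
        values=Z,
        gene_names=norm.gene_names,
        barcodes=norm.barcodes,
        batch=norm.batch,
        clip_bound=clip,
    )


def cluster_cells(
    scaled: ScaledMatrix,
    n_clusters: int = 4,
    n_pcs: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA on the scaled matrix followed by k-means; deterministic under seed."""
    n_genes, n_cells = scaled.shape
    if n_clusters > n_cells:
        raise ValueError(f"{n_clusters} clusters requested for {n_cells} cells")
    n_pcs = min(n_pcs, min(n_genes, n_cells) - 1)
    if n_pcs < 1:
        raise ValueError("matrix too small for PCA")
    X = scaled.values.T  # cells x genes for sklearn
    solver = "full" if min(X.shape) <= 500 else "randomized"
    pcs = PCA(
        n_components=n_pcs, svd_solver=solver, random_state=seed
    ).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
    return ClusterAssignment(
        labels=km.labels_.astype(int),
        barcodes=scaled.barcodes,
        method="pca_kmeans",
        params={"n_clusters": n_clusters, "n_pcs": n_pcs},
        seed=seed,
    )


def combine_batches(matrices: list[CountMatrix], scale: float = 1e4,
                    clip: float | None = 10.0) -> ScaledMatrix:
    """Normalize and z-score each batch independently, then concatenate.

    Gene universe is the intersection across batches (order taken from the
    first matrix).  Barcodes are prefixed with the batch index when needed to
    stay unique.  Per-gene means are ~0 within each batch by construction,
    which removes batch location effects; this is a deliberate simplification
    relative to anchor-based integration and is recorded in the provenance.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    shared = set(matrices[0].gene_names)
    for m in matrices[1:]:
        shared &= set(m.gene_names)
    if not shared:
        raise ValueError("empty gene intersection across batches")
    order = [g for g in matrices[0].gene_names if g in shared]

    blocks, barcodes, batch_labels = [], [], []
    seen = set()
    for bi, m in enumerate(matrices):
        idx = {g: i for i, g in enumerate(m.gene_names)}
        gmask = np.array([idx[g] for g in order], dtype=int)
        sub = m.subset_genes(np.isin(np.arange(m.n_genes), gmask))
        # subset_genes keeps original order; reorder to `order`
        reorder = {g: i for i, g in enumerate(sub.gene_names)}
        perm = np.array([reorder[g] for g in order], dtype=int)
        dense = sub.dense()[perm, :]
        bm = CountMatrix(
            values=dense,
            gene_names=np.array(order, dtype=object),
            barcodes=sub.barcodes,
            batch=sub.batch,
            mito_flag=sub.mito_flag[perm],
        )
        z = scale_genes(normalize_log(bm, scale=scale), clip=clip)
        blocks.append(z.values)
        for bc, ba in zip(bm.barcodes, bm.batch):
            key = bc if bc not in seen else f"b{bi}:{bc}"
            seen.add(key)
            barcodes.append(key)
            batch_labels.append(f"b{bi}:{ba}" if ba == "batch0" else str(ba))
    return ScaledMatrix(
        values=np.concatenate(blocks, axis=1),
        gene_names=np.array(order, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        batch=np.array(batch_labels, dtype=object),
        clip_bound=clip,
    )
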