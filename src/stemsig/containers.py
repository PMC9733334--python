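"""In-memory containers for the gene x cell expression pipeline.

The genes-as-rows convention is used throughout: ``values[g, c]`` is the
measurement of gene ``g`` in cell ``c``.  Raw counts may be stored sparse
(any scipy.sparse matrix); normalized and scaled values are dense float
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class CountMatrix:
    """Raw gene x cell integer counts with annotation.

    Attributes
    ----------
    values : (n_genes, n_cells) array or sparse matrix of non-negative ints
    gene_names : unique gene symbols, one per row
    barcodes : unique cell barcodes, one per column
    batch : per-cell batch label (defaults to a single batch "batch0")
    mito_flag : per-gene boolean, True for mitochondrial genes
    """

    values: object
    gene_names: np.ndarray
    barcodes: np.ndarray
    batch: Optional[np.ndarray] = None
    mito_flag: Optional[np.ndarray] = None

    def __post_init__(self):
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        n_genes, n_cells = self.shape
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene_names length {len(self.gene_names)} != rows {n_genes}"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcodes length {len(self.barcodes)} != columns {n_cells}"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("barcodes must be unique")
        if self.batch is None:
            self.batch = np.array(["batch0"] * n_cells, dtype=object)
        else:
            self.batch = _as_str_array(self.batch)
            if len(self.batch) != n_cells:
                raise ValueError("batch length mismatch")
        if self.mito_flag is None:
            self.mito_flag = np.array(
                [str(g).upper().startswith("MT-") for g in self.gene_names]
            )
        else:
            self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
            if len(self.mito_flag) != n_genes:
                raise ValueError("mito_flag length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.shape[0]

    @property
    def n_cells(self) -> int:
        return self.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        v = self.values
        if sp.issparse(v):
            return np.asarray((v > 0).sum(axis=0)).ravel()
        return (np.asarray(v) > 0).sum(axis=0)

    def mito_fraction(self) -> np.ndarray:
        """Mitochondrial reads / total reads, per cell (0 for empty cells)."""
        v = self.values
        if sp.issparse(v):
            total = np.asarray(v.sum(axis=0)).ravel().astype(float)
            mito = np.asarray(v[self.mito_flag, :].sum(axis=0)).ravel().astype(float)
        else:
            v = np.asarray(v)
            total = v.sum(axis=0).astype(float)
            mito = v[self.mito_flag, :].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
        return frac

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        v = self.values[:, mask] if not sp.issparse(self.values) else self.values.tocsc()[:, mask]
        return CountMatrix(
            values=v,
            gene_names=self.gene_names,
            barcodes=self.barcodes[mask],
            batch=self.batch[mask],
            mito_flag=self.mito_flag,
        )

    def subset_genes(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        v = self.values[mask, :] if not sp.issparse(self.values) else self.values.tocsr()[mask, :]
        return CountMatrix(
            values=v,
            gene_names=self.gene_names[mask],
            barcodes=self.barcodes,
            batch=self.batch,
            mito_flag=self.mito_flag[mask],
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized, log-transformed gene x cell expression.

    ``values[g, c] = log(1 + scale * count[g, c] / total[c])``.
    """

    values: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    batch: Optional[np.ndarray] = None
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        if self.batch is None:
            self.batch = np.array(["batch0"] * self.values.shape[1], dtype=object)
        else:
            self.batch = _as_str_array(self.batch)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def shape(self):
        return self.values.shape

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


@dataclass
class ScaledMatrix:
    """Gene-wise z-scored expression, optionally clipped to +/- clip_bound.

    Zero-variance genes are represented as all-zero rows rather than NaN.
    """

    values: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    batch: Optional[np.ndarray] = None
    clip_bound: Optional[float] = 10.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = _as_str_array(self.gene_names)
        self.barcodes = _as_str_array(self.barcodes)
        if self.batch is None:
            self.batch = np.array(["batch0"] * self.values.shape[1], dtype=object)
        else:
            self.batch = _as_str_array(self.batch)

    @property
    def shape(self):
        return self.values.shape

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels (0-based ints) plus fitting provenance."""

    labels: np.ndarray
    barcodes: np.ndarray
    method: str = "external"
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.barcodes = _as_str_array(self.barcodes)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("labels/barcodes length mismatch")

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    def relabeled(self, mapping: dict) -> "ClusterAssignment":
        new = np.array([mapping[l] for l in self.labels], dtype=int)
        return replace(self, labels=new)
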