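"""Reading and writing the pipeline's file formats.

Count matrices come in as Matrix Market 10x-style triplets (matrix.mtx +
features.tsv + barcodes.tsv, genes as rows) or dense TSV (genes as rows,
header row of barcodes).  All tabular outputs are TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_tsv",
    "write_dense_tsv",
    "write_tables",
]


def read_mtx_triplet(directory, mito_prefix: str = "MT-") -> CountMatrix:
    """Read matrix.mtx + features.tsv + barcodes.tsv from a directory."""
    mtx_path = os.path.join(directory, "matrix.mtx")
    feat_path = os.path.join(directory, "features.tsv")
    bc_path = os.path.join(directory, "barcodes.tsv")
    for p in (mtx_path, feat_path, bc_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(mtx_path).tocsr()
    features = pd.read_csv(feat_path, sep="\t", header=None)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)
    genes = features.iloc[:, 0].astype(str).to_numpy()
    bcs = barcodes.iloc[:, 0].astype(str).to_numpy()
    if mat.shape[0] != len(genes) or mat.shape[1] != len(bcs):
        raise ValueError(
            f"dimension mismatch: matrix {mat.shape}, "
            f"{len(genes)} features, {len(bcs)} barcodes"
        )
    mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in genes])
    return CountMatrix(
        values=mat.astype(np.int64),
        gene_names=genes,
        barcodes=bcs,
        mito_flag=mito,
    )


def write_mtx_triplet(counts: CountMatrix, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    values = counts.values
    if not sp.issparse(values):
        values = sp.coo_matrix(values)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), values, field="integer")
    pd.DataFrame({0: counts.gene_names}).to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.DataFrame({0: counts.barcodes}).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_dense_tsv(path, mito_prefix: str = "MT-") -> CountMatrix:
    """Dense TSV with genes as rows and a header row of barcodes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
        raise ValueError("counts must be non-negative numbers")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integral")
    genes = df.index.astype(str).to_numpy()
    mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in genes])
    return CountMatrix(
        values=vals.astype(np.int64),
        gene_names=genes,
        barcodes=df.columns.astype(str).to_numpy(),
        mito_flag=mito,
    )


def write_dense_tsv(counts: CountMatrix, path) -> None:
    pd.DataFrame(
        counts.dense(), index=counts.gene_names, columns=counts.barcodes
    ).to_csv(path, sep="\t")


def write_tables(results: dict, directory) -> None:
    """Write a dict of name -> DataFrame/Series as TSV files."""
    os.makedirs(directory, exist_ok=True)
    for name, obj in results.items():
        path = os.path.join(directory, f"{name}.tsv")
        if isinstance(obj, pd.Series):
            obj.to_frame().to_csv(path, sep="\t")
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=bool(obj.index.name) or not isinstance(
                obj.index, pd.RangeIndex))
        else:
            raise TypeError(f"cannot write {name}: {type(obj)}")
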