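"""Readers and writers for count matrices, spike-in tables and results.

Supported on-disk formats: dense tab-delimited count matrices (first column
gene ids, header row of cell ids), the 10X-style MatrixMarket triplet layout
(``matrix.mtx`` + ``genes.tsv``/``features.tsv`` + ``barcodes.tsv``), the
ERCC-style tab-delimited concentration table, and a per-cell label TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CountMatrix, DataError, NormalizedMatrix, SpikeInReference

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_spikein_reference",
    "read_labels",
    "write_normalized",
    "read_normalized",
]

DEFAULT_SPIKEIN_PREFIX = "ERCC-"


def read_counts_tsv(
    path: str | Path,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> CountMatrix:
    """Read a dense TSV count matrix (rows genes, columns cells).

    Rows whose gene id starts with ``spikein_prefix`` are flagged as
    spike-ins.  Non-integer or negative entries raise :class:`DataError`
    naming the offending gene and cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] == 0:
        raise DataError(f"{path}: no data rows")
    if df.shape[1] == 0:
        raise DataError(f"{path}: no cell columns")
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()][0]
        raise DataError(f"{path}: duplicate gene id {dup!r}")
    if len(set(cell_ids)) != len(cell_ids):
        raise DataError(f"{path}: duplicate cell ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(_is_number)(values))
        i, j = bad[0]
        raise DataError(
            f"{path}: non-numeric entry {values[i, j]!r} at gene "
            f"{gene_ids[i]!r}, cell {cell_ids[j]!r}"
        )
    values = values.astype(float)
    bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.floor(values)))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"{path}: invalid count {values[i, j]!r} at gene {gene_ids[i]!r}, "
            f"cell {cell_ids[j]!r} (counts must be non-negative integers)"
        )
    is_spikein = np.array([g.startswith(spikein_prefix) for g in gene_ids])
    return CountMatrix(values.astype(np.int64), gene_ids, cell_ids, is_spikein)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_mtx(
    directory: str | Path,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> CountMatrix:
    """Read a 10X-style MatrixMarket triplet directory.

    Expects ``matrix.mtx`` plus ``genes.tsv`` or ``features.tsv`` (first
    column gene id) and ``barcodes.tsv``; genes are rows of the matrix,
    barcodes are columns.  MatrixMarket's 1-based indices are converted to
    0-based internally by the reader.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    if not mtx_path.exists():
        raise DataError(f"{directory}: matrix.mtx not found")
    genes_path = directory / "genes.tsv"
    if not genes_path.exists():
        genes_path = directory / "features.tsv"
    if not genes_path.exists():
        raise DataError(f"{directory}: genes.tsv / features.tsv not found")
    barcodes_path = directory / "barcodes.tsv"
    if not barcodes_path.exists():
        raise DataError(f"{directory}: barcodes.tsv not found")

    mat = scipy.io.mmread(mtx_path)
    mat = scipy.sparse.coo_matrix(mat).toarray()
    genes_df = pd.read_csv(genes_path, sep="\t", header=None)
    gene_ids = [str(g) for g in genes_df.iloc[:, 0]]
    barcodes = [
        line.strip().split("\t")[0]
        for line in open(barcodes_path)
        if line.strip()
    ]
    if mat.shape[0] != len(gene_ids):
        raise DataError(
            f"{directory}: matrix has {mat.shape[0]} rows but "
            f"{len(gene_ids)} gene ids"
        )
    if mat.shape[1] != len(barcodes):
        raise DataError(
            f"{directory}: matrix has {mat.shape[1]} columns but "
            f"{len(barcodes)} barcodes"
        )
    is_spikein = np.array([g.startswith(spikein_prefix) for g in gene_ids])
    return CountMatrix(mat, gene_ids, barcodes, is_spikein)


def write_counts_mtx(cm: CountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), scipy.sparse.coo_matrix(cm.counts)
    )
    with open(directory / "genes.tsv", "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for c in cm.cell_ids:
            fh.write(f"{c}\n")


def read_spikein_reference(
    path: str | Path,
    id_column: str | int = 0,
    concentration_column: str | int = 1,
    unit: str = "attomoles/uL",
) -> SpikeInReference:
    """Read an ERCC-style tab-delimited spike-in concentration table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    ids = df[id_column] if isinstance(id_column, str) else df.iloc[:, id_column]
    conc = (
        df[concentration_column]
        if isinstance(concentration_column, str)
        else df.iloc[:, concentration_column]
    )
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
        raise DataError(f"{path}: duplicate spike-in id {dup!r}")
    mapping = {}
    for sid, c in zip(ids, conc):
        c = pd.to_numeric(c, errors="coerce")
        if pd.isna(c) or c <= 0:
            raise DataError(f"{path}: non-positive or missing concentration for {sid!r}")
        mapping[sid] = float(c)
    return SpikeInReference(mapping, unit=unit)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``cell_id<TAB>condition``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (cell_id, condition)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_normalized(nm: NormalizedMatrix, path: str | Path) -> None:
    """Write a normalized matrix as TSV with a metadata header comment."""
    if not np.all(np.isfinite(nm.values)):
        raise DataError("refusing to write non-finite normalized values")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# method={nm.method} scale={nm.scale}\n")
        if nm.size_factors is not None:
            fh.write("# size_factors=" + ",".join(f"{s:.17g}" for s in nm.size_factors) + "\n")
        df = pd.DataFrame(nm.values, index=nm.gene_ids, columns=nm.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(fh, sep="\t", float_format="%.17g")


def read_normalized(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    method, scale, size_factors = "unknown", "linear", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("size_factors="):
                size_factors = np.array(
                    [float(x) for x in body.split("=", 1)[1].split(",")]
                )
            else:
                for tok in body.split():
                    if tok.startswith("method="):
                        method = tok.split("=", 1)[1]
                    elif tok.startswith("scale="):
                        scale = tok.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return NormalizedMatrix(
        values=df.to_numpy(dtype=float),
        method=method,
        scale=scale,
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        size_factors=size_factors,
    )
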