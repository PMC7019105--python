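"""Core in-memory containers for count matrices and normalization results.

Conventions used throughout the package: genes are rows, cells are columns,
and all indices are 0-based.  Counts are non-negative integers (reads or
UMIs).  Spike-in transcripts -- synthetic RNA added in known, equal amounts
to every cell's lysate -- live in the same matrix as biological genes and
are distinguished by a boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "SpikeInReference",
    "NormalizedMatrix",
    "clean_counts",
    "compute_fpkm",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class CountMatrix:
    """A genes-by-cells matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` array of non-negative integers.
    gene_ids, cell_ids
        Unique row and column identifiers.
    is_spikein
        Boolean mask over genes marking spike-in rows.  Defaults to all
        ``False``.
    condition
        Optional per-cell condition label (cell type / group).
    gene_lengths
        Optional per-gene transcript lengths in base pairs (for FPKM).
    source_gene_index, source_cell_index
        When the matrix is the product of filtering, these map each row /
        column back to its index in the matrix it was derived from.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_spikein: np.ndarray = None
    condition: np.ndarray | None = None
    gene_lengths: np.ndarray | None = None
    source_gene_index: np.ndarray | None = None
    source_cell_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.floor(self.counts)
            ):
                raise DataError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DataError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise DataError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise DataError("duplicate cell ids")
        if self.is_spikein is None:
            self.is_spikein = np.zeros(n_genes, dtype=bool)
        self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
        if self.is_spikein.shape != (n_genes,):
            raise DataError("is_spikein must have one entry per gene")
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.shape != (n_cells,):
                raise DataError("condition must have one entry per cell")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.int64)
            if self.gene_lengths.shape != (n_genes,):
                raise DataError("gene_lengths must have one entry per gene")
            if np.any(self.gene_lengths <= 0):
                raise DataError("gene_lengths must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def spikein_ids(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.is_spikein) if s]

    def subset(
        self,
        gene_index: np.ndarray | None = None,
        cell_index: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        gi = np.arange(self.n_genes) if gene_index is None else np.asarray(gene_index)
        ci = np.arange(self.n_cells) if cell_index is None else np.asarray(cell_index)
        return CountMatrix(
            counts=self.counts[np.ix_(gi, ci)],
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[j] for j in ci],
            is_spikein=self.is_spikein[gi],
            condition=None if self.condition is None else self.condition[ci],
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[gi],
            source_gene_index=gi,
            source_cell_index=ci,
        )

    def with_condition(self, condition: Sequence) -> "CountMatrix":
        return replace(self, condition=np.asarray(condition, dtype=object))


@dataclass
class SpikeInReference:
    """Known spike-in concentrations, e.g. the ERCC control-mix table.

    Maps spike-in transcript ids to positive concentrations (attomoles/uL
    or molecules per lysate; the unit is carried as metadata only).
    """

    concentrations: Mapping[str, float]
    unit: str = "attomoles/uL"

    def __post_init__(self) -> None:
        conc = dict(self.concentrations)
        for sid, c in conc.items():
            c = float(c)
            if not np.isfinite(c) or c <= 0:
                raise DataError(f"non-positive concentration for spike-in {sid!r}")
            conc[sid] = c
        self.concentrations = conc

    def __len__(self) -> int:
        return len(self.concentrations)

    def __getitem__(self, sid: str) -> float:
        return self.concentrations[sid]

    @property
    def ids(self) -> list[str]:
        return list(self.concentrations)

    def lookup(self, ids: Sequence[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.concentrations]
        if missing:
            raise DataError(f"spike-in ids missing from reference: {missing[:5]}")
        return np.array([self.concentrations[i] for i in ids], dtype=float)


@dataclass
class NormalizedMatrix:
    """Output of a normalization method.

    ``scale`` records whether values are on a log or a linear scale;
    ``size_factors`` holds per-cell divisors for global-scaling methods;
    ``kept_gene_index`` maps each output row to the input row it came from
    (identity unless the method dropped genes).
    """

    values: np.ndarray
    method: str
    scale: str
    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray | None = None
    kept_gene_index: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("normalized values must be finite")
        if self.scale not in ("log", "linear"):
            raise DataError("scale must be 'log' or 'linear'")
        if len(self.gene_ids) != self.values.shape[0]:
            raise DataError("gene_ids length mismatch")
        if len(self.cell_ids) != self.values.shape[1]:
            raise DataError("cell_ids length mismatch")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (self.values.shape[1],):
                raise DataError("size_factors must have one entry per cell")
            if np.any(self.size_factors <= 0):
                raise DataError("size_factors must be positive")
        if self.kept_gene_index is None:
            self.kept_gene_index = np.arange(self.values.shape[0])
        self.kept_gene_index = np.asarray(self.kept_gene_index, dtype=np.int64)
        if len(np.unique(self.kept_gene_index)) != len(self.kept_gene_index):
            raise DataError("kept_gene_index must be injective")


def clean_counts(
    cm: CountMatrix,
    min_gene_total: int = 10,
    min_cell_total: int = 10000,
    exempt_spikeins: bool = True,
    to_fixed_point: bool = False,
) -> CountMatrix:
    """Drop low-count genes and cells.

    A single pass: genes whose row total is below ``min_gene_total`` are
    removed first, then cells whose column total over the *remaining* genes
    is below ``min_cell_total``.  Spike-in rows are exempt from the gene
    filter by default so that small spike-in panels survive.  With
    ``to_fixed_point`` the pass is repeated until nothing changes.

    The returned matrix carries ``source_gene_index`` / ``source_cell_index``
    maps back into ``cm``.
    """
    gene_idx = np.arange(cm.n_genes)
    cell_idx = np.arange(cm.n_cells)
    current = cm
    while True:
        gene_totals = current.counts.sum(axis=1)
        keep_genes = gene_totals >= min_gene_total
        if exempt_spikeins:
            keep_genes |= current.is_spikein
        if not np.any(keep_genes):
            raise DataError("cleaning removed every gene")
        sub_counts = current.counts[keep_genes]
        cell_totals = sub_counts.sum(axis=0)
        keep_cells = cell_totals >= min_cell_total
        if not np.any(keep_cells):
            raise DataError("cleaning removed every cell")
        gene_idx = gene_idx[keep_genes]
        cell_idx = cell_idx[keep_cells]
        nxt = cm.subset(gene_idx, cell_idx)
        unchanged = nxt.counts.shape == current.counts.shape
        current = nxt
        if not to_fixed_point or unchanged:
            break
    current.source_gene_index = gene_idx
    current.source_cell_index = cell_idx
    return current


def compute_fpkm(cm: CountMatrix) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM[i, j] = counts[i, j] * 1e9 / (gene_lengths[i] * column_total[j])``
    where the per-cell "mapped reads" denominator is the column total of
    ``cm`` itself.
    """
    if cm.gene_lengths is None:
        raise DataError("gene_lengths are required to compute FPKM")
    totals = cm.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DataError(
            f"zero column total for cell(s) {[cm.cell_ids[j] for j in zero[:5]]}"
        )
    return cm.counts * 1e9 / (cm.gene_lengths[:, None].astype(float) * totals[None, :])
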