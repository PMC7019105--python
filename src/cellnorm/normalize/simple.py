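"""Simple (library-size) normalization with log transform.

Each cell's counts are divided by the cell's total, multiplied by a fixed
scale factor, and log-transformed with ``ln(x + 1)``:

    Y_ij = ln(X_ij * scale_factor / colsum_j + 1)
"""

from __future__ import annotations

import numpy as np

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = ["SimpleNormalizer", "normalize_simple"]


class SimpleNormalizer(BaseNormalizer):
    """Depth normalization to a fixed scale followed by ``log1p``."""

    method_name = "simple"

    def __init__(self, scale_factor: float = 10000.0):
        self.scale_factor = scale_factor

    def fit(self, X: CountMatrix, y=None):
        if self.scale_factor <= 0:
            raise DataError("scale_factor must be positive")
        totals = self._column_totals(X, "simple")
        self.cell_ids_ = list(X.cell_ids)
        self.size_factors_ = totals / self.scale_factor
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        values = np.log1p(X.counts / self.size_factors_[None, :])
        return NormalizedMatrix(
            values=values,
            method=self.method_name,
            scale="log",
            gene_ids=list(X.gene_ids),
            cell_ids=list(X.cell_ids),
            size_factors=self.size_factors_,
        )


def normalize_simple(cm: CountMatrix, scale_factor: float = 10000.0) -> NormalizedMatrix:
    """One-shot :class:`SimpleNormalizer`."""
    return SimpleNormalizer(scale_factor=scale_factor).fit_transform(cm)
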