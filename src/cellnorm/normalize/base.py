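"""Shared transformer interface for the normalization methods.

Every method is exposed as a scikit-learn style estimator: constructor
parameters are hyper-parameters (available through ``get_params`` /
``set_params``), ``fit`` estimates the method's per-cell / per-gene
quantities from a :class:`~cellnorm.data.CountMatrix`, and ``transform``
applies them, returning a :class:`~cellnorm.data.NormalizedMatrix`.

These normalizers are not inductive: the fitted factors belong to the cells
of the fitted matrix, so ``transform`` expects the same cells it was fitted
on (``fit_transform`` is the typical entry point).  Module-level
``normalize_*`` functions wrap the classes for one-shot use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ..data import CountMatrix, DataError, NormalizedMatrix

__all__ = ["BaseNormalizer"]


class BaseNormalizer(BaseEstimator):
    """Base class: ``fit`` estimates factors, ``transform`` applies them."""

    #: name recorded in the NormalizedMatrix
    method_name: str = "base"

    def fit(self, X: CountMatrix, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, X: CountMatrix) -> NormalizedMatrix:  # pragma: no cover
        raise NotImplementedError

    def fit_transform(self, X: CountMatrix, y=None) -> NormalizedMatrix:
        return self.fit(X, y).transform(X)

    def _check_fitted_cells(self, X: CountMatrix) -> None:
        fitted = getattr(self, "cell_ids_", None)
        if fitted is None:
            raise DataError(f"{type(self).__name__} is not fitted")
        if list(fitted) != list(X.cell_ids):
            raise DataError(
                "transform expects the matrix the normalizer was fitted on "
                "(per-cell factors are not transferable to new cells)"
            )

    @staticmethod
    def _column_totals(X: CountMatrix, name: str) -> np.ndarray:
        totals = X.counts.sum(axis=0).astype(float)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise DataError(
                f"{name}: zero column total for cell(s) "
                f"{[X.cell_ids[j] for j in zero[:5]]}"
            )
        return totals
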