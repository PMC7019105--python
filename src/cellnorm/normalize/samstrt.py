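"""Spike-in based depth normalization with optional Poisson resampling.

Sequencing depth is estimated from the spike-in rows alone, on the premise
that every cell received the same amount of spike-in material: cell ``j``'s
depth factor is its spike-in column total divided by the geometric mean of
all spike-in column totals.  In ``expected`` mode counts are simply divided
by the depth factor; in ``resample`` mode each entry is replaced by the
mean of seeded Poisson draws with that expectation, mimicking resampling
all cells to a common spike-in depth.
"""

from __future__ import annotations

import numpy as np

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = ["SAMstrtNormalizer", "normalize_samstrt"]


class SAMstrtNormalizer(BaseNormalizer):
    """Spike-in depth scaling, deterministic or Poisson-resampled."""

    method_name = "samstrt"

    def __init__(self, mode: str = "resample", n_resamples: int = 20, seed: int = 1):
        self.mode = mode
        self.n_resamples = n_resamples
        self.seed = seed

    def fit(self, X: CountMatrix, y=None):
        if self.mode not in ("expected", "resample"):
            raise DataError("mode must be 'expected' or 'resample'")
        if not np.any(X.is_spikein):
            raise DataError("samstrt requires spike-in rows")
        spike_totals = X.counts[X.is_spikein].sum(axis=0).astype(float)
        zero = np.flatnonzero(spike_totals == 0)
        if zero.size:
            raise DataError(
                f"samstrt: zero spike-in total for cell(s) "
                f"{[X.cell_ids[j] for j in zero[:5]]}"
            )
        geo_mean = np.exp(np.mean(np.log(spike_totals)))
        self.cell_ids_ = list(X.cell_ids)
        self.depth_factors_ = spike_totals / geo_mean
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        expected = X.counts / self.depth_factors_[None, :]
        if self.mode == "expected":
            values = expected
        else:
            rng = np.random.default_rng(self.seed)
            acc = np.zeros_like(expected)
            for _ in range(self.n_resamples):
                acc += rng.poisson(expected)
            values = acc / self.n_resamples
        return NormalizedMatrix(
            values=values,
            method=self.method_name,
            scale="linear",
            gene_ids=list(X.gene_ids),
            cell_ids=list(X.cell_ids),
            size_factors=self.depth_factors_,
            extra={"spikein_rows": np.flatnonzero(X.is_spikein).tolist()},
        )


def normalize_samstrt(
    cm: CountMatrix,
    mode: str = "resample",
    n_resamples: int = 20,
    seed: int = 1,
) -> NormalizedMatrix:
    """One-shot :class:`SAMstrtNormalizer`."""
    return SAMstrtNormalizer(mode=mode, n_resamples=n_resamples, seed=seed).fit_transform(cm)
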