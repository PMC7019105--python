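"""Stable-gene linear-model normalization.

Counts are first put on a relative scale ``R_ij = X_ij / colsum_j`` and a
common pseudo-depth ``lambda`` (the median of column totals) defines the
log expression ``G_ij = ln(lambda * R_ij)``.  Genes expressed in (nearly)
every cell with the lowest variance of ``G`` across cells -- "stable"
genes -- anchor one ordinary least-squares model per cell,

    z_i = a_j G_ij + b_j        (over stable genes i)

where ``z_i`` is the across-cell mean of ``G_ij``.  A strength coefficient
``c`` in [0, 1] interpolates between doing nothing (c = 0) and fully
mapping each cell onto the stable-gene consensus (c = 1):

    a_j <- c (a_j - 1) + 1,   b_j <- c b_j
    B_ij = exp(a_j G_ij + b_j),   Y_ij = ln(B_ij + 1)

Zero counts stay zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = ["LinnormFit", "LinnormNormalizer", "normalize_linnorm"]


@dataclass
class LinnormFit:
    """Estimated per-cell linear models and intermediate quantities."""

    lambda_: float                 # median of column totals
    stable_genes: np.ndarray       # indices of the anchor genes
    a: np.ndarray                  # per-cell slopes (before strength update)
    b: np.ndarray                  # per-cell intercepts (before strength update)
    c: float                       # normalization strength in [0, 1]
    a_updated: np.ndarray
    b_updated: np.ndarray
    R: np.ndarray                  # relative-scale matrix, columns sum to 1
    G: np.ndarray                  # ln(lambda R); -inf at zero counts
    zbar: np.ndarray               # per-stable-gene mean of G across cells


class LinnormNormalizer(BaseNormalizer):
    """Per-cell linear rescaling anchored on low-variance genes."""

    method_name = "linnorm"

    def __init__(
        self,
        c: float = 0.5,
        stable_fraction: float = 0.3,
        min_nonzero_fraction: float = 1.0,
    ):
        self.c = c
        self.stable_fraction = stable_fraction
        self.min_nonzero_fraction = min_nonzero_fraction

    def fit(self, X: CountMatrix, y=None):
        if not 0.0 <= self.c <= 1.0:
            raise DataError("normalization strength c must be in [0, 1]")
        totals = self._column_totals(X, "linnorm")
        lam = float(np.median(totals))
        R = X.counts / totals[None, :]
        with np.errstate(divide="ignore"):
            G = np.log(lam * R)  # -inf where the count is zero

        nonzero_frac = (X.counts > 0).mean(axis=1)
        candidates = np.flatnonzero(nonzero_frac >= self.min_nonzero_fraction)
        if candidates.size == 0:
            raise DataError(
                "no genes pass the stable-gene nonzero-fraction criterion; "
                "lower min_nonzero_fraction"
            )
        g_var = G[candidates].var(axis=1)
        n_keep = max(1, int(np.ceil(self.stable_fraction * candidates.size)))
        order = np.argsort(g_var, kind="stable")
        stable = np.sort(candidates[order[:n_keep]])

        Gs = G[stable]
        zbar = Gs.mean(axis=1)
        # per-cell OLS of zbar on G (slope a_j, intercept b_j)
        gm = Gs.mean(axis=0)
        gc = Gs - gm[None, :]
        denom = (gc**2).sum(axis=0)
        if np.any(denom == 0):
            raise DataError("stable-gene expression is constant within a cell")
        a = (gc * (zbar[:, None] - zbar.mean())).sum(axis=0) / denom
        b = zbar.mean() - a * gm

        self.cell_ids_ = list(X.cell_ids)
        self.fit_ = LinnormFit(
            lambda_=lam,
            stable_genes=stable,
            a=a,
            b=b,
            c=float(self.c),
            a_updated=self.c * (a - 1.0) + 1.0,
            b_updated=b * self.c,
            R=R,
            G=G,
            zbar=zbar,
        )
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        f = self.fit_
        nonzero = X.counts > 0
        B = np.zeros_like(f.G)
        B[nonzero] = np.exp(
            f.a_updated[None, :] * np.where(nonzero, f.G, 0.0) + f.b_updated[None, :]
        )[nonzero]
        values = np.log1p(B)
        return NormalizedMatrix(
            values=values,
            method=self.method_name,
            scale="log",
            gene_ids=list(X.gene_ids),
            cell_ids=list(X.cell_ids),
        )


def normalize_linnorm(
    cm: CountMatrix,
    c: float = 0.5,
    stable_fraction: float = 0.3,
    min_nonzero_fraction: float = 1.0,
) -> tuple[NormalizedMatrix, LinnormFit]:
    """One-shot :class:`LinnormNormalizer`; returns the matrix and the fit."""
    est = LinnormNormalizer(
        c=c,
        stable_fraction=stable_fraction,
        min_nonzero_fraction=min_nonzero_fraction,
    )
    nm = est.fit_transform(cm)
    return nm, est.fit_
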