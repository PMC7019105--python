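"""Deconvolution of per-cell size factors from cell pools.

Cells are arranged on a ring ordered by library size so that sliding
windows (pools) have comparable total depth.  For each pool ``S_k`` the
library-size-adjusted expression ``X_ij / t_j`` is summed within the pool
(``V_ik``) and referenced against the across-all-cells average (``U_i``);
the median over expressed genes of ``R_ik = V_ik / U_i`` is a robust
pool-level size factor that is insensitive to a minority of differentially
expressed genes.  Each pool contributes one linear equation

    sum_{j in S_k} x_j = median_i R_ik,      x_j = theta_j / t_j,

and the stacked system over many pools and pool sizes is solved by least
squares.  Low-weight per-cell rows pulling each ``x_j`` toward the average
pool-level factor make the system full rank without biasing exact data.
Per-cell size factors ``theta_j = x_j t_j`` are rescaled to mean one and
divide the raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = ["ScranPools", "ScranNormalizer", "normalize_scran", "default_pool_sizes"]


@dataclass
class ScranPools:
    """The pooled linear system and its solution."""

    pool_memberships: list[np.ndarray]   # cell indices per pool
    pool_ratio_factor: np.ndarray        # median over genes of R_ik per pool
    design_rows: np.ndarray              # 0/1 pool incidence + augmentation rows
    rhs: np.ndarray
    solution: np.ndarray                 # theta_j / t_j per cell
    t: np.ndarray                        # per-cell library sizes


def default_pool_sizes(n_cells: int) -> tuple[int, ...]:
    """The ladder 21, 26, 31, ... capped at min(101, n_cells)."""
    top = min(101, n_cells)
    sizes = tuple(range(21, top + 1, 5))
    if not sizes:
        sizes = (max(2, n_cells // 2),)
    return sizes


class ScranNormalizer(BaseNormalizer):
    """Pool-and-deconvolve size factor estimation."""

    method_name = "scran"

    def __init__(
        self,
        pool_sizes: tuple[int, ...] | None = None,
        min_cells: int = 20,
        augment_weight: float = 1e-3,
    ):
        self.pool_sizes = pool_sizes
        self.min_cells = min_cells
        self.augment_weight = augment_weight

    def fit(self, X: CountMatrix, y=None):
        n = X.n_cells
        if n < 2:
            raise DataError("scran needs at least 2 cells")
        if n < self.min_cells:
            warnings.warn(
                f"scran: {n} cells is below the recommended minimum of "
                f"{self.min_cells}; size factor estimates may be unstable",
                UserWarning,
                stacklevel=2,
            )
        t = self._column_totals(X, "scran")
        sizes = self.pool_sizes or default_pool_sizes(n)
        sizes = tuple(s for s in sizes if 2 <= s <= n)
        if not sizes:
            raise DataError("no valid pool sizes for this number of cells")

        # ring ordered by library size so pools have comparable depth
        ring = np.argsort(t, kind="stable")
        adj = X.counts / t[None, :]
        u = adj.mean(axis=1)
        expressed = u > 0
        if not np.any(expressed):
            raise DataError("no expressed genes")

        memberships: list[np.ndarray] = []
        ratios: list[float] = []
        rows: list[np.ndarray] = []
        adj_expr = adj[expressed]
        u_expr = u[expressed]
        for size in sizes:
            for start in range(n):
                idx = ring[(np.arange(start, start + size)) % n]
                v = adj_expr[:, idx].sum(axis=1)
                r = float(np.median(v / u_expr))
                row = np.zeros(n)
                row[idx] = 1.0
                memberships.append(idx)
                ratios.append(r)
                rows.append(row)

        design = np.array(rows)
        rhs = np.array(ratios)
        # low-weight per-cell rows anchored at the mean per-cell pool factor
        target = float(np.mean(rhs / np.array([len(m) for m in memberships])))
        w = self.augment_weight
        design = np.vstack([design, w * np.eye(n)])
        rhs = np.concatenate([rhs, np.full(n, w * target)])

        solution, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        if not np.all(np.isfinite(solution)):
            raise DataError("scran linear system is singular even after augmentation")
        factors = solution * t
        if np.any(factors <= 0):
            raise DataError(
                "scran solved non-positive size factors; filter low-quality "
                "cells/genes more strictly and retry"
            )
        factors = factors / factors.mean()

        self.cell_ids_ = list(X.cell_ids)
        self.size_factors_ = factors
        self.pools_ = ScranPools(
            pool_memberships=memberships,
            pool_ratio_factor=np.array(ratios),
            design_rows=design,
            rhs=rhs,
            solution=solution,
            t=t,
        )
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        values = X.counts / self.size_factors_[None, :]
        return NormalizedMatrix(
            values=values,
            method=self.method_name,
            scale="linear",
            gene_ids=list(X.gene_ids),
            cell_ids=list(X.cell_ids),
            size_factors=self.size_factors_,
        )


def normalize_scran(
    cm: CountMatrix,
    pool_sizes: tuple[int, ...] | None = None,
    min_cells: int = 20,
) -> NormalizedMatrix:
    """One-shot :class:`ScranNormalizer`."""
    return ScranNormalizer(pool_sizes=pool_sizes, min_cells=min_cells).fit_transform(cm)
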