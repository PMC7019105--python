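"""Quantile-regression normalization of the count-depth relationship.

The slope of log nonzero expression on log sequencing depth (the
"count-depth relationship") is 1 for a pure depth effect and should be 0
after ideal normalization.  Because genes at different expression levels
can show systematically different count-depth slopes, genes are split into
``K`` groups; within each group a quantile-regression fit of pooled log
expression on log depth defines a per-cell, per-group scale factor:

    per gene:   Q_0.5(X_ij | D_j) = beta_i0 + beta_i1 D_j          (slopes)
    per group:  Q_tau^d(X | D)   = eta_0 + eta_1 D + ... + eta_d D^d
    SF_j = exp(fit_{tau*,d*}(D_j)) / exp(quantile_{tau*}(group X))
    Y_ij = exp(X_ij) / SF_j

where ``(tau*, d*)`` minimize the gap between the slope of the group fit
and the mode of the group's gene-level slopes.  Starting at ``K = 1``, the
normalized data is checked in 10 equal-size expression pools; if any
pool's slope mode exceeds 0.1 in magnitude, ``K`` is incremented and the
procedure repeats.  Zero counts stay zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = [
    "quantile_regression",
    "mode_of_slopes",
    "gene_slopes",
    "check_slope_modes",
    "SCnormFit",
    "SCnormNormalizer",
    "normalize_scnorm",
]

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
DEFAULT_DEGREE_GRID = (1, 2, 3)


_EXACT_MAX_N = 600


def quantile_regression(
    y: np.ndarray,
    x: np.ndarray,
    tau: float,
    degree: int,
    weights: np.ndarray | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Polynomial quantile regression.

    Minimizes ``sum w rho_tau(y - poly(x))`` with the check loss
    ``rho_tau(u) = u * (tau - 1[u < 0])``.  Small problems (and any
    weighted problem) are solved exactly as a linear program, which is
    deterministic for given inputs (degenerate optima resolved by the
    simplex vertex the solver reports, which is reproducible); large
    unweighted problems use iteratively reweighted least squares
    (statsmodels), which agrees with the LP to solver tolerance.

    Returns coefficients ``(c_0, ..., c_degree)`` in increasing order.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DataError("y and x must be matching 1-D arrays")
    if not 0.0 < tau < 1.0:
        raise DataError("tau must be in (0, 1)")
    p = degree + 1
    if y.size < degree + 2:
        raise DataError(f"need at least degree+2={degree + 2} points")
    design = np.vander(x, p, increasing=True)
    if np.linalg.matrix_rank(design) < p:
        raise DataError("collinear design (too few distinct x values)")
    if method == "auto":
        method = "exact" if (y.size <= _EXACT_MAX_N or weights is not None) else "irls"
    if method == "irls" and weights is None:
        import warnings as _warnings
        from statsmodels.regression.quantile_regression import QuantReg
        from statsmodels.tools.sm_exceptions import IterationLimitWarning
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", IterationLimitWarning)
            res = QuantReg(y, design).fit(q=tau, max_iter=5000)
        return np.asarray(res.params)
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    # variables: beta (p, free), u+ (n), u- (n)
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w])
    a_eq = np.hstack([design, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise DataError(f"quantile regression LP failed: {res.message}")
    return res.x[:p]


def mode_of_slopes(slopes: np.ndarray, bandwidth_rule: str = "silverman") -> float:
    """Mode of a set of slopes via Gaussian kernel density estimation.

    The KDE is evaluated on a 512-point grid over the slope range; ties are
    broken toward the smaller value.  A degenerate (all-identical) sample
    returns that value directly.
    """
    s = np.asarray(slopes, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 1:
        raise DataError("no finite slopes")
    lo, hi = float(s.min()), float(s.max())
    if lo == hi:
        return lo
    if s.size < 2:
        return float(s[0])
    if bandwidth_rule == "silverman":
        sd = s.std(ddof=1)
        iqr = np.subtract(*np.percentile(s, [75, 25]))
        sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
        bw = 0.9 * sigma * s.size ** (-0.2)
        if bw <= 0:
            bw = sd * s.size ** (-0.2) or 1e-6
    else:
        raise DataError(f"unknown bandwidth rule {bandwidth_rule!r}")
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - s[None, :]) / bw) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])  # argmax takes the first (smaller) tie


def gene_slopes(
    log_values: np.ndarray,
    nonzero: np.ndarray,
    log_depth: np.ndarray,
    min_nonzero: int = 10,
) -> np.ndarray:
    """Per-gene median-regression slope of log nonzero expression on depth.

    ``log_values`` holds log expression (arbitrary content at zero entries,
    masked by ``nonzero``).  Genes with fewer than ``min_nonzero`` nonzero
    cells, or without enough distinct depths, get ``nan``.
    """
    n_genes = log_values.shape[0]
    slopes = np.full(n_genes, np.nan)
    for i in range(n_genes):
        mask = nonzero[i]
        if mask.sum() < min_nonzero:
            continue
        x = log_depth[mask]
        if np.unique(x).size < 2:
            continue
        try:
            coef = quantile_regression(log_values[i, mask], x, 0.5, 1)
        except DataError:
            continue
        slopes[i] = coef[1]
    return slopes


def check_slope_modes(
    log_values: np.ndarray,
    nonzero: np.ndarray,
    log_depth: np.ndarray,
    n_pools: int = 10,
    min_nonzero: int = 10,
    slopes: np.ndarray | None = None,
) -> np.ndarray:
    """Slope modes within equal-size expression pools of genes.

    Genes with a defined count-depth slope are ranked by their median log
    nonzero expression and split into ``n_pools`` contiguous pools; the
    KDE mode of the slopes in each pool is returned.
    """
    if slopes is None:
        slopes = gene_slopes(log_values, nonzero, log_depth, min_nonzero)
    valid = np.flatnonzero(np.isfinite(slopes))
    if valid.size == 0:
        raise DataError("no genes with a defined count-depth slope")
    med_expr = np.array(
        [np.median(log_values[i, nonzero[i]]) for i in valid]
    )
    order = valid[np.argsort(med_expr, kind="stable")]
    n_pools = min(n_pools, order.size)
    modes = np.empty(n_pools)
    for p, chunk in enumerate(np.array_split(order, n_pools)):
        modes[p] = mode_of_slopes(slopes[chunk])
    return modes


@dataclass
class SCnormFit:
    """Fitted group structure and per-group scale factor models."""

    K: int
    group_assignment: np.ndarray          # group index per gene (-1 = all-zero gene)
    gene_slope: np.ndarray                # nan where undefined
    tau_star: list[float] = field(default_factory=list)
    d_star: list[int] = field(default_factory=list)
    eta: list[np.ndarray] = field(default_factory=list)
    size_factor: np.ndarray | None = None  # n_groups x n_cells
    check_modes: np.ndarray | None = None
    passthrough_genes: np.ndarray | None = None  # genes excluded from fitting
    converged: bool = True


class SCnormNormalizer(BaseNormalizer):
    """Group-wise quantile-regression scale factors."""

    method_name = "scnorm"

    def __init__(
        self,
        n_check_pools: int = 10,
        slope_mode_threshold: float = 0.1,
        quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
        degree_grid: tuple[int, ...] = DEFAULT_DEGREE_GRID,
        min_nonzero: int = 10,
        K_min: int = 1,
        K_max: int = 10,
        pooled_point_cap: int = 600,
        depths: np.ndarray | None = None,
    ):
        self.n_check_pools = n_check_pools
        self.slope_mode_threshold = slope_mode_threshold
        self.quantile_grid = quantile_grid
        self.degree_grid = degree_grid
        self.min_nonzero = min_nonzero
        self.K_min = K_min
        self.K_max = K_max
        self.pooled_point_cap = pooled_point_cap
        self.depths = depths

    # -- internal pieces -------------------------------------------------

    @staticmethod
    def _downsample(x: np.ndarray, y: np.ndarray, cap: int) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic even-spaced thinning of a pooled point cloud."""
        if x.size <= cap:
            return x, y
        order = np.lexsort((y, x))
        pick = order[np.linspace(0, x.size - 1, cap).round().astype(int)]
        return x[pick], y[pick]

    def _fit_group(
        self,
        genes: np.ndarray,
        log_x: np.ndarray,
        nonzero: np.ndarray,
        log_depth: np.ndarray,
        slopes: np.ndarray,
    ) -> tuple[float, int, np.ndarray, np.ndarray]:
        """Search (tau, degree) for one gene group; return the winner and SF."""
        mask = nonzero[genes]
        px = np.broadcast_to(log_depth, mask.shape)[mask]
        py = log_x[genes][mask]
        px, py = self._downsample(px, py, self.pooled_point_cap)
        target = mode_of_slopes(slopes[genes][np.isfinite(slopes[genes])])

        # the count-depth line through the fitted curve only depends on the
        # distinct depths, so fit it on unique x with multiplicity weights
        ux, uw = np.unique(px, return_counts=True)
        best = None
        for d in self.degree_grid:
            for tau in self.quantile_grid:
                try:
                    eta = quantile_regression(py, px, float(tau), d)
                except DataError:
                    continue
                pred = np.polyval(eta[::-1], ux)
                try:
                    line = quantile_regression(pred, ux, 0.5, 1, weights=uw.astype(float))
                except DataError:
                    continue
                gap = abs(line[1] - target)
                if best is None or gap < best[0] - 1e-15:
                    best = (gap, float(tau), d, eta)
        if best is None:
            raise DataError("no admissible (tau, degree) fit for a gene group")
        _, tau_s, d_s, eta = best
        fitted = np.polyval(eta[::-1], log_depth)
        sf = np.exp(fitted) / np.exp(np.quantile(py, tau_s))
        return tau_s, d_s, eta, sf

    # -- estimator API ---------------------------------------------------

    def fit(self, X: CountMatrix, y=None):
        counts = X.counts
        n_genes, n_cells = counts.shape
        if self.depths is not None:
            # sequencing depth is a property of the experiment; callers can
            # supply it when the matrix itself no longer carries it (e.g.
            # when checking an already-normalized matrix)
            depth = np.asarray(self.depths, dtype=float)
            if depth.shape != (n_cells,) or np.any(depth <= 0):
                raise DataError("depths must be positive, one per cell")
        else:
            depth = self._column_totals(X, "scnorm")
        log_depth = np.log(depth)
        nonzero = counts > 0
        log_x = np.zeros(counts.shape)
        log_x[nonzero] = np.log(counts[nonzero].astype(float))

        if np.ptp(log_depth) < 1e-8:
            # equal sequencing depths: there is no count-depth relationship
            # to remove, so the data is already normalized (K = 1, SF = 1)
            self.cell_ids_ = list(X.cell_ids)
            self._values = counts.astype(float)
            self.fit_ = SCnormFit(
                K=1,
                group_assignment=np.zeros(n_genes, dtype=int),
                gene_slope=np.full(n_genes, np.nan),
                size_factor=np.ones((1, n_cells)),
                check_modes=np.zeros(1),
                passthrough_genes=np.arange(n_genes),
                converged=True,
            )
            return self

        slopes = gene_slopes(log_x, nonzero, log_depth, self.min_nonzero)
        fitted_genes = np.flatnonzero(np.isfinite(slopes))
        if fitted_genes.size == 0:
            raise DataError("no genes usable for scnorm fitting; lower min_nonzero")
        passthrough = np.flatnonzero(~np.isfinite(slopes))
        med_expr = np.full(n_genes, np.nan)
        for i in range(n_genes):
            if nonzero[i].any():
                med_expr[i] = np.median(log_x[i, nonzero[i]])

        fit = None
        for K in range(self.K_min, self.K_max + 1):
            if fitted_genes.size < K:
                raise DataError(f"fewer usable genes ({fitted_genes.size}) than K={K} groups")
            order = fitted_genes[np.argsort(slopes[fitted_genes], kind="stable")]
            groups = np.array_split(order, K)
            assignment = np.full(n_genes, -1, dtype=int)
            group_med = np.empty(K)
            tau_star, d_star, etas = [], [], []
            sf = np.empty((K, n_cells))
            for g, members in enumerate(groups):
                assignment[members] = g
                group_med[g] = np.median(med_expr[members])
                t, d, eta, factors = self._fit_group(
                    members, log_x, nonzero, log_depth, slopes
                )
                tau_star.append(t)
                d_star.append(d)
                etas.append(eta)
                sf[g] = factors
            # excluded genes ride along with the expression-nearest group
            for i in passthrough:
                if np.isnan(med_expr[i]):
                    assignment[i] = 0
                else:
                    assignment[i] = int(np.argmin(np.abs(group_med - med_expr[i])))

            values = np.zeros_like(counts, dtype=float)
            values[nonzero] = (counts / sf[assignment, :])[nonzero]

            log_norm = np.zeros_like(values)
            log_norm[nonzero] = np.log(values[nonzero])
            modes = check_slope_modes(
                log_norm, nonzero, log_depth,
                n_pools=self.n_check_pools, min_nonzero=self.min_nonzero,
            )
            fit = SCnormFit(
                K=K,
                group_assignment=assignment,
                gene_slope=slopes,
                tau_star=tau_star,
                d_star=d_star,
                eta=etas,
                size_factor=sf,
                check_modes=modes,
                passthrough_genes=passthrough,
                converged=bool(np.all(np.abs(modes) <= self.slope_mode_threshold)),
            )
            self._values = values
            if fit.converged:
                break
        if fit is not None and not fit.converged:
            warnings.warn(
                f"scnorm: check modes still exceed {self.slope_mode_threshold} at "
                f"K_max={self.K_max}; returning the K_max fit",
                UserWarning,
                stacklevel=2,
            )
        self.cell_ids_ = list(X.cell_ids)
        self.fit_ = fit
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        return NormalizedMatrix(
            values=self._values,
            method=self.method_name,
            scale="linear",
            gene_ids=list(X.gene_ids),
            cell_ids=list(X.cell_ids),
            extra={
                "K": self.fit_.K,
                "converged": self.fit_.converged,
                "passthrough_genes": self.fit_.passthrough_genes.tolist(),
            },
        )


def normalize_scnorm(
    cm: CountMatrix,
    n_check_pools: int = 10,
    slope_mode_threshold: float = 0.1,
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
    degree_grid: tuple[int, ...] = DEFAULT_DEGREE_GRID,
    min_nonzero: int = 10,
    K_max: int = 10,
    depths: np.ndarray | None = None,
) -> tuple[NormalizedMatrix, SCnormFit]:
    """One-shot :class:`SCnormNormalizer`; returns the matrix and the fit."""
    est = SCnormNormalizer(
        n_check_pools=n_check_pools,
        slope_mode_threshold=slope_mode_threshold,
        quantile_grid=quantile_grid,
        degree_grid=degree_grid,
        min_nonzero=min_nonzero,
        K_max=K_max,
        depths=depths,
    )
    nm = est.fit_transform(cm)
    return nm, est.fit_
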