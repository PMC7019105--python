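"""Per-cell gamma-regression calibration against spike-in concentrations.

For each cell independently, the natural log of the known spike-in
concentrations ``C`` is modeled as Gamma-distributed with polynomial mean

    C ~ Gamma(mean = mu(X) = sum_d beta_d X^d, shape = phi),

where ``X = ln(FPKM)`` of the spike-in in that cell.  Candidate polynomial
degrees 1..4 are fitted by maximum likelihood and the degree with the
smallest mean squared spike-in residual (the cell's technical noise) is
selected.  Every biological gene is then mapped through the fitted
polynomial: its normalized value is the expected log concentration
``mu_hat(ln FPKM)``.  The method is local -- each cell's output depends on
that cell's counts only -- so it denoises rather than rescales across
cells.

The Gamma response must be positive, so spike-ins whose log concentration
is <= 0 (concentration <= 1) are excluded from the calibration fit, as are
spike-ins with zero FPKM.  Genes with a zero count keep a normalized value
of 0 and are flagged in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma

from ..data import CountMatrix, DataError, NormalizedMatrix, SpikeInReference, compute_fpkm
from .base import BaseNormalizer

__all__ = ["GRMFit", "fit_grm_cell", "GRMNormalizer", "normalize_grm"]

_MAX_SHAPE = 1e12


@dataclass
class GRMFit:
    """A fitted per-cell gamma regression."""

    degree: int             # selected polynomial degree
    beta: np.ndarray        # coefficients beta_0..beta_degree
    shape: float            # gamma shape (phi)
    cell_id: str | None     # which cell the fit belongs to
    fit_score: float        # mean squared spike-in residual of the winner
    candidates: dict | None = None  # degree -> (beta, shape, score)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.polyval(self.beta[::-1], x)


def _gamma_irls(y: np.ndarray, design: np.ndarray, max_iter: int = 200, tol: float = 1e-12):
    """MLE of the mean polynomial for a Gamma response with identity link.

    The score equation for the mean coefficients does not involve the shape,
    so beta is fitted by iteratively reweighted least squares with weights
    ``1/mu^2``; the shape is then the profile MLE given the fitted means.
    Returns ``(beta, shape)`` or raises ``DataError`` when the fitted mean
    goes non-positive (the candidate degree is then rejected).
    """
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    mu = design @ beta
    if np.any(mu <= 0):
        raise DataError("non-positive fitted mean")
    for _ in range(max_iter):
        w = 1.0 / mu**2
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd, wd.T @ y)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"singular design in gamma regression: {exc}") from exc
        mu_new = design @ beta_new
        if np.any(mu_new <= 0):
            raise DataError("non-positive fitted mean")
        step = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
        beta, mu = beta_new, mu_new
        if step < tol:
            break
    # profile MLE for the shape: log k - digamma(k) = s
    ratio = y / mu
    s = float(np.mean(ratio - np.log(ratio) - 1.0))
    if s <= 1e-12:
        shape = _MAX_SHAPE  # (near-)noiseless fit
    else:
        # solve in log space for conditioning; log k - digamma(k) is
        # monotone decreasing from +inf to 0
        g = lambda t: np.log(np.exp(t)) - digamma(np.exp(t)) - s
        lo, hi = -18.0, 27.0
        if g(lo) * g(hi) < 0:
            shape = float(np.exp(brentq(g, lo, hi, maxiter=200)))
        else:
            shape = _MAX_SHAPE if g(lo) < 0 else float(np.exp(lo))
    return beta, shape


def fit_grm_cell(
    log_fpkm_spike: np.ndarray,
    log_conc: np.ndarray,
    degrees: tuple[int, ...] = (1, 2, 3, 4),
    cell_id: str | None = None,
) -> GRMFit:
    """Fit the gamma calibration for one cell and select the degree.

    ``log_fpkm_spike`` / ``log_conc`` are the spike-ins usable in this cell
    (positive FPKM, positive log concentration).  Each candidate degree with
    enough points (``degree + 2``) is fitted by Gamma MLE; the degree with
    minimal mean squared residual wins.
    """
    x = np.asarray(log_fpkm_spike, dtype=float)
    y = np.asarray(log_conc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("log_fpkm_spike and log_conc must be matching vectors")
    if np.any(y <= 0):
        raise DataError("log concentrations must be positive for the gamma response")
    usable = [d for d in degrees if x.size >= d + 2]
    if not usable:
        raise DataError(
            f"only {x.size} usable spike-ins; need at least min(degrees)+2"
        )
    candidates: dict[int, tuple[np.ndarray, float, float]] = {}
    for d in usable:
        design = np.vander(x, d + 1, increasing=True)
        try:
            beta, shape = _gamma_irls(y, design)
        except DataError:
            continue
        resid = y - design @ beta
        candidates[d] = (beta, shape, float(np.mean(resid**2)))
    if not candidates:
        raise DataError("every candidate degree was rejected (non-positive fitted means)")
    # smallest degree within numerical tolerance of the best score wins,
    # so noiseless data selects the simplest interpolating polynomial
    best_score = min(sc for _, _, sc in candidates.values())
    tol = best_score * 1e-9 + 1e-12
    best = min(d for d, (_, _, sc) in candidates.items() if sc <= best_score + tol)
    beta, shape, score = candidates[best]
    return GRMFit(
        degree=best,
        beta=beta,
        shape=shape,
        cell_id=cell_id,
        fit_score=score,
        candidates={d: {"beta": b, "shape": s, "score": sc} for d, (b, s, sc) in candidates.items()},
    )


class GRMNormalizer(BaseNormalizer):
    """Cell-by-cell spike-in calibration to expected log concentration."""

    method_name = "grm"

    def __init__(self, ref: SpikeInReference = None, degrees: tuple[int, ...] = (1, 2, 3, 4)):
        self.ref = ref
        self.degrees = degrees

    def fit(self, X: CountMatrix, y=None):
        if self.ref is None:
            raise DataError("grm requires a spike-in concentration reference")
        if not np.any(X.is_spikein):
            raise DataError("grm requires spike-in rows in the count matrix")
        fpkm = compute_fpkm(X)
        spike_rows = np.flatnonzero(X.is_spikein)
        spike_ids = [X.gene_ids[i] for i in spike_rows]
        conc = self.ref.lookup(spike_ids)
        log_conc_all = np.log(conc)

        fits = []
        for j, cell in enumerate(X.cell_ids):
            f_spike = fpkm[spike_rows, j]
            ok = (f_spike > 0) & (log_conc_all > 0)
            if not np.any(f_spike > 0):
                raise DataError(f"grm: all spike-ins are zero in cell {cell!r}")
            fits.append(
                fit_grm_cell(
                    np.log(f_spike[ok]), log_conc_all[ok],
                    degrees=self.degrees, cell_id=cell,
                )
            )
        self.cell_ids_ = list(X.cell_ids)
        self.fits_ = fits
        self._fpkm = fpkm
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        bio_rows = np.flatnonzero(~X.is_spikein)
        values = np.zeros((bio_rows.size, X.n_cells))
        zero_flags = np.zeros_like(values, dtype=bool)
        for j, fit in enumerate(self.fits_):
            col = self._fpkm[bio_rows, j]
            nz = col > 0
            values[nz, j] = fit.predict(np.log(col[nz]))
            zero_flags[~nz, j] = True
        return NormalizedMatrix(
            values=values,
            method=self.method_name,
            scale="log",
            gene_ids=[X.gene_ids[i] for i in bio_rows],
            cell_ids=list(X.cell_ids),
            kept_gene_index=bio_rows,
            extra={"zero_count_flag": zero_flags},
        )


def normalize_grm(
    cm: CountMatrix,
    ref: SpikeInReference,
    degrees: tuple[int, ...] = (1, 2, 3, 4),
) -> NormalizedMatrix:
    """One-shot :class:`GRMNormalizer`."""
    return GRMNormalizer(ref=ref, degrees=degrees).fit_transform(cm)
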