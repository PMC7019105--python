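"""Hierarchical Poisson-Gamma model for counts with spike-ins (MCMC).

The model separates technical from biological variation by borrowing the
known behaviour of spike-in transcripts, which enter every cell in equal
amounts and therefore respond only to capture efficiency:

    X_ij ~ Poisson(phi_j nu_j mu_i rho_ij)   biological genes
    X_ij ~ Poisson(nu_j mu_i)                spike-in genes
    nu_j | s_j, theta ~ Gamma(1/theta, rate 1/(s_j theta))   (mean s_j)
    rho_ij | delta_i ~ Gamma(1/delta_i, 1/delta_i)           (mean 1)

``phi_j`` is the cell's size factor (identified by the constraint
``sum_j phi_j = n``), ``s_j`` the capture-efficiency constant, ``theta``
the strength of technical noise shared by all cells, and ``delta_i`` the
biological over-dispersion of gene ``i``.  The gene-level random effect
``rho_ij`` is marginalized analytically (Poisson-Gamma = negative binomial
with size ``1/delta_i`` and mean ``phi_j nu_j mu_i``), so the sampler works
on ``(mu, delta, phi, s, theta, nu)`` with Metropolis-within-Gibbs random
walks on log scale and adaptive step sizes during burn-in.

Priors: log-normal(0, 2^2) on ``mu_i`` and ``delta_i``, Gamma(1, 1) on
``s`` and ``theta``, flat on ``log phi`` within the sum constraint.  The
spike-in rates ``mu_i`` are fixed inputs (their known input amounts); when
not supplied they default to the empirical spike-in row means, which
anchors the ``nu_j`` scale near one.

Because spike-ins are added to every cell in the same volume, the capture
efficiency constant ``s`` is shared across cells: a free per-cell ``s_j``
under a vague prior would track its own ``nu_j`` exactly and collapse
``theta`` to zero (a Neyman-Scott-type degeneracy), leaving the technical
noise unidentified.  Cell-to-cell capture differences are carried by
``nu_j`` and quantified by ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ..data import CountMatrix, DataError, NormalizedMatrix
from .base import BaseNormalizer

__all__ = [
    "BASiCSFit",
    "fit_basics",
    "normalize_basics",
    "simulate_basics_model",
    "BASiCSNormalizer",
]

_DELTA_FLOOR = 1e-6
_THETA_FLOOR = 1e-6


@dataclass
class BASiCSFit:
    """Posterior medians and retained draws from the sampler."""

    mu: np.ndarray            # biological gene rates
    delta: np.ndarray         # biological over-dispersions
    phi: np.ndarray           # cell size factors, sum = n_cells
    s: np.ndarray             # capture-efficiency constant (shared, broadcast per cell)
    theta: float              # technical noise
    nu: np.ndarray            # capture random effects
    spikein_mu: np.ndarray    # fixed spike-in rates used
    chains: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    bio_rows: np.ndarray | None = None
    spike_rows: np.ndarray | None = None
    cell_ids: list[str] | None = None


def _nb_terms(x: np.ndarray, r: np.ndarray, m: np.ndarray) -> np.ndarray:
    """NB log-pmf without the gammaln(x+1) data constant."""
    return (
        gammaln(x + r) - gammaln(r)
        + r * np.log(r / (r + m))
        + x * np.log(m / (r + m))
    )


def _nb_mean_ratio(x: np.ndarray, r: np.ndarray, m_new: np.ndarray, m_old: np.ndarray) -> np.ndarray:
    """Log-likelihood change when only the NB mean moves (gammaln terms cancel)."""
    return r * (np.log(r + m_old) - np.log(r + m_new)) + x * (
        np.log(m_new) - np.log(m_old) + np.log(r + m_old) - np.log(r + m_new)
    )


def fit_basics(
    cm: CountMatrix,
    n_iter: int = 20000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 1,
    spikein_mu: np.ndarray | None = None,
) -> BASiCSFit:
    """Run the Metropolis-within-Gibbs sampler on a cleaned count matrix.

    Requires both spike-in and biological rows.  Returns posterior medians
    of the retained (post burn-in, thinned) draws plus the chains and
    acceptance diagnostics.
    """
    if not np.any(cm.is_spikein):
        raise DataError("the model requires spike-in rows")
    if not np.any(~cm.is_spikein):
        raise DataError("the model requires biological rows")
    if burn_in >= n_iter:
        raise DataError("burn_in must be smaller than n_iter")

    bio_rows = np.flatnonzero(~cm.is_spikein)
    spike_rows = np.flatnonzero(cm.is_spikein)
    B = cm.counts[bio_rows].astype(float)      # n_b x n
    S = cm.counts[spike_rows].astype(float)    # n_s x n
    n_b, n = B.shape

    if spikein_mu is None:
        mu_s = S.mean(axis=1)
    else:
        mu_s = np.asarray(spikein_mu, dtype=float)
        if mu_s.shape != (len(spike_rows),):
            raise DataError("spikein_mu must have one entry per spike-in row")
    if np.any(mu_s <= 0):
        raise DataError("spike-in rates must be positive (empty spike-in row?)")

    rng = np.random.default_rng(seed)

    # -- initialization --------------------------------------------------
    spike_tot = S.sum(axis=0)
    nu = np.maximum(spike_tot / mu_s.sum(), 1e-6)
    s = float(np.mean(nu))
    theta = 0.2
    bio_tot = B.sum(axis=0)
    phi = np.maximum(bio_tot / nu, 1e-6)
    phi *= n / phi.sum()
    mu_b = np.maximum((B / (phi * nu)[None, :]).mean(axis=1), 1e-8)
    adj = B / (phi * nu)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d0 = (adj.var(axis=1, ddof=1) - mu_b) / mu_b**2
    delta = np.clip(np.nan_to_num(d0, nan=0.3), 0.05, 5.0)

    def log_post_check():
        m = mu_b[:, None] * (phi * nu)[None, :]
        lp = _nb_terms(B, (1.0 / delta)[:, None], m).sum()
        lp += (S * np.log(mu_s[:, None] * nu[None, :]) - mu_s[:, None] * nu[None, :]).sum()
        return lp

    if not np.isfinite(log_post_check()):
        raise DataError("non-finite log-posterior at initialization; clean the data")

    # -- proposal scales & adaptation -----------------------------------
    sd_mu = np.full(n_b, 0.1)
    sd_delta = np.full(n_b, 0.3)
    sd_phi = np.full(n, 0.1)
    sd_nu = np.full(n, 0.1)
    sd_s = 0.2
    sd_theta = 0.3
    acc = {k: np.zeros_like(v) for k, v in
           [("mu", sd_mu), ("delta", sd_delta), ("phi", sd_phi), ("nu", sd_nu)]}
    acc_s = 0.0
    acc_theta = 0.0
    batch = 50

    keep_iters = range(burn_in, n_iter, thin)
    n_keep = len(keep_iters)
    chains = {
        "mu": np.empty((n_keep, n_b)),
        "delta": np.empty((n_keep, n_b)),
        "phi": np.empty((n_keep, n)),
        "s": np.empty(n_keep),
        "nu": np.empty((n_keep, n)),
        "theta": np.empty(n_keep),
    }
    keep_i = 0

    r = 1.0 / delta
    gl_r = gammaln(B + r[:, None]) - gammaln(r)[:, None]  # cached gene-row terms

    for it in range(n_iter):
        cell_scale = phi * nu  # bio mean scale per cell

        # --- mu (per biological gene) ---------------------------------
        prop = mu_b * np.exp(sd_mu * rng.standard_normal(n_b))
        m_old = mu_b[:, None] * cell_scale[None, :]
        m_new = prop[:, None] * cell_scale[None, :]
        d_lik = _nb_mean_ratio(B, r[:, None], m_new, m_old).sum(axis=1)
        d_pri = (np.log(mu_b) ** 2 - np.log(prop) ** 2) / 8.0
        accept = np.log(rng.random(n_b)) < d_lik + d_pri
        mu_b = np.where(accept, prop, mu_b)
        acc["mu"] += accept

        # --- delta (per biological gene) -------------------------------
        prop = np.maximum(delta * np.exp(sd_delta * rng.standard_normal(n_b)), _DELTA_FLOOR)
        r_new = 1.0 / prop
        m = mu_b[:, None] * cell_scale[None, :]
        gl_new = gammaln(B + r_new[:, None]) - gammaln(r_new)[:, None]
        term_new = gl_new + r_new[:, None] * np.log(r_new[:, None] / (r_new[:, None] + m)) \
            + B * np.log(m / (r_new[:, None] + m))
        term_old = gl_r + r[:, None] * np.log(r[:, None] / (r[:, None] + m)) \
            + B * np.log(m / (r[:, None] + m))
        d_lik = (term_new - term_old).sum(axis=1)
        d_pri = (np.log(delta) ** 2 - np.log(prop) ** 2) / 8.0
        accept = np.log(rng.random(n_b)) < d_lik + d_pri
        delta = np.where(accept, prop, delta)
        r = 1.0 / delta
        gl_r = np.where(accept[:, None], gl_new, gl_r)
        acc["delta"] += accept

        # --- phi (per cell; flat prior on log phi) ---------------------
        prop = phi * np.exp(sd_phi * rng.standard_normal(n))
        m_old = mu_b[:, None] * (phi * nu)[None, :]
        m_new = mu_b[:, None] * (prop * nu)[None, :]
        d_lik = _nb_mean_ratio(B, r[:, None], m_new, m_old).sum(axis=0)
        accept = np.log(rng.random(n)) < d_lik
        phi = np.where(accept, prop, phi)
        acc["phi"] += accept
        # project onto the identifiability constraint along the flat
        # direction (phi * c, mu / c leaves the likelihood unchanged)
        c = n / phi.sum()
        phi = phi * c
        mu_b = mu_b / c

        # --- nu (per cell) ---------------------------------------------
        prop = nu * np.exp(sd_nu * rng.standard_normal(n))
        m_old = mu_b[:, None] * (phi * nu)[None, :]
        m_new = mu_b[:, None] * (phi * prop)[None, :]
        d_bio = _nb_mean_ratio(B, r[:, None], m_new, m_old).sum(axis=0)
        d_spk = (S * (np.log(prop) - np.log(nu))[None, :] - mu_s[:, None] * (prop - nu)[None, :]).sum(axis=0)
        # Gamma(1/theta, rate 1/(s theta)) prior + log-scale Jacobian
        d_pri = (1.0 / theta) * (np.log(prop) - np.log(nu)) - (prop - nu) / (s * theta)
        accept = np.log(rng.random(n)) < d_bio + d_spk + d_pri
        nu = np.where(accept, prop, nu)
        acc["nu"] += accept

        # --- s (shared capture-efficiency constant) ---------------------
        prop_s = s * float(np.exp(sd_s * rng.standard_normal()))
        d_tgt = (
            -(n / theta) * (np.log(prop_s) - np.log(s))
            - (nu.sum() / theta) * (1.0 / prop_s - 1.0 / s)
            - (prop_s - s)                     # Gamma(1,1) prior
            + (np.log(prop_s) - np.log(s))     # Jacobian
        )
        if np.log(rng.random()) < d_tgt:
            s = prop_s
            acc_s += 1

        # --- theta (scalar) ---------------------------------------------
        prop_t = max(theta * np.exp(sd_theta * rng.standard_normal()), _THETA_FLOOR)

        def nu_prior_sum(th):
            sh = 1.0 / th
            return float(
                n * (-gammaln(sh)) - n * sh * np.log(s * th)
                + (sh - 1.0) * np.log(nu).sum() - nu.sum() / (s * th)
            )

        d_tgt = nu_prior_sum(prop_t) - nu_prior_sum(theta) - (prop_t - theta) \
            + (np.log(prop_t) - np.log(theta))
        if np.log(rng.random()) < d_tgt:
            theta = prop_t
            acc_theta += 1

        # --- adaptation during burn-in ----------------------------------
        if it < burn_in and (it + 1) % batch == 0:
            for key, sd in [("mu", sd_mu), ("delta", sd_delta), ("phi", sd_phi),
                            ("nu", sd_nu)]:
                rate = acc[key] / batch
                np.multiply(sd, np.exp(np.clip(rate - 0.44, -0.3, 0.3)), out=sd)
                np.clip(sd, 1e-3, 5.0, out=sd)
                acc[key][:] = 0
            sd_s = float(np.clip(sd_s * np.exp(np.clip(acc_s / batch - 0.44, -0.3, 0.3)), 1e-3, 5.0))
            acc_s = 0.0
            sd_theta = float(np.clip(sd_theta * np.exp(np.clip(acc_theta / batch - 0.44, -0.3, 0.3)), 1e-3, 5.0))
            acc_theta = 0.0

        if it in keep_iters:
            chains["mu"][keep_i] = mu_b
            chains["delta"][keep_i] = delta
            chains["phi"][keep_i] = phi
            chains["s"][keep_i] = s
            chains["nu"][keep_i] = nu
            chains["theta"][keep_i] = theta
            keep_i += 1

    post_iters = n_iter - burn_in
    diagnostics = {
        "acceptance": {k: float(np.mean(v) / post_iters) for k, v in acc.items()},
        "acceptance_s": acc_s / post_iters,
        "acceptance_theta": acc_theta / post_iters,
        "n_kept": n_keep,
    }
    return BASiCSFit(
        mu=np.median(chains["mu"], axis=0),
        delta=np.median(chains["delta"], axis=0),
        phi=np.median(chains["phi"], axis=0),
        s=np.full(n, float(np.median(chains["s"]))),
        theta=float(np.median(chains["theta"])),
        nu=np.median(chains["nu"], axis=0),
        spikein_mu=mu_s,
        chains=chains,
        diagnostics=diagnostics,
        bio_rows=bio_rows,
        spike_rows=spike_rows,
        cell_ids=list(cm.cell_ids),
    )


def normalize_basics(fit: BASiCSFit, cm: CountMatrix) -> NormalizedMatrix:
    """Divide out the estimated cell-specific terms.

    Biological genes: ``Y_ij = X_ij / (phi_j nu_j)``; spike-ins:
    ``Y_ij = X_ij / nu_j`` (spike-ins carry no cell-size effect).
    """
    if fit.cell_ids is not None and list(fit.cell_ids) != list(cm.cell_ids):
        raise DataError("fit and matrix have different cells")
    factors_bio = fit.phi * fit.nu
    if np.any(factors_bio <= 0) or np.any(fit.nu <= 0):
        raise DataError("non-positive estimated factors")
    values = cm.counts.astype(float).copy()
    values[~cm.is_spikein] /= factors_bio[None, :]
    values[cm.is_spikein] /= fit.nu[None, :]
    return NormalizedMatrix(
        values=values,
        method="basics",
        scale="linear",
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        size_factors=factors_bio,
        extra={"theta": fit.theta},
    )


def simulate_basics_model(
    n_bio: int = 192,
    n_spike: int = 8,
    n_cells: int = 40,
    theta: float = 0.3,
    seed: int = 0,
    mu_log_mean: float = 2.0,
    mu_log_sd: float = 1.0,
    delta_log_mean: float = float(np.log(0.3)),
    delta_log_sd: float = 0.5,
    s_true: float = 1.0,
    phi_log_sd: float = 0.4,
) -> tuple[CountMatrix, dict]:
    """Draw a data set from the model itself (for parameter recovery)."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mu_log_mean, mu_log_sd, n_bio)
    delta = rng.lognormal(delta_log_mean, delta_log_sd, n_bio)
    s = float(s_true)
    phi = rng.lognormal(0.0, phi_log_sd, n_cells)
    phi *= n_cells / phi.sum()
    if theta > 0:
        nu = rng.gamma(1.0 / theta, scale=s * theta, size=n_cells)
    else:
        nu = np.full(n_cells, s)
    mu_spike = np.geomspace(5.0, 5000.0, n_spike)

    m_bio = mu[:, None] * (phi * nu)[None, :]
    # rho is i.i.d. per entry (mean-one Gamma noise per gene-cell pair)
    rho = rng.gamma(np.broadcast_to((1.0 / delta)[:, None], m_bio.shape),
                    scale=np.broadcast_to(delta[:, None], m_bio.shape))
    bio = rng.poisson(m_bio * rho)
    spike = rng.poisson(mu_spike[:, None] * nu[None, :])

    counts = np.vstack([bio, spike])
    gene_ids = [f"gene{i:04d}" for i in range(n_bio)] + [
        f"ERCC-{i + 1:05d}" for i in range(n_spike)
    ]
    is_spikein = np.r_[np.zeros(n_bio, bool), np.ones(n_spike, bool)]
    cm = CountMatrix(counts, gene_ids, [f"cell{j:03d}" for j in range(n_cells)], is_spikein)
    truth = {
        "mu": mu, "delta": delta, "phi": phi, "s": s, "nu": nu,
        "theta": theta, "mu_spike": mu_spike,
    }
    return cm, truth


class BASiCSNormalizer(BaseNormalizer):
    """Estimator wrapper around :func:`fit_basics` / :func:`normalize_basics`."""

    method_name = "basics"

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 10000,
        thin: int = 10,
        seed: int = 1,
        spikein_mu: np.ndarray | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.spikein_mu = spikein_mu

    def fit(self, X: CountMatrix, y=None):
        self.fit_ = fit_basics(
            X,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            spikein_mu=self.spikein_mu,
        )
        self.cell_ids_ = list(X.cell_ids)
        self.size_factors_ = self.fit_.phi * self.fit_.nu
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        self._check_fitted_cells(X)
        return normalize_basics(self.fit_, X)
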