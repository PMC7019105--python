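"""Synthetic scRNA-seq count generator with full ground-truth tracking.

The generator emulates a two-group single-cell experiment: negative-binomial
counts with gene-specific overdispersion, cell-specific global scaling
factors, a minority of fold-changed (differentially expressed) genes in one
subgroup, and a small panel of spike-in rows whose expected counts follow
known concentrations through a per-cell capture random effect.

Parameterization: a count with mean ``m`` and overdispersion ``phi`` has
variance ``m + phi * m**2`` (``phi = 0`` recovers the Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountMatrix, DataError, SpikeInReference

__all__ = [
    "SimulationTruth",
    "SpikeInSim",
    "estimate_template_params",
    "simulate_counts",
    "simulate_spikeins",
    "attach_labels",
    "default_spikein_reference",
    "simulate_dataset",
]

GROUP_LABELS = ("group1", "group2")


@dataclass
class SimulationTruth:
    """Ground truth for a simulated data set."""

    gene_mean: np.ndarray          # mu_i, biological genes
    gene_dispersion: np.ndarray    # phi_i, variance = m + phi m^2
    cell_factor: np.ndarray        # s_j, global per-cell scaling
    de_flags: np.ndarray           # True where the gene is fold-changed
    fold_change: float             # applied to de genes in group 2
    group_label: np.ndarray        # per-cell group name
    capture_efficiency: np.ndarray | None = None  # spike-in branch s_j
    spike_mu: np.ndarray | None = None            # expected spike-in counts at nu=1
    spike_nu: np.ndarray | None = None            # realized capture random effects
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_mean = np.asarray(self.gene_mean, dtype=float)
        self.gene_dispersion = np.asarray(self.gene_dispersion, dtype=float)
        self.cell_factor = np.asarray(self.cell_factor, dtype=float)
        self.de_flags = np.asarray(self.de_flags, dtype=bool)
        self.group_label = np.asarray(self.group_label, dtype=object)
        if self.de_flags.shape != self.gene_mean.shape:
            raise DataError("de_flags must have one entry per gene")
        if self.fold_change < 1:
            raise DataError("fold_change must be >= 1")
        if np.any(self.cell_factor <= 0) or np.any(self.gene_mean <= 0):
            raise DataError("means and cell factors must be positive")
        if np.any(self.gene_dispersion < 0):
            raise DataError("dispersions must be non-negative")


@dataclass
class SpikeInSim:
    """Simulated spike-in rows plus the latent variables that produced them."""

    counts: np.ndarray   # n_spikeins x n_cells
    ids: list[str]
    mu: np.ndarray       # expected count per spike-in at nu = 1
    nu: np.ndarray       # per-cell capture random effect


def estimate_template_params(
    cm: CountMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments template parameters from a real count matrix.

    Returns ``(gene_mean, gene_dispersion, cell_factor)`` where
    ``cell_factor[j]`` is the column total divided by the mean column total,
    ``gene_mean[i]`` the mean of factor-adjusted counts, and
    ``gene_dispersion[i] = max(0, (var - mean) / mean**2)`` on the
    factor-adjusted counts.
    """
    if cm.n_cells < 2:
        raise DataError("template estimation needs at least 2 cells")
    totals = cm.counts.sum(axis=0).astype(float)
    cell_factor = totals / totals.mean()
    if np.any(cell_factor <= 0):
        raise DataError("template matrix has empty cells")
    adj = cm.counts / cell_factor[None, :]
    mean = adj.mean(axis=1)
    var = adj.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    disp = np.maximum(disp, 0.0)
    return mean, disp, cell_factor


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Draw NB(mean, variance = mean + phi mean^2); phi = 0 rows are Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        m = mean[~pois]
        out[~pois] = rng.negative_binomial(r, r / (r + m))
    return out


def simulate_counts(
    gene_mean: np.ndarray,
    gene_dispersion: np.ndarray,
    n_cells_per_group: int,
    fold_change: float = 2.0,
    n_de: int = 1000,
    cell_factor: np.ndarray | None = None,
    cell_factor_sigma: float = 0.3,
    seed: int = 1,
    gene_ids: list[str] | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate a two-subgroup NB count matrix.

    Cell ``j`` of gene ``i`` is drawn ``NB`` with mean
    ``s_j * mu_i * f**[i in DE and j in group2]`` and variance
    ``m + phi_i m**2``.  The ``n_de`` fold-changed genes are chosen
    uniformly at random under ``seed``; output is deterministic given
    ``seed``.  Cell factors default to a mean-one log-normal with
    ``sigma = cell_factor_sigma``.
    """
    if fold_change < 1:
        raise DataError("fold_change must be >= 1")
    if n_cells_per_group < 2:
        raise DataError("need at least 2 cells per group")
    gene_mean = np.asarray(gene_mean, dtype=float)
    gene_dispersion = np.asarray(gene_dispersion, dtype=float)
    n_genes = gene_mean.size
    n_cells = 2 * n_cells_per_group
    rng = np.random.default_rng(seed)

    if cell_factor is None:
        cell_factor = rng.lognormal(0.0, cell_factor_sigma, size=n_cells)
        cell_factor /= cell_factor.mean()
    else:
        cell_factor = np.asarray(cell_factor, dtype=float)
        if cell_factor.size != n_cells:
            raise DataError("cell_factor must have one entry per cell")

    n_de = min(int(n_de), n_genes)
    de_flags = np.zeros(n_genes, dtype=bool)
    de_flags[rng.choice(n_genes, size=n_de, replace=False)] = True

    group = np.array(
        [GROUP_LABELS[0]] * n_cells_per_group + [GROUP_LABELS[1]] * n_cells_per_group,
        dtype=object,
    )
    fold = np.ones((n_genes, n_cells))
    fold[np.ix_(de_flags, group == GROUP_LABELS[1])] = fold_change

    mean = cell_factor[None, :] * gene_mean[:, None] * fold
    counts = _nb_sample(rng, mean, gene_dispersion[:, None])

    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    cell_ids = [f"cell{j:03d}" for j in range(n_cells)]
    truth = SimulationTruth(
        gene_mean=gene_mean,
        gene_dispersion=gene_dispersion,
        cell_factor=cell_factor,
        de_flags=de_flags,
        fold_change=float(fold_change),
        group_label=group,
        seed=seed,
    )
    cm = CountMatrix(counts, gene_ids, cell_ids, condition=group.copy())
    return cm, truth


def simulate_spikeins(
    ref: SpikeInReference,
    n_cells: int,
    capture_efficiency: np.ndarray | float = 1.0,
    noise_theta: float = 0.0,
    seed: int = 1,
    count_scale: float | None = None,
) -> SpikeInSim:
    """Simulate spike-in count rows.

    Per cell ``j`` a capture random effect ``nu_j`` is drawn from a Gamma
    with shape ``1/theta`` and mean ``s_j`` (``nu_j = s_j`` when
    ``theta = 0``); the count of spike-in ``i`` is Poisson with mean
    ``nu_j * mu_i`` where ``mu_i`` is proportional to the known
    concentration.  The proportionality constant defaults so that the
    median expected spike-in count at ``s_j = 1`` is about 50.
    """
    if len(ref) == 0:
        raise DataError("spike-in reference is empty")
    if noise_theta < 0:
        raise DataError("noise_theta must be non-negative")
    s = np.broadcast_to(np.asarray(capture_efficiency, dtype=float), (n_cells,)).copy()
    if np.any(s <= 0):
        raise DataError("capture efficiencies must be positive")
    conc = np.array(list(ref.concentrations.values()), dtype=float)
    ids = list(ref.concentrations)
    if count_scale is None:
        count_scale = 50.0 / np.median(conc)
    mu = count_scale * conc
    rng = np.random.default_rng(seed)
    if noise_theta > 0:
        nu = rng.gamma(1.0 / noise_theta, scale=s * noise_theta)
        nu = np.maximum(nu, 1e-12)
    else:
        nu = s
    counts = rng.poisson(mu[:, None] * nu[None, :])
    return SpikeInSim(counts=counts.astype(np.int64), ids=ids, mu=mu, nu=nu)


def attach_labels(cm: CountMatrix, truth: SimulationTruth) -> CountMatrix:
    """Populate the matrix's condition field from the truth group labels."""
    if truth.group_label.size != cm.n_cells:
        raise DataError(
            f"truth has {truth.group_label.size} labels but matrix has "
            f"{cm.n_cells} cells"
        )
    return cm.with_condition(truth.group_label)


def default_spikein_reference(n_spikeins: int = 8) -> SpikeInReference:
    """A synthetic spike-in panel with concentrations spanning ~4 decades.

    Stands in for an ERCC-style control mix when simulating; concentrations
    are geometrically spaced so that log-concentration is linear in the
    panel index (all above 1, so natural logs are positive).
    """
    conc = np.geomspace(4.0, 30000.0, n_spikeins)
    return SpikeInReference(
        {f"ERCC-{i + 1:05d}": float(c) for i, c in enumerate(conc)},
        unit="attomoles/uL",
    )


def simulate_dataset(
    n_genes: int = 10000,
    n_cells_per_group: int = 24,
    fold_change: float = 2.0,
    n_de: int = 1000,
    theta: float = 0.3,
    n_spikeins: int = 8,
    seed: int = 1,
    mean_log_mu: float = 1.0,
    mean_log_sigma: float = 1.5,
    disp_log_mu: float = float(np.log(0.3)),
    disp_log_sigma: float = 0.7,
    cell_factor_sigma: float = 0.3,
    spikein_reference: SpikeInReference | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Generate a complete labelled data set: biological genes + spike-ins.

    Gene mean rates are log-normal (heavily right-skewed, as in real
    droplet/plate data), overdispersions log-normal around 0.3, and cell
    factors mean-one log-normal.  Spike-in rows share the cell's scaling
    through the capture effect ``nu_j`` (mean ``s_j``, noise ``theta``) and
    are appended below the biological genes with gene lengths attached so
    FPKM-based methods can run.
    """
    rng = np.random.default_rng(seed)
    gene_mean = rng.lognormal(mean_log_mu, mean_log_sigma, size=n_genes)
    gene_disp = rng.lognormal(disp_log_mu, disp_log_sigma, size=n_genes)
    cm, truth = simulate_counts(
        gene_mean,
        gene_disp,
        n_cells_per_group,
        fold_change=fold_change,
        n_de=n_de,
        cell_factor_sigma=cell_factor_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )
    ref = spikein_reference or default_spikein_reference(n_spikeins)
    spikes = simulate_spikeins(
        ref,
        cm.n_cells,
        capture_efficiency=truth.cell_factor,
        noise_theta=theta,
        seed=int(rng.integers(2**31 - 1)),
    )
    counts = np.vstack([cm.counts, spikes.counts])
    gene_ids = cm.gene_ids + spikes.ids
    is_spikein = np.concatenate(
        [np.zeros(n_genes, dtype=bool), np.ones(len(spikes.ids), dtype=bool)]
    )
    lengths = np.concatenate(
        [
            rng.integers(500, 5000, size=n_genes),
            rng.integers(250, 2000, size=len(spikes.ids)),
        ]
    )
    full = CountMatrix(
        counts,
        gene_ids,
        cm.cell_ids,
        is_spikein=is_spikein,
        condition=truth.group_label.copy(),
        gene_lengths=lengths,
    )
    truth.capture_efficiency = truth.cell_factor.copy()
    truth.spike_mu = spikes.mu
    truth.spike_nu = spikes.nu
    truth.seed = seed
    return full, truth
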