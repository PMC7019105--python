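"""Quantile regression, slope modes and the K-group acceptance loop."""

import numpy as np
import pytest

from cellnorm.data import CountMatrix, DataError
from cellnorm.normalize import (
    SCnormNormalizer,
    check_slope_modes,
    gene_slopes,
    mode_of_slopes,
    normalize_scnorm,
    quantile_regression,
)


class TestQuantileRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        coef = quantile_regression(2 * x, x, tau=0.5, degree=1)
        np.testing.assert_allclose(coef, [0.0, 2.0], atol=1e-9)

    def test_median_slope_recovery_under_symmetric_noise(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 500)
        y = x + rng.laplace(0, 0.5, 500)
        coef = quantile_regression(y, x, tau=0.5, degree=1)
        assert abs(coef[1] - 1.0) < 0.1

    def test_quantile_monotonicity_of_intercept(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 500)
        y = x + rng.laplace(0, 0.5, 500)
        c50 = quantile_regression(y, x, tau=0.5, degree=1)
        c90 = quantile_regression(y, x, tau=0.9, degree=1)
        assert c90[0] >= c50[0] - 0.2

    def test_check_loss_is_minimized(self):
        # the LP solution should beat small perturbations on the check loss
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 60)
        y = 1 + 0.7 * x + rng.normal(0, 0.3, 60)
        tau = 0.3
        coef = quantile_regression(y, x, tau, 1)
        def loss(c):
            u = y - (c[0] + c[1] * x)
            return np.sum(u * (tau - (u < 0)))
        base = loss(coef)
        for d0 in (-0.05, 0.05):
            for d1 in (-0.05, 0.05):
                assert base <= loss(coef + [d0, d1]) + 1e-9

    def test_collinear_design_errors(self):
        with pytest.raises(DataError, match="collinear"):
            quantile_regression(np.arange(5.0), np.ones(5), 0.5, 1)


class TestModeOfSlopes:
    def test_constant_sample(self):
        assert mode_of_slopes([1.0, 1.0, 1.0]) == 1.0

    def test_bimodal_mode_at_heavier_cluster(self):
        rng = np.random.default_rng(4)
        sample = np.concatenate([
            rng.normal(0, 0.01, 100), rng.normal(1, 0.01, 10)
        ])
        assert abs(mode_of_slopes(sample)) < 0.05

    def test_symmetric_unimodal_mode_near_median(self):
        rng = np.random.default_rng(5)
        sample = rng.normal(0.4, 0.1, 2000)
        assert abs(mode_of_slopes(sample) - np.median(sample)) < 0.05


def _depth_matrix(n_genes=30, n_cells=24):
    """Counts exactly proportional to depth: count-depth slope 1."""
    mu = np.array([2, 3, 5, 8, 12, 20, 30, 50, 80, 120] * (n_genes // 10))
    depth = np.arange(1, n_cells + 1)
    return CountMatrix(
        mu[:, None] * depth[None, :],
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
    )


class TestNormalizeScnorm:
    def test_pure_depth_accepted_at_k1(self):
        cm = _depth_matrix()
        nm, fit = normalize_scnorm(cm)
        assert fit.K == 1 and fit.converged
        assert np.all(np.abs(fit.check_modes) <= 0.1)
        ratio = nm.values / nm.values[:, :1]
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[0:1, :], ratio.shape), rtol=1e-6
        )

    def test_violating_mode_triggers_k_increment(self):
        # construct data where one expression pool keeps slope ~0.15 after
        # any common per-cell rescaling within K=1 (half the genes slope 1,
        # half slope ~1.3): a single group cannot flatten both
        rng = np.random.default_rng(6)
        n_cells = 24
        depth = np.exp(np.linspace(0, 2.5, n_cells))
        mu_flat = rng.lognormal(2.0, 0.3, 40)
        mu_steep = rng.lognormal(2.0, 0.3, 40)
        flat = mu_flat[:, None] * depth[None, :]
        steep = mu_steep[:, None] * depth[None, :] ** 1.4
        counts = np.maximum(np.round(np.vstack([flat, steep])), 1).astype(int)
        cm = CountMatrix(
            counts, [f"g{i}" for i in range(80)], [f"c{j}" for j in range(n_cells)]
        )
        _, fit = normalize_scnorm(
            cm, K_max=4,
            quantile_grid=(0.25, 0.5, 0.75), degree_grid=(1, 2),
        )
        assert fit.K > 1

    def test_check_function_flags_constructed_mode(self):
        # normalized data where one pool of genes still has slope 0.15
        n_cells = 30
        log_depth = np.linspace(0, 3, n_cells)
        n_genes = 40
        log_values = np.zeros((n_genes, n_cells))
        log_values[:20] = 5.0                      # flat pool, high expression
        log_values[20:] = 1.0 + 0.15 * log_depth   # residual depth effect
        nonzero = np.ones_like(log_values, dtype=bool)
        modes = check_slope_modes(log_values, nonzero, log_depth, n_pools=2)
        assert np.any(np.abs(modes) > 0.1)
        assert np.any(np.abs(modes) <= 0.1)

    def test_renormalizing_accepted_output_stays_k1(self):
        rng = np.random.default_rng(17)
        mu = rng.lognormal(2.5, 0.8, 40)
        depth = np.exp(np.linspace(0, 2, 24))
        cm = CountMatrix(
            rng.poisson(mu[:, None] * depth[None, :]) + 1,
            [f"g{i}" for i in range(40)],
            [f"c{j}" for j in range(24)],
        )
        nm, fit = normalize_scnorm(cm)
        assert fit.converged
        # re-check the accepted output against the original sequencing
        # depths (depth is a property of the experiment, not of the
        # normalized values, whose column totals are deliberately flat)
        rounded = np.round(nm.values * 16).astype(int)
        cm2 = CountMatrix(rounded, cm.gene_ids, cm.cell_ids)
        _, fit2 = normalize_scnorm(cm2, depths=cm.counts.sum(axis=0))
        assert fit2.K == 1 and fit2.converged

    def test_low_coverage_gene_passed_through_scaled(self):
        cm = _depth_matrix()
        counts = cm.counts.copy()
        counts[0, :] = 0
        counts[0, :9] = 5  # only 9 nonzero cells < min_nonzero=10
        cm2 = CountMatrix(counts, cm.gene_ids, cm.cell_ids)
        nm, fit = normalize_scnorm(cm2, min_nonzero=10)
        assert 0 in fit.passthrough_genes
        g = fit.group_assignment[0]
        assert g >= 0
        expected = counts[0] / fit.size_factor[g]
        nonzero = counts[0] > 0
        np.testing.assert_allclose(nm.values[0, nonzero], expected[nonzero])
        assert np.all(nm.values[0, ~nonzero] == 0)

    def test_zeros_stay_zero(self):
        cm = _depth_matrix()
        counts = cm.counts.copy()
        counts[2, ::2] = 0
        cm2 = CountMatrix(counts, cm.gene_ids, cm.cell_ids)
        nm, _ = normalize_scnorm(cm2)
        assert np.all(nm.values[2, ::2] == 0)

    def test_fewer_genes_than_groups_errors(self):
        cm = _depth_matrix(n_genes=10).subset(np.arange(3), None)
        est = SCnormNormalizer(K_min=5, K_max=6)
        with pytest.raises(DataError, match="K=5"):
            est.fit(cm)


class TestGeneSlopes:
    def test_known_slopes_recovered(self):
        n_cells = 30
        log_depth = np.linspace(0, 3, n_cells)
        log_values = np.vstack([
            2.0 + 1.0 * log_depth,
            1.0 + 0.0 * log_depth,
            0.5 + 0.5 * log_depth,
        ])
        nonzero = np.ones_like(log_values, dtype=bool)
        slopes = gene_slopes(log_values, nonzero, log_depth, min_nonzero=5)
        np.testing.assert_allclose(slopes, [1.0, 0.0, 0.5], atol=1e-8)

    def test_insufficient_coverage_gives_nan(self):
        log_values = np.ones((1, 30))
        nonzero = np.zeros((1, 30), dtype=bool)
        nonzero[0, :5] = True
        slopes = gene_slopes(log_values, nonzero, np.linspace(0, 3, 30), min_nonzero=10)
        assert np.isnan(slopes[0])
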