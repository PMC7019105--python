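"""Simple, SAMstrt, Linnorm and scran: identities, formulas, invariances."""

import numpy as np
import pytest

from cellnorm.data import CountMatrix, DataError
from cellnorm.normalize import (
    LinnormNormalizer,
    SAMstrtNormalizer,
    ScranNormalizer,
    default_pool_sizes,
    normalize_linnorm,
    normalize_samstrt,
    normalize_scran,
    normalize_simple,
)


def _cm(arr, spike=None, **kw):
    arr = np.asarray(arr)
    return CountMatrix(
        arr,
        [f"g{i}" for i in range(arr.shape[0])],
        [f"c{j}" for j in range(arr.shape[1])],
        is_spikein=spike,
        **kw,
    )


class TestSimple:
    def test_closed_form(self):
        cm = _cm([[1], [1], [2]])
        nm = normalize_simple(cm, scale_factor=100)
        np.testing.assert_allclose(
            nm.values[:, 0], [np.log(26), np.log(26), np.log(51)]
        )
        assert nm.values[0, 0] == pytest.approx(3.2581, abs=1e-4)

    def test_zero_maps_to_zero(self):
        cm = _cm([[0], [10]])
        assert normalize_simple(cm).values[0, 0] == 0.0

    def test_depth_invariance(self):
        cm = _cm([[1, 3], [2, 6], [3, 9]])
        nm = normalize_simple(cm)
        np.testing.assert_allclose(nm.values[:, 0], nm.values[:, 1])

    def test_zero_column_errors(self):
        with pytest.raises(DataError, match="c1"):
            normalize_simple(_cm([[1, 0], [1, 0]]))

    def test_monotone_within_cell(self, random_counts):
        nm = normalize_simple(random_counts)
        col = 0
        order = np.argsort(random_counts.counts[:, col], kind="stable")
        diffs = np.diff(nm.values[order, col])
        assert np.all(diffs >= -1e-12)


class TestSAMstrt:
    def _with_spikes(self, bio, spikes):
        arr = np.vstack([bio, spikes])
        mask = [False] * len(bio) + [True] * len(spikes)
        return _cm(arr, spike=mask)

    def test_equal_spike_totals_identity(self):
        cm = self._with_spikes([[4, 7], [2, 9]], [[10, 10]])
        nm = normalize_samstrt(cm, mode="expected")
        np.testing.assert_allclose(nm.values, cm.counts)

    def test_double_depth_halves_counts(self):
        # spike totals (10, 40): geometric mean 20, factors (0.5, 2.0)
        cm = self._with_spikes([[8, 8]], [[10, 40]])
        nm = normalize_samstrt(cm, mode="expected")
        np.testing.assert_allclose(nm.values[0], [16.0, 4.0])

    def test_resample_mean_matches_expectation(self):
        cm = self._with_spikes([[50, 20]], [[10, 40]])
        nm = normalize_samstrt(cm, mode="resample", n_resamples=10000, seed=0)
        expected = cm.counts[0] / np.array([0.5, 2.0])
        se = np.sqrt(expected / 10000)
        assert np.all(np.abs(nm.values[0] - expected) < 3 * se)

    def test_zero_spike_total_errors(self):
        cm = self._with_spikes([[5, 5]], [[10, 0]])
        with pytest.raises(DataError, match="zero spike-in"):
            normalize_samstrt(cm)

    def test_no_spikeins_errors(self):
        with pytest.raises(DataError):
            normalize_samstrt(_cm([[1, 2]]))


class TestLinnorm:
    @pytest.fixture()
    def counts(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(2.0, 1.2, 80)
        depth = rng.uniform(0.5, 2.0, 12)
        return _cm(rng.poisson(mu[:, None] * depth[None, :]) + 1)

    def test_c_zero_equals_simple_at_lambda(self, counts):
        nm, fit = normalize_linnorm(counts, c=0.0)
        simple = normalize_simple(counts, scale_factor=fit.lambda_)
        np.testing.assert_allclose(nm.values, simple.values, atol=1e-12)

    def test_default_strength_recorded(self, counts):
        _, fit = normalize_linnorm(counts)
        assert fit.c == 0.5

    def test_identical_columns_identical_models(self):
        col = np.arange(1, 41)
        cm = _cm(np.c_[col, col])
        nm, fit = normalize_linnorm(cm, c=0.5)
        assert fit.a[0] == pytest.approx(fit.a[1])
        assert fit.b[0] == pytest.approx(fit.b[1])
        np.testing.assert_allclose(nm.values[:, 0], nm.values[:, 1])

    def test_depth_invariance_of_scaled_cell(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(20, size=(60, 5)) + 1
        cm = _cm(base)
        scaled = base.copy()
        scaled[:, 0] *= 3  # cell 0 is not the median-total cell
        cm_scaled = _cm(scaled)
        a = normalize_linnorm(cm, c=0.5)[0]
        b = normalize_linnorm(cm_scaled, c=0.5)[0]
        np.testing.assert_allclose(a.values[:, 0], b.values[:, 0], rtol=1e-10)

    def test_continuity_in_c(self, counts):
        values = [normalize_linnorm(counts, c=c)[0].values
                  for c in (0.0, 0.25, 0.5, 0.75, 1.0)]
        steps = [np.max(np.abs(values[i + 1] - values[i])) for i in range(4)]
        assert all(s < 2.0 for s in steps)
        assert np.max(np.abs(values[1] - values[0])) < np.max(np.abs(values[4] - values[0])) + 1e-9

    def test_invalid_strength_errors(self, counts):
        with pytest.raises(DataError):
            normalize_linnorm(counts, c=1.5)

    def test_column_relative_scale_sums_to_one(self, counts):
        _, fit = normalize_linnorm(counts)
        np.testing.assert_allclose(fit.R.sum(axis=0), 1.0)


class TestScran:
    def test_identical_cells_unit_factors(self):
        col = np.arange(1, 101)
        cm = _cm(np.tile(col[:, None], (1, 30)))
        nm = normalize_scran(cm)
        np.testing.assert_allclose(nm.size_factors, 1.0, atol=1e-9)
        np.testing.assert_allclose(nm.values, cm.counts)

    def test_noiseless_proportional_exact_recovery(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 60, 300)
        mult = np.arange(1, 41)
        cm = _cm(base[:, None] * mult[None, :])
        nm = normalize_scran(cm)
        truth = mult / mult.mean()
        rel = np.abs(nm.size_factors - truth) / truth
        assert rel.max() < 1e-6

    def test_small_data_warns_about_minimum(self):
        cm = _cm(np.arange(1, 51).reshape(5, 10) + 10)
        with pytest.warns(UserWarning, match="minimum of 20"):
            normalize_scran(cm)

    def test_gene_permutation_invariance(self, random_counts):
        nm = normalize_scran(random_counts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(random_counts.n_genes)
        shuffled = random_counts.subset(perm, None)
        nm2 = normalize_scran(shuffled)
        np.testing.assert_allclose(nm.size_factors, nm2.size_factors, rtol=1e-10)

    def test_global_scaling_invariance(self, random_counts):
        nm = normalize_scran(random_counts)
        tripled = _cm(random_counts.counts * 3)
        nm2 = normalize_scran(tripled)
        np.testing.assert_allclose(nm.size_factors, nm2.size_factors, rtol=1e-8)

    def test_pool_size_ladder(self):
        assert default_pool_sizes(200) == tuple(range(21, 102, 5))
        assert default_pool_sizes(48) == (21, 26, 31, 36, 41, 46)
        assert default_pool_sizes(10) == (5,)

    def test_every_cell_in_a_pool(self, random_counts):
        est = ScranNormalizer().fit(random_counts)
        seen = np.zeros(random_counts.n_cells, dtype=bool)
        for pool in est.pools_.pool_memberships:
            assert len(pool) >= 2
            seen[pool] = True
        assert seen.all()
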