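"""Kappa, KNN repeats, PCA, BH adjustment and DE screening."""

import numpy as np
import pytest
from scipy import stats

from cellnorm.data import DataError, NormalizedMatrix
from cellnorm.evaluate import (
    ConfusionMatrix,
    bh_adjust,
    cohens_kappa,
    de_screen,
    knn_classify_repeated,
    pca_embed,
)
from cellnorm.simulate import simulate_counts


class TestCohensKappa:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[50, 0], [0, 50]], 1.0),
            ([[9, 1], [81, 9]], 0.0),
            ([[40, 10], [20, 30]], 0.4),
        ],
    )
    def test_hand_computed_values(self, table, expected):
        cmx = ConfusionMatrix(np.array(table), ["a", "b"])
        assert cohens_kappa(cmx) == pytest.approx(expected, abs=1e-12)

    def test_perfect_iff_diagonal(self):
        diag = ConfusionMatrix(np.array([[7, 0], [0, 3]]), ["a", "b"])
        assert cohens_kappa(diag) == 1.0
        off = ConfusionMatrix(np.array([[7, 1], [0, 3]]), ["a", "b"])
        assert cohens_kappa(off) < 1.0

    def test_label_permutation_invariance(self):
        t = np.array([[40, 10], [20, 30]])
        k1 = cohens_kappa(ConfusionMatrix(t, ["a", "b"]))
        k2 = cohens_kappa(ConfusionMatrix(t[::-1, ::-1], ["b", "a"]))
        assert k1 == pytest.approx(k2)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(0)
        y1 = rng.integers(0, 3, 200)
        y2 = rng.integers(0, 3, 200)
        cmx = ConfusionMatrix.from_predictions(y1, y2)
        assert cohens_kappa(cmx) == pytest.approx(cohen_kappa_score(y1, y2))

    def test_empty_matrix_errors(self):
        with pytest.raises(DataError):
            ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])


class TestKnnRepeated:
    def test_separated_clouds_perfect_kappa(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(30, 5))
        b = rng.normal(100, 1, size=(30, 5))
        values = np.vstack([a, b])
        labels = ["x"] * 30 + ["y"] * 30
        kappas = knn_classify_repeated(values, labels, n_repeats=100, seed=2)
        assert kappas == [1.0] * 100

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(80, 10))
        labels = np.array(["x"] * 40 + ["y"] * 40)
        rng.shuffle(labels)
        kappas = knn_classify_repeated(values, labels, n_repeats=100, seed=4)
        assert abs(np.mean(kappas)) < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(40, 4))
        labels = ["x"] * 20 + ["y"] * 20
        a = knn_classify_repeated(values, labels, n_repeats=10, seed=6)
        b = knn_classify_repeated(values, labels, n_repeats=10, seed=6)
        assert a == b

    def test_small_condition_errors(self):
        values = np.zeros((8, 2))
        labels = ["x"] * 5 + ["y"] * 3
        with pytest.raises(DataError, match="k\\+1"):
            knn_classify_repeated(values, labels, k=5)


class TestPcaEmbed:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 11.0)
        v = np.linspace(0.5, 2.0, 6)
        values = np.outer(u, v)
        scores = pca_embed(values, n_components=3)
        total = (scores**2).sum()
        assert (scores[:, 0] ** 2).sum() / total > 0.9999

    def test_rotation_invariance_of_distances(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(20, 10))
        q, _ = np.linalg.qr(rng.normal(size=(20, 20)))
        rotated = q @ values
        s1 = pca_embed(values, 5)
        s2 = pca_embed(rotated, 5)
        d1 = np.linalg.norm(s1[:, None] - s1[None, :], axis=-1)
        d2 = np.linalg.norm(s2[:, None] - s2[None, :], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(20, 10))
        scores = pca_embed(values, 5)
        X = values.T - values.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1][:5]
        oracle = X @ evecs[:, order]
        for c in range(5):
            a, b = scores[:, c], oracle[:, c]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_constant_matrix_errors(self):
        with pytest.raises(DataError):
            pca_embed(np.ones((5, 4)), 2)

    def test_too_many_components_errors(self):
        with pytest.raises(DataError):
            pca_embed(np.random.default_rng(0).normal(size=(5, 4)), 5)


class TestBhAdjust:
    def test_step_up_oracle(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_adjusted_at_least_raw_and_rank_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_idempotent_on_uniform_block(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(adj), adj)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        p = rng.random(500) ** 2
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


def _nm(values):
    v = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=v, method="test", scale="log",
        gene_ids=[f"g{i}" for i in range(v.shape[0])],
        cell_ids=[f"c{j}" for j in range(v.shape[1])],
    )


class TestDeScreen:
    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(2000, 60))
        labels = ["a"] * 30 + ["b"] * 30
        p, n_sig = de_screen(_nm(values), labels, alpha=0.05)
        # BH controls the false discovery rate, so under the global null the
        # significant fraction should be (close to) zero
        assert n_sig / 2000 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 2000)

    def test_truth_aware_precision_on_simulated_de(self):
        mu = np.random.default_rng(12).lognormal(2.0, 1.0, 3000)
        cm, truth = simulate_counts(
            mu, np.full(3000, 0.3), 100, fold_change=5.0, n_de=300, seed=13
        )
        # remove depth with the generator's own factors so the screen is
        # tested in isolation from normalization composition bias
        values = np.log1p(cm.counts / truth.cell_factor[None, :])
        p, n_sig = de_screen(_nm(values), truth.group_label, alpha=0.05)
        adj = bh_adjust(p)
        flagged = adj < 0.05
        precision = truth.de_flags[flagged].mean()
        assert n_sig > 0
        assert precision >= 0.8

    def test_three_conditions_rejected(self):
        values = np.zeros((5, 9))
        labels = ["a", "b", "c"] * 3
        with pytest.raises(DataError, match="pairwise"):
            de_screen(_nm(values), labels)

    def test_nb_wald_runs_on_counts(self):
        rng = np.random.default_rng(14)
        base = rng.poisson(20, size=(30, 40)).astype(float)
        base[:5, 20:] *= 6  # strong group effect in 5 genes
        labels = ["a"] * 20 + ["b"] * 20
        nm = NormalizedMatrix(
            values=base, method="t", scale="linear",
            gene_ids=[f"g{i}" for i in range(30)],
            cell_ids=[f"c{j}" for j in range(40)],
        )
        p, n_sig = de_screen(nm, labels, test="nb_wald")
        assert np.all(bh_adjust(p)[:5] < 0.05)


class TestEmbedNonlinear:
    def test_tsne_hook_shape_and_determinism(self):
        from cellnorm.evaluate import embed_nonlinear
        rng = np.random.default_rng(15)
        scores = np.vstack([rng.normal(0, 1, (15, 6)), rng.normal(8, 1, (15, 6))])
        a = embed_nonlinear(scores, method="tsne", seed=3)
        b = embed_nonlinear(scores, method="tsne", seed=3)
        assert a.shape == (30, 2)
        np.testing.assert_allclose(a, b)

    def test_unknown_method_errors(self):
        from cellnorm.evaluate import embed_nonlinear
        with pytest.raises(DataError):
            embed_nonlinear(np.zeros((10, 3)), method="pca")
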