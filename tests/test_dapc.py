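import numpy as np
import pytest

from ssrpop import (
    Dapc,
    cross_validate,
    find_clusters,
    fit_dapc,
    fit_pca,
    simulate_binary_fmodel,
    subset_reanalysis,
)
from ssrpop.synthetic_data import OriginSpec, SimConfig, simulate_panel


def _blobs(centers, n_each=30, sd=0.1, dim=40, seed=0):
    """Spherical Gaussian blobs; centers given in the first coordinates.

    Dimensionality mirrors a retained-PC-score matrix: the BIC penalty
    K·ln(N) is calibrated for such moderately high-dimensional scores
    (in very low dimension k-means reduces noise WSS too fast for it).
    """
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            np.pad(np.asarray(c, dtype=float), (0, dim - len(c)))
            + sd * rng.standard_normal((n_each, dim))
            for c in centers
        ]
    )
    labels = np.repeat(np.arange(len(centers)), n_each)
    return X, labels


class TestPca:
    def test_eigenvalues_equal_column_variances_for_orthogonal_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3)) * np.array([3.0, 2.0, 1.0])
        X -= X.mean(axis=0)
        pca = fit_pca(X)
        np.testing.assert_allclose(
            np.sort(pca.eigenvalues)[::-1],
            np.sort(X.var(axis=0, ddof=1))[::-1],
            rtol=0.1,
        )

    def test_total_variance_conserved(self, small_binary):
        pca = fit_pca(small_binary)
        from ssrpop.dapc import _as_imputed_array

        X = _as_imputed_array(small_binary)
        assert pca.eigenvalues.sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), rel=1e-9
        )

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 6))
        pca = fit_pca(X)
        recon = pca.scores @ pca.loadings.T + pca.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_cumulative_variance_monotone(self, small_binary):
        pca = fit_pca(small_binary)
        cv = pca.cumulative_variance
        assert (np.diff(cv) >= -1e-12).all()
        assert cv[-1] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((5, 3)))


class TestFindClusters:
    def test_three_separated_blobs(self):
        X, _ = _blobs([np.r_[0, 0, 0, 0], np.r_[10, 0, 0, 0], np.r_[0, 10, 0, 0]])
        search = find_clusters(fit_pca(X), k_max=8, seed=0)
        assert search.best_k == 3

    def test_single_blob(self):
        X, _ = _blobs([np.r_[0, 0, 0, 0]], n_each=60)
        search = find_clusters(fit_pca(X), k_max=6, seed=0)
        assert search.best_k == 1

    def test_wss_nonincreasing(self, small_binary):
        search = find_clusters(fit_pca(small_binary), k_max=8, n_pcs=10, seed=1)
        assert (np.diff(search.wss) <= 1e-9).all()

    def test_bic_reproducible_for_fixed_seed(self, small_binary):
        pca = fit_pca(small_binary)
        a = find_clusters(pca, k_max=6, n_pcs=10, seed=7)
        b = find_clusters(pca, k_max=6, n_pcs=10, seed=7)
        np.testing.assert_array_equal(a.bic, b.bic)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestFitDapc:
    def test_two_groups_single_axis(self):
        X, labels = _blobs([np.r_[0, 0, 0, 0], np.r_[5, 0, 0, 0]])
        model = fit_dapc(fit_pca(X), labels)
        assert model.n_da == 1
        assert (model.eigenvalues >= 0).all()

    def test_disjoint_clouds_training_accuracy(self):
        X, labels = _blobs(
            [np.r_[0, 0, 0, 0], np.r_[8, 0, 0, 0], np.r_[0, 8, 0, 0]]
        )
        pca = fit_pca(X)
        model = fit_dapc(pca, labels)
        pred, posterior = model.predict(pca.scores[:, : model.n_pcs])
        assert (pred == labels).all()
        np.testing.assert_allclose(posterior.sum(axis=1), 1.0)

    def test_matches_bruteforce_fisher_on_two_groups(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 2))
        X[:20] += [2.0, 1.0]
        labels = np.repeat([0, 1], 20)
        pca = fit_pca(X)
        model = fit_dapc(pca, labels)
        # brute force: maximize Fisher ratio over a dense angle grid
        S = pca.scores
        best, best_ratio = None, -1
        for theta in np.linspace(0, np.pi, 2000, endpoint=False):
            a = np.array([np.cos(theta), np.sin(theta)])
            proj = S @ a
            mw = [proj[labels == g].mean() for g in (0, 1)]
            within = sum(
                ((proj[labels == g] - mw[g]) ** 2).sum() for g in (0, 1)
            )
            between = sum(
                (labels == g).sum() * (mw[g] - proj.mean()) ** 2 for g in (0, 1)
            )
            if between / within > best_ratio:
                best_ratio, best = between / within, a
        axis = model.axes[:, 0]
        axis = axis / np.linalg.norm(axis)
        assert abs(abs(axis @ best) - 1) < 1e-3
        assert model.eigenvalues[0] == pytest.approx(best_ratio, rel=1e-3)

    def test_single_member_group_warns_not_fails(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((1, 3))])
        labels = ["a"] * 5 + ["b"]
        X[:5] += np.random.default_rng(0).normal(0, 0.1, (5, 3))
        with pytest.warns(UserWarning, match="single member"):
            model = fit_dapc(fit_pca(X), labels)
        assert model.n_da == 1


class TestCrossValidate:
    def test_perfectly_separable_all_pcs(self):
        X, labels = _blobs([np.r_[0, 0, 0, 0], np.r_[10, 0, 0, 0]], n_each=20)
        table, rec = cross_validate(X, labels, pc_grid=[1, 2, 4], reps=5, seed=0)
        assert (table["mean_success"] == 1.0).all()
        assert rec == 1  # ties resolved toward fewer PCs

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 6))
        labels = np.array(["a", "b"] * 40)
        table, _ = cross_validate(X, labels, pc_grid=[3], reps=30,
                                  holdout=0.2, seed=1)
        assert table["mean_success"].iloc[0] == pytest.approx(0.5, abs=0.15)

    def test_reproducible_for_fixed_seed(self, small_binary, small_panel):
        table, _ = small_panel
        t1, r1 = cross_validate(
            small_binary, table.pop_labels, pc_grid=[3, 6], reps=5,
            holdout=0.25, seed=9
        )
        t2, r2 = cross_validate(
            small_binary, table.pop_labels, pc_grid=[3, 6], reps=5,
            holdout=0.25, seed=9
        )
        assert r1 == r2
        np.testing.assert_array_equal(
            t1["mean_success"].values, t2["mean_success"].values
        )

    def test_sklearn_estimator_roundtrip(self):
        X, labels = _blobs([np.r_[0, 0, 0, 0], np.r_[6, 0, 0, 0]], n_each=15)
        clf = Dapc(n_pcs=2).fit(X, labels)
        assert set(clf.get_params()) >= {"n_pcs", "n_da", "scale", "reg"}
        assert (clf.predict(X) == labels).all()
        proba = clf.predict_proba(X)
        assert proba.shape == (30, 2)


class TestSubsetReanalysis:
    def _two_cluster_panel(self):
        # two origins with disjoint-ish allele pools via strong divergence
        origins = (
            OriginSpec("A", 20, 0, 0.01),
            OriginSpec("B", 20, 1, 0.01),
        )
        cfg = SimConfig(
            origins=origins, n_loci=12, subpop_f=0.5, admix_fraction=0.0,
            missing_rate=0.0, seed=5,
        )
        return simulate_panel(cfg)

    def test_full_table_run_matches_direct(self):
        table, _ = self._two_cluster_panel()
        full = subset_reanalysis(table, k_max=5, seed=2)
        again = subset_reanalysis(table, sample_ids=table.sample_ids,
                                  k_max=5, seed=2)
        np.testing.assert_array_equal(full.clusters.bic, again.clusters.bic)

    def test_recovers_two_strong_clusters(self):
        table, truth = self._two_cluster_panel()
        res = subset_reanalysis(table, k_max=5, seed=2)
        assert res.clusters.best_k == 2
        pred, _ = res.dapc.predict(res.pca.scores[:, : res.dapc.n_pcs])
        subpop = np.array(truth.sample_subpop)
        # training accuracy vs true subpopulations, up to label swap
        match = max(
            np.mean((np.array(pred) == res.dapc.groups[0]) == (subpop == 0)),
            np.mean((np.array(pred) == res.dapc.groups[0]) == (subpop == 1)),
        )
        assert match > 0.95

    def test_single_cluster_subset(self):
        table, _ = self._two_cluster_panel()
        a_ids = [s for s, p in zip(table.sample_ids, table.pop_labels) if p == "A"]
        res = subset_reanalysis(table, sample_ids=a_ids, k_max=4, seed=3)
        assert res.clusters.best_k == 1
        assert res.dapc is None

    def test_subset_columns_rederived(self, small_panel):
        table, _ = small_panel
        res = subset_reanalysis(table, sample_ids=table.sample_ids[:10], seed=0)
        full_cols = len(subset_reanalysis(table, seed=0).binary.column_index)
        assert len(res.binary.column_index) <= full_cols
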