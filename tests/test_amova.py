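import numpy as np
import pytest

from ssrpop import (
    BinaryMatrix,
    DistanceMatrix,
    amova_oneway,
    nm_from_phipt,
    pairwise_phipt,
    permutation_test,
    phipt,
    simulate_binary_fmodel,
    squared_distances,
    variance_components,
)


def _bm(values, mask=None):
    values = np.asarray(values, dtype=np.int8)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return BinaryMatrix(
        [f"s{i}" for i in range(values.shape[0])],
        [("L", j + 1) for j in range(values.shape[1])],
        values,
        mask,
    )


class TestSquaredDistances:
    def test_identical_rows_zero(self):
        D = squared_distances(_bm([[1, 0, 1], [1, 0, 1]]))
        assert D.d2[0, 1] == 0

    def test_single_mismatch(self):
        D = squared_distances(_bm([[1, 0, 1], [0, 0, 1]]))
        assert D.d2[0, 1] == 1

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(20, 30))
        D = squared_distances(_bm(X))
        brute = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                brute[i, j] = ((X[i] - X[j]) ** 2).sum()
        np.testing.assert_allclose(D.d2, brute)

    def test_mean_imputation_of_masked_cells(self):
        values = np.array([[1, 1], [0, 1], [0, 1]], dtype=np.int8)
        mask = np.zeros_like(values, dtype=bool)
        mask[2, 0] = True  # imputed to mean of (1, 0) = 0.5
        D = squared_distances(_bm(values, mask))
        assert D.d2[0, 2] == pytest.approx(0.25)
        assert D.d2[1, 2] == pytest.approx(0.25)

    def test_fully_masked_column_dropped(self):
        values = np.array([[1, 1], [0, 1]], dtype=np.int8)
        mask = np.array([[True, False], [True, False]])
        with pytest.warns(UserWarning, match="dropping"):
            D = squared_distances(_bm(values, mask))
        assert D.d2[0, 1] == 0


class TestAmovaOneway:
    def test_reference_chain_from_printed_mean_squares(self):
        comp = variance_components(80.296, 26.329, [29, 42, 48, 122, 60, 41, 140])
        assert comp["n0"] == pytest.approx(64.886, abs=5e-4)
        assert comp["va"] == pytest.approx(0.832, abs=5e-4)

    def test_all_identical_samples(self):
        bm = _bm(np.ones((6, 4)))
        res = amova_oneway(squared_distances(bm), ["A"] * 3 + ["B"] * 3)
        assert res.ss_total == 0
        assert res.phi_pt == 0

    def test_ss_additivity(self, small_binary, small_panel):
        table, _ = small_panel
        res = amova_oneway(squared_distances(small_binary), table.pop_labels)
        direct = squared_distances(small_binary).d2.sum() / (
            2 * table.n_samples
        )
        assert res.ss_total == pytest.approx(direct, rel=1e-9)
        assert res.ss_among + res.ss_within == pytest.approx(
            res.ss_total, rel=1e-6
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_classical_anova_on_1d_binary(self, trial):
        """Distance AMOVA SS == textbook one-way ANOVA SS on a 0/1 variable."""
        rng = np.random.default_rng(trial)
        k = rng.integers(2, 5)
        sizes = rng.integers(3, 9, size=k)
        x = rng.integers(0, 2, size=sizes.sum()).astype(float)
        labels = np.repeat([f"g{i}" for i in range(k)], sizes)
        res = amova_oneway(squared_distances(_bm(x[:, None])), labels)
        grand = x.mean()
        ss_among = sum(
            (x[labels == g].size) * (x[labels == g].mean() - grand) ** 2
            for g in np.unique(labels)
        )
        ss_within = sum(
            ((x[labels == g] - x[labels == g].mean()) ** 2).sum()
            for g in np.unique(labels)
        )
        assert res.ss_among == pytest.approx(ss_among, abs=1e-9)
        assert res.ss_within == pytest.approx(ss_within, abs=1e-9)

    def test_scale_equivariance(self, small_binary, small_panel):
        table, _ = small_panel
        D = squared_distances(small_binary)
        res1 = amova_oneway(D, table.pop_labels)
        res2 = amova_oneway(
            DistanceMatrix(D.sample_ids, D.d2 * 3.0), table.pop_labels
        )
        assert res2.ss_total == pytest.approx(3 * res1.ss_total)
        assert res2.va == pytest.approx(3 * res1.va)
        assert res2.phi_pt == pytest.approx(res1.phi_pt)

    def test_phi_increases_with_divergence(self):
        phis = []
        for f in (0.01, 0.05, 0.2):
            bm, pops = simulate_binary_fmodel(100, 20, f, seed=11)
            res = amova_oneway(
                squared_distances(bm), [f"p{p}" for p in pops]
            )
            phis.append(res.phi_pt)
        assert phis[0] < phis[1] < phis[2]

    def test_rejects_single_group(self, small_binary):
        with pytest.raises(ValueError):
            amova_oneway(
                squared_distances(small_binary),
                ["A"] * small_binary.n_samples,
            )


class TestPhiptAndNm:
    @pytest.mark.parametrize(
        "va, vw, expected",
        [(0.832, 26.329, 0.031), (8.742, 21.398, 0.290), (0.0, 5.0, 0.0)],
    )
    def test_phipt(self, va, vw, expected):
        assert phipt(va, vw) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "phi, expected", [(0.290, 1.224), (0.5, 0.5), (1.0, 0.0)]
    )
    def test_nm_values(self, phi, expected):
        assert nm_from_phipt(phi) == pytest.approx(expected, abs=5e-4)

    def test_nm_zero_phi_is_infinite(self):
        assert np.isinf(nm_from_phipt(0.0))


class TestPermutationTest:
    def test_deterministic_given_seed(self, small_binary, small_panel):
        table, _ = small_panel
        D = squared_distances(small_binary)
        p1 = permutation_test(D, table.pop_labels, n_perm=49, seed=5)
        p2 = permutation_test(D, table.pop_labels, n_perm=49, seed=5)
        assert p1 == p2

    def test_maximal_separation_gives_minimal_p(self):
        # two groups with disjoint allele sets
        X = np.zeros((20, 8), dtype=np.int8)
        X[:10, :4] = 1
        X[10:, 4:] = 1
        D = squared_distances(_bm(X))
        p = permutation_test(D, ["A"] * 10 + ["B"] * 10, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_degenerate_distances_give_p_one(self):
        D = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        assert permutation_test(D, ["A", "A", "B", "B"], n_perm=9, seed=0) == 1.0


class TestPairwise:
    def test_shape_symmetry_and_truth_ordering(self):
        # 3 groups: p0 vs p2 most diverged under increasing F layout
        rng = np.random.default_rng(2)
        p_anc = rng.uniform(0.2, 0.8, 40)
        freqs = np.vstack(
            [p_anc, np.clip(p_anc + 0.25, 0, 1), np.clip(p_anc - 0.25, 0, 1)]
        )
        pops = np.repeat([0, 1, 2], 20)
        X = (rng.random((60, 40)) < freqs[pops]).astype(np.int8)
        bm = _bm(X)
        labels = [f"g{p}" for p in pops]
        mat, pvals = pairwise_phipt(bm, labels, n_perm=0, seed=3)
        # 3 pairs computed, PhiPT above diagonal, Nm below
        assert np.isfinite(mat.values[np.triu_indices(3, 1)]).all()
        assert np.isfinite(mat.values[np.tril_indices(3, -1)]).all()
        assert mat.loc["g1", "g2"] > 0
        # most diverged pair (g1 vs g2, +/-0.25 apart) has largest PhiPT
        pairs = {
            (a, b): mat.loc[a, b]
            for a, b in [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]
        }
        assert max(pairs, key=pairs.get) == ("g1", "g2")

    def test_small_group_skipped(self):
        X = np.array([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8)
        labels = ["A", "A", "B", "B", "C"]
        with pytest.warns(UserWarning, match="'C'"):
            mat, _ = pairwise_phipt(_bm(X), labels, n_perm=0)
        assert list(mat.index) == ["A", "B"]
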