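"""Co-expression network: soft threshold, adjacency, TOM, module
detection, eigengenes, trait correlation and hub genes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import heterosiskit as hk
from conftest import planted_block_expression


def scale_free_expression(n_genes=300, n_samples=200, seed=3):
    """Hub-structured expression whose connectivity is power-law distributed."""
    rng = np.random.default_rng(seed)
    w = 0.3 * (0.95 / 0.3) ** rng.uniform(size=n_genes)  # log-uniform weights
    f = rng.standard_normal(n_samples)
    return (
        w[None, :] * f[:, None]
        + np.sqrt(1 - w**2)[None, :] * rng.standard_normal((n_samples, n_genes))
    )


class TestSoftThreshold:
    def test_power_law_network_reaches_scale_free_fit(self):
        from heterosiskit.network import _scale_free_fit

        X = scale_free_expression()
        beta = hk.pick_soft_threshold(X)
        C = np.corrcoef(X.T)
        k = (np.abs(C) ** beta).sum(axis=0) - 1
        assert _scale_free_fit(k) >= 0.8

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            hk.pick_soft_threshold(np.random.default_rng(0).random((10, 2)))

    def test_choice_is_in_candidate_set(self):
        X = scale_free_expression(n_genes=50, n_samples=30, seed=1)
        assert hk.pick_soft_threshold(X, candidates=range(1, 13)) in range(1, 13)


class TestAdjacency:
    def test_perfect_correlation_is_unit_edge(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x + 3, -x])
        A = hk.build_adjacency(X, beta=7).to_numpy()
        assert A == pytest.approx(np.ones((3, 3)))

    def test_monotone_decreasing_in_beta_below_unit_correlation(self):
        X, _ = planted_block_expression((30,), n_samples=15, within_cor=0.5, seed=2)
        a1 = hk.build_adjacency(X, beta=2).to_numpy()
        a2 = hk.build_adjacency(X, beta=8).to_numpy()
        off = ~np.eye(30, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_zero_variance_gene_is_error(self):
        X = pd.DataFrame({"g0": [1.0, 2, 3], "g1": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="g1"):
            hk.build_adjacency(X, beta=6)


class TestTOM:
    def test_isolated_perfect_pair_has_unit_overlap(self):
        A = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert hk.compute_tom(A)[0, 1] == pytest.approx(1.0)

    def test_unconnected_pair_without_shared_neighbors_is_zero(self):
        A = np.eye(3)
        assert hk.compute_tom(A)[0, 1] == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(9)
        for n in (4, 8, 10):
            M = rng.random((n, n))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            tom = hk.compute_tom(A)
            k = A.sum(axis=0) - 1
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    num = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                    expected = (num + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-12)


class TestModules:
    def test_planted_blocks_recovered_across_seeds(self):
        for seed in range(10):
            X, truth = planted_block_expression((50, 50), 20, 0.9, seed)
            net = hk.CoexpressionNetwork(beta=6).fit(X)
            assert net.n_modules_ == 2
            assert adjusted_rand_score(truth, net.labels_.to_numpy()) >= 0.9

    def test_min_size_larger_than_n_genes_unassigns_all(self):
        X, _ = planted_block_expression((20,), 10, 0.9, 0)
        with pytest.warns(RuntimeWarning):
            labels = hk.detect_modules(np.eye(20), min_module_size=50)
        assert (labels == 0).all()

    def test_gene_permutation_permutes_labels_consistently(self):
        X, _ = planted_block_expression((40, 40), 20, 0.9, 4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        net1 = hk.CoexpressionNetwork(beta=6).fit(X)
        net2 = hk.CoexpressionNetwork(beta=6).fit(X.iloc[:, perm])
        lab1 = net1.labels_.reindex(net2.labels_.index)
        # partitions agree up to label renaming
        assert adjusted_rand_score(lab1.to_numpy(), net2.labels_.to_numpy()) == 1.0


class TestEigengenes:
    def test_rank_one_module_eigengene_matches_profile(self):
        x = np.random.default_rng(1).standard_normal(12)
        X = np.column_stack([x, 2 * x, 3 * x + 1])
        me = hk.module_eigengenes(X, np.array([1, 1, 1]))
        r = np.corrcoef(me["ME1"], x)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert np.linalg.norm(me["ME1"]) == pytest.approx(1.0)

    def test_explains_maximal_variance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 6))
        me = hk.module_eigengenes(X, np.ones(6, dtype=int))
        Z = (X - X.mean(0)) / X.std(0)
        explained = np.linalg.norm(Z.T @ me["ME1"].to_numpy()) ** 2
        top_eig = np.linalg.eigvalsh(Z @ Z.T).max()
        assert explained == pytest.approx(top_eig, rel=1e-10)

    def test_orientation_follows_mean_profile(self):
        x = np.linspace(0, 1, 8)
        X = np.column_stack([x, x * 1.5])
        me = hk.module_eigengenes(X, np.array([1, 1]))
        assert np.corrcoef(me["ME1"], X.mean(1))[0, 1] > 0
        # flipping all gene profiles flips nothing observable
        me2 = hk.module_eigengenes(-X, np.array([1, 1]))
        assert np.corrcoef(me2["ME1"], (-X).mean(1))[0, 1] > 0


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene_is_perfect(self):
        X, _ = planted_block_expression((40,), 20, 0.9, 5)
        net = hk.CoexpressionNetwork(beta=6).fit(X)
        mt = net.trait_correlation(net.eigengenes_["ME1"].to_numpy())
        assert mt.loc["ME1", "r"] == pytest.approx(1.0)

    def test_orthogonalized_trait_is_null(self):
        X, _ = planted_block_expression((40,), 20, 0.9, 6)
        net = hk.CoexpressionNetwork(beta=6).fit(X)
        e = net.eigengenes_["ME1"].to_numpy()
        t = np.random.default_rng(0).standard_normal(len(e))
        t -= (t - t.mean()) @ (e - e.mean()) / ((e - e.mean()) @ (e - e.mean())) * (e - e.mean())
        assert abs(net.trait_correlation(t).loc["ME1", "r"]) < 1e-10

    def test_p_matches_closed_form(self):
        rng = np.random.default_rng(7)
        me = pd.DataFrame({"ME1": rng.standard_normal(15)})
        trait = rng.standard_normal(15)
        mt = hk.module_trait_correlation(me, trait)
        r = mt.loc["ME1", "r"]
        t_stat = r * np.sqrt((15 - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t_stat), 13)
        assert mt.loc["ME1", "p"] == pytest.approx(p, abs=1e-10)
        assert mt.loc["ME1", "r"] == pytest.approx(
            stats.pearsonr(me["ME1"], trait).statistic, abs=1e-10
        )


class TestHubGenes:
    def test_thresholds_are_strict(self):
        kme = pd.DataFrame(
            {"module": [1, 1, 1], "kme": [0.95, 0.95, 0.89], "p": [1e-8, 1e-5, 1e-8]},
            index=["a", "b", "c"],
        )
        hubs = kme[(kme["kme"] > 0.90) & (kme["p"] < 1e-6)]
        assert list(hubs.index) == ["a"]

    def test_tight_module_yields_mostly_hubs(self):
        X, _ = planted_block_expression((60,), n_samples=30, within_cor=0.95, seed=8)
        net = hk.CoexpressionNetwork(beta=6).fit(X)
        hubs = net.hub_genes(kme_min=0.90, p_max=1e-6)
        assert len(hubs) >= 0.9 * 60

    def test_kme_within_unit_interval(self):
        X, _ = planted_block_expression((40, 40), 20, 0.8, 9)
        net = hk.CoexpressionNetwork(beta=6).fit(X)
        assert net.kme_["kme"].between(-1, 1).all()
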