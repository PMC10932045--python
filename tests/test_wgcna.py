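import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cerna.wgcna import (
    UNASSIGNED,
    adjacency,
    cluster_modules,
    module_eigengenes,
    module_trait_correlation,
    pick_beta,
    scale_free_fit,
    scan_soft_threshold,
    select_key_modules,
    select_top_mad,
    tom_similarity,
)


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestSelectTopMad:
    def test_k_at_least_n_keeps_all(self):
        e = _expr(np.random.default_rng(0).normal(size=(5, 8)))
        assert select_top_mad(e, k=10).shape[0] == 5

    def test_constant_gene_loses_to_varying_gene(self):
        e = _expr([[1, 1, 1, 1], [1, 5, 2, 9]])
        assert list(select_top_mad(e, k=1).index) == ["g1"]

    def test_hand_computed_mads(self):
        # per-gene values {1,1,1}, {1,2,3}, {1,3,5} -> MADs 0, 1, 2
        e = _expr([[1, 1, 1], [1, 2, 3], [1, 3, 5]])
        assert sorted(select_top_mad(e, k=2).index) == ["g1", "g2"]

    def test_ties_break_lexicographically(self):
        e = _expr([[1, 2, 3], [1, 2, 3], [1, 2, 3]], genes=["b", "a", "c"])
        assert list(select_top_mad(e, k=2).index) == ["b", "a"]  # order kept, a+b chosen


class TestScaleFreeFit:
    def test_exact_power_law_gives_unit_r2(self):
        # counts 2520/b at connectivity b for b = 1..10: the binned
        # log-frequency vs log-connectivity relation is exactly linear
        k = np.concatenate([np.full(2520 // b, float(b)) for b in range(1, 11)])
        r2_signed, slope = scale_free_fit(k)
        assert r2_signed == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_flat_connectivity_degenerates_to_zero(self):
        assert scale_free_fit(np.full(100, 3.0)) == (0.0, 0.0)


class TestAdjacencyAndScan:
    def test_power_of_half_correlation(self):
        # duplicated profiles give |r| = 1 -> a = 1; beta=1 equals |corr|
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 12))
        a1 = adjacency(_expr(x), beta=1)
        r = np.abs(np.corrcoef(x))
        assert np.allclose(a1.to_numpy(), np.where(np.eye(4), 1.0, r), atol=1e-12)
        a5 = adjacency(_expr(x), beta=5)
        assert np.allclose(a5.to_numpy()[0, 1], r[0, 1] ** 5)
        assert 0.5**5 == pytest.approx(0.03125)

    def test_duplicated_gene_pair_has_unit_adjacency(self):
        e = _expr([[1, 4, 2, 8], [1, 4, 2, 8]])
        assert adjacency(e, 5).iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(_expr([[1, 1, 1], [1, 2, 3]]), 2)

    def test_connectivity_matches_brute_force(self):
        rng = np.random.default_rng(2)
        e = _expr(rng.normal(size=(15, 10)))
        scan = scan_soft_threshold(e, beta_range=(1, 3, 6))
        r = np.corrcoef(e.to_numpy())
        for beta in (1, 3, 6):
            k = np.array([
                sum(abs(r[i, j]) ** beta for j in range(15) if j != i)
                for i in range(15)
            ])
            assert scan.loc[beta, "mean_connectivity"] == pytest.approx(k.mean(), abs=1e-12)
            assert scan.loc[beta, "max_connectivity"] == pytest.approx(k.max(), abs=1e-12)


class TestPickBeta:
    def test_smallest_power_reaching_target(self):
        scan = pd.DataFrame({"scale_free_r2_signed": [0.2, 0.9]}, index=[1, 2])
        assert pick_beta(scan, 0.85) == (2, False)

    def test_fallback_to_best_with_warning(self):
        scan = pd.DataFrame({"scale_free_r2_signed": [0.2, 0.5, 0.7, 0.6]},
                            index=[3, 4, 6, 8])
        with pytest.warns(UserWarning, match="no power reached"):
            beta, warned = pick_beta(scan, 0.85)
        assert beta == 6 and warned

    def test_tie_prefers_smaller_power(self):
        scan = pd.DataFrame({"scale_free_r2_signed": [0.9, 0.9]}, index=[4, 7])
        assert pick_beta(scan, 0.85)[0] == 4


class TestTomSimilarity:
    def test_complete_unit_graph(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        assert np.allclose(tom_similarity(a).to_numpy(), 1.0)

    def test_disconnected_pair_without_shared_neighbors(self):
        a = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        assert tom_similarity(a).iloc[0, 1] == pytest.approx(0.0)

    def test_hand_evaluated_three_nodes(self):
        # a12 = a13 = 0.5, a23 = 0 -> TOM_23 = 0.25 / 1.5
        a = np.array([[1, 0.5, 0.5], [0.5, 1, 0.0], [0.5, 0.0, 1]])
        tom = tom_similarity(pd.DataFrame(a, index=list("abc"), columns=list("abc")))
        assert tom.iloc[1, 2] == pytest.approx(0.25 / 1.5, abs=1e-12)
        assert tom.iloc[1, 2] == pytest.approx(0.1667, abs=5e-5)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 9))
        a = adjacency(_expr(x), 4).to_numpy()
        tom = tom_similarity(adjacency(_expr(x), 4)).to_numpy()
        n = a.shape[0]
        k = a.sum(axis=1) - 1.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-10)

    def test_rejects_asymmetric_input(self):
        a = pd.DataFrame([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestClusterModules:
    @staticmethod
    def _two_blocks(n1=6, n2=5):
        n = n1 + n2
        d = np.ones((n, n))
        d[:n1, :n1] = 0.0
        d[n1:, n1:] = 0.0
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i:02d}" for i in range(n)]
        return pd.DataFrame(d, index=genes, columns=genes)

    def test_two_perfect_blocks_recovered(self):
        d = self._two_blocks()
        mods = cluster_modules(d, min_module_size=3)
        labels = [mods.assignment[g] for g in d.index]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert mods.sizes == {"turquoise": 6, "blue": 5}

    def test_all_far_apart_means_unassigned(self):
        n = 20
        d = 1.0 - np.eye(n)
        genes = [f"g{i}" for i in range(n)]
        mods = cluster_modules(pd.DataFrame(d, index=genes, columns=genes),
                               min_module_size=30)
        assert all(v == UNASSIGNED for v in mods.assignment.values())

    def test_fewer_genes_than_min_size_warns(self):
        d = self._two_blocks(3, 2)
        with pytest.warns(UserWarning, match="fewer genes"):
            mods = cluster_modules(d, min_module_size=10)
        assert all(v == UNASSIGNED for v in mods.assignment.values())

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        d = self._two_blocks(8, 6)
        noise = rng.uniform(0, 0.05, size=d.shape)
        dn = np.clip(d.to_numpy() + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(dn, 0)
        d = pd.DataFrame(dn, index=d.index, columns=d.columns)
        mods = cluster_modules(d, min_module_size=3)
        perm = rng.permutation(len(d))
        dp = d.iloc[perm, perm]
        mods_p = cluster_modules(dp, min_module_size=3)
        # same partition up to labels
        for g1 in d.index:
            for g2 in d.index:
                same = mods.assignment[g1] == mods.assignment[g2]
                same_p = mods_p.assignment[g1] == mods_p.assignment[g2]
                assert same == same_p


class TestModuleEigengenes:
    def test_repeated_profile_module(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(size=10)
        e = _expr(np.tile(profile, (5, 1)))
        mods = module_eigengenes(e, {g: "turquoise" for g in e.index})
        assert mods.variance_explained["turquoise"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        eig = mods.eigengenes["turquoise"].to_numpy()
        assert np.allclose(eig, z, atol=1e-8)

    def test_orientation_contract(self):
        rng = np.random.default_rng(6)
        e = _expr(rng.normal(size=(6, 14)))
        mods = module_eigengenes(e, {g: "blue" for g in e.index})
        eig = mods.eigengenes["blue"]
        corrs = [np.corrcoef(eig, e.loc[g])[0, 1] for g in e.index]
        assert np.mean(corrs) >= 0

    def test_two_gene_module_variance_explained(self):
        # sample correlation exactly 0.5 via orthonormal construction
        z1 = np.array([1.0, 1.0, -1.0, -1.0])
        z2 = np.array([1.0, -1.0, 1.0, -1.0])
        e = _expr([z1, 0.5 * z1 + np.sqrt(0.75) * z2])
        mods = module_eigengenes(e, {g: "brown" for g in e.index})
        assert mods.variance_explained["brown"] == pytest.approx(0.75, abs=1e-10)

    def test_constant_gene_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(3, 8))
        vals[1] = 2.0
        e = _expr(vals)
        with pytest.warns(UserWarning, match="constant"):
            mods = module_eigengenes(e, {g: "red" for g in e.index})
        assert mods.eigengenes is not None


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([0.0, 0, 0, 1, 1, 1])
        eig = pd.DataFrame({"turquoise": trait})
        table = module_trait_correlation(eig, trait)
        assert table.loc["turquoise", "r"] == pytest.approx(1.0)
        assert table.loc["turquoise", "p"] == 0.0

    def test_orthogonal_eigengene(self):
        trait = np.array([0.0, 0, 1, 1])
        eig = pd.DataFrame({"blue": [1.0, -1.0, 1.0, -1.0]})
        table = module_trait_correlation(eig, trait)
        assert table.loc["blue", "r"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["blue", "p"] == pytest.approx(1.0)

    def test_hand_example_r08_n20(self):
        # r = 0.8, n = 20 -> t = 5.657, p ~ 2.2e-5 (t-distribution oracle)
        t = 0.8 * np.sqrt(18) / np.sqrt(1 - 0.64)
        assert t == pytest.approx(5.657, abs=5e-4)
        p = 2 * sps.t.sf(t, df=18)
        assert p == pytest.approx(2.2e-5, rel=0.05)


class TestSelectKeyModules:
    def test_strongest_each_direction(self):
        table = pd.DataFrame({"r": [0.9, -0.8, 0.1]}, index=["M1", "M2", "M3"])
        assert select_key_modules(table) == ("M1", "M2")

    def test_all_positive_leaves_negative_empty(self):
        table = pd.DataFrame({"r": [0.9, 0.2]}, index=["M1", "M2"])
        assert select_key_modules(table) == ("M1", None)

    def test_tie_breaks_lexicographically(self):
        table = pd.DataFrame({"r": [0.9, 0.9, -0.3]}, index=["brown", "blue", "red"])
        assert select_key_modules(table)[0] == "blue"
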