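"""Adjacency, TOM, module detection/merging, eigengenes, kME and hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from genebirth import network as nw
from genebirth.io_formats import ExpressionMatrix, ValidationError
from genebirth.network import (
    NetworkConfig,
    adjacency,
    detect_modules,
    gene_significance,
    kme_and_hubs,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    one_hot_traits,
    tom_similarity,
)


def _planted_expression(rng, sizes, n_samples=14, loading=2.0, sigma=1.0,
                        n_noise=0):
    """Gene x sample matrix with latent-factor modules (within-module r ~ 0.8)."""
    rows, labels = [], []
    for m, size in enumerate(sizes, start=1):
        f = rng.normal(0, 1, n_samples)
        for _ in range(size):
            rows.append(loading * f + rng.normal(0, sigma, n_samples))
            labels.append(m)
    for _ in range(n_noise):
        rows.append(rng.normal(0, 1, n_samples))
        labels.append(0)
    X = pd.DataFrame(rows, index=[f"g{k}" for k in range(len(rows))])
    return X, np.array(labels)


class TestAdjacency:
    def test_perfect_correlation(self):
        X = pd.DataFrame([[1, 2, 3, 4.0], [2, 4, 6, 8.0]])
        A = adjacency(X, 9)
        assert A[0, 1] == pytest.approx(1.0)

    def test_soft_power_on_moderate_correlation(self):
        # |r| = 0.5 at beta = 9 -> 0.5^9
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 5000)
        x = z + rng.normal(0, np.sqrt(3), 5000)  # r = 0.5 with z
        X = pd.DataFrame([z, x])
        A = adjacency(X, 9)
        assert A[0, 1] == pytest.approx(0.5 ** 9, rel=0.4)

    def test_zero_variance_gene_named(self):
        X = pd.DataFrame([[1, 1, 1, 1.0], [1, 2, 3, 4.0]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            adjacency(X, 9)


class TestTOM:
    def test_two_gene_network_equals_adjacency(self):
        A = np.array([[1.0, 0.3], [0.3, 1.0]])
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.3)

    def test_complete_graph_all_ones(self):
        A = np.ones((5, 5))
        assert tom_similarity(A) == pytest.approx(np.ones((5, 5)))

    def test_three_gene_hand_computed(self):
        # a12 = 0.6, a13 = 0.4, a23 = 0.2
        A = np.array([[1, 0.6, 0.4], [0.6, 1, 0.2], [0.4, 0.2, 1]])
        tom = tom_similarity(A)
        # TOM_12 = (a13*a23 + a12) / (min(k1,k2) + 1 - a12)
        k1, k2 = 0.6 + 0.4, 0.6 + 0.2
        expect = (0.4 * 0.2 + 0.6) / (min(k1, k2) + 1 - 0.6)
        assert tom[0, 1] == pytest.approx(expect)

    def test_no_shared_neighbours_reduces_to_adjacency(self):
        # star-free 3-node: a13 = a23 = 0 so genes 1,2 share nothing
        A = np.array([[1, 0.5, 0.0], [0.5, 1, 0.0], [0.0, 0.0, 1]])
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0, 1, (20, 20))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(A)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            tom_similarity(np.array([[1, 0.2], [0.5, 1]]))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        X, truth = _planted_expression(rng, [50, 50])
        tom = tom_similarity(adjacency(X, 9))
        labels = detect_modules(tom, NetworkConfig())
        assert len(set(labels) - {0}) == 2
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_pure_noise_gives_no_modules(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(0, 1, (200, 14)))
        tom = tom_similarity(adjacency(X, 9))
        labels = detect_modules(tom, NetworkConfig())
        assert set(labels) == {0}

    def test_fewer_genes_than_min_size_all_unassigned(self):
        rng = np.random.default_rng(7)
        X, _ = _planted_expression(rng, [20])
        tom = tom_similarity(adjacency(X, 9))
        assert set(detect_modules(tom, NetworkConfig(min_module_size=30))) == {0}

    def test_standard_fixture_ari(self):
        """Planted-partition recovery on the standard fixture layout:
        3 modules of 50-200 genes, 14 samples, within-module r ~ 0.8."""
        rng = np.random.default_rng(11)
        X, truth = _planted_expression(rng, [200, 100, 50], n_noise=50)
        tom = tom_similarity(adjacency(X, 9))
        labels = detect_modules(tom, NetworkConfig())
        mask = truth > 0
        assert adjusted_rand_score(truth[mask], labels[mask]) >= 0.9


class TestEigengene:
    def test_identical_profiles_reproduce_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        X = pd.DataFrame([profile] * 4)
        me = module_eigengene(X, np.ones(4, dtype=int))["ME1"].values
        z = (profile - profile.mean()) / profile.std()
        assert me == pytest.approx(z, abs=1e-9)

    def test_orientation_stable_under_global_sign_flip(self):
        rng = np.random.default_rng(8)
        X, _ = _planted_expression(rng, [10])
        me1 = module_eigengene(X, np.ones(10, dtype=int))["ME1"]
        me2 = module_eigengene(-X, np.ones(10, dtype=int))["ME1"]
        # orientation follows the module mean profile in both cases
        assert abs(np.corrcoef(me1, me2)[0, 1]) == pytest.approx(1.0)

    def test_recovers_latent_factor(self):
        rng = np.random.default_rng(9)
        f = rng.normal(0, 1, 14)
        X = pd.DataFrame([0.9 * f + rng.normal(0, 0.44, 14) for _ in range(40)])
        me = module_eigengene(X, np.ones(40, dtype=int))["ME1"].values
        assert abs(np.corrcoef(me, f)[0, 1]) > 0.95


class TestMerge:
    def _correlated_modules(self, rng, cors, size=20, n_samples=30):
        f0 = rng.normal(0, 1, n_samples)
        rows, labels = [], []
        for m, c in enumerate(cors, start=1):
            f = c * f0 + np.sqrt(max(1 - c * c, 0)) * rng.normal(0, 1, n_samples)
            for _ in range(size):
                rows.append(2.0 * f + rng.normal(0, 0.3, n_samples))
                labels.append(m)
        return pd.DataFrame(rows), np.array(labels)

    def test_similar_modules_merge(self):
        rng = np.random.default_rng(10)
        X, labels = self._correlated_modules(rng, [1.0, 0.95])
        merged = merge_modules(X, labels, threshold=0.5)
        assert len(set(merged) - {0}) == 1

    def test_dissimilar_modules_kept(self):
        rng = np.random.default_rng(12)
        X, labels = self._correlated_modules(rng, [1.0, 0.1])
        merged = merge_modules(X, labels, threshold=0.5)
        assert len(set(merged) - {0}) == 2

    def test_three_similar_modules_collapse_to_one(self):
        rng = np.random.default_rng(13)
        X, labels = self._correlated_modules(rng, [1.0, 0.9, 0.92])
        merged = merge_modules(X, labels, threshold=0.5)
        assert len(set(merged) - {0}) == 1

    def test_idempotent_at_fixed_point(self):
        rng = np.random.default_rng(14)
        X, labels = self._correlated_modules(rng, [1.0, 0.1])
        once = merge_modules(X, labels, threshold=0.5)
        assert np.array_equal(merge_modules(X, once, threshold=0.5), once)

    def test_no_residual_pair_above_merge_threshold(self):
        rng = np.random.default_rng(15)
        X, labels = self._correlated_modules(rng, [1.0, 0.6, 0.1, -0.5])
        merged = merge_modules(X, labels, threshold=0.5)
        if len(set(merged) - {0}) >= 2:
            me = module_eigengene(X, merged)
            cor = np.corrcoef(me.values.T)
            np.fill_diagonal(cor, 0.0)
            assert cor.max() <= 1 - 0.5 + 1e-9


class TestTraitsAndKME:
    def test_me_identical_to_trait_gives_r_one(self):
        me = pd.DataFrame({"ME1": [1, 0, 1, 0, 1, 0.0]})
        traits = pd.DataFrame({"t": [1, 0, 1, 0, 1, 0.0]})
        R, P = module_trait_correlation(me, traits)
        assert R.loc["ME1", "t"] == pytest.approx(1.0)

    def test_orthogonal_trait_r_zero(self):
        me = pd.DataFrame({"ME1": [1, -1, 1, -1.0]})
        traits = pd.DataFrame({"t": [1, 1, -1, -1.0]})
        R, P = module_trait_correlation(me, traits)
        assert R.loc["ME1", "t"] == pytest.approx(0.0, abs=1e-12)
        assert P.loc["ME1", "t"] == pytest.approx(1.0)

    def test_constant_trait_flagged(self):
        me = pd.DataFrame({"ME1": [1, 2, 3, 4.0]})
        R, P = module_trait_correlation(me, pd.DataFrame({"t": [1, 1, 1, 1.0]}))
        assert np.isnan(R.loc["ME1", "t"])

    def test_kme_one_for_eigengene_identical_profile(self):
        rng = np.random.default_rng(16)
        X, _ = _planted_expression(rng, [10])
        labels = np.ones(10, dtype=int)
        me = module_eigengene(X, labels)
        X2 = pd.concat([X, pd.DataFrame([me["ME1"].values], index=["proxy"])])
        labels2 = np.append(labels, 1)
        kme, hubs = kme_and_hubs(X2, me, labels2)
        assert kme.loc["proxy", "ME1"] == pytest.approx(1.0)
        assert hubs[1] == "proxy"
        assert kme.values.min() >= -1 - 1e-9 and kme.values.max() <= 1 + 1e-9

    def test_anticorrelated_gene_negative_kme(self):
        rng = np.random.default_rng(17)
        X, _ = _planted_expression(rng, [10])
        me = module_eigengene(X, np.ones(10, dtype=int))
        X2 = pd.concat([X, pd.DataFrame([-me["ME1"].values], index=["anti"])])
        kme, _ = kme_and_hubs(X2, me, np.append(np.ones(10, dtype=int), 0))
        assert kme.loc["anti", "ME1"] < 0

    def test_highest_loading_gene_is_hub(self):
        rng = np.random.default_rng(18)
        f = rng.normal(0, 1, 20)
        rows = {f"g{k}": 0.7 * f + rng.normal(0, 0.7, 20) for k in range(15)}
        rows["star"] = 0.99 * f + rng.normal(0, 0.05, 20)
        X = pd.DataFrame(rows).T
        labels = np.ones(len(X), dtype=int)
        me = module_eigengene(X, labels)
        _, hubs = kme_and_hubs(X, me, labels)
        assert hubs[1] == "star"

    def test_gene_significance_examples(self):
        trait = [1, 1, 0, 0, 1, 0.0]
        X = pd.DataFrame({"prop": [2, 2, 0, 0, 2, 0.0],
                          "flat": [1, 1, 1, 1, 1, 1.0]}).T
        gs = gene_significance(X, trait)
        assert gs["prop"] == pytest.approx(1.0)
        assert np.isnan(gs["flat"])
        with pytest.raises(ValidationError):
            gene_significance(X, [1, 1, 1, 1, 1, 1])


class TestRunNetworkFixture:
    def test_planted_modules_and_trait_links(self, full_fixture):
        fx, expr = full_fixture
        res = nw.run_network(expr)
        genes = list(res.labels.index)
        mod_genes = [g for g in genes if fx.truth.module.get(g, 0) > 0]
        ari = adjusted_rand_score([fx.truth.module[g] for g in mod_genes],
                                  res.labels.loc[mod_genes].values)
        assert ari >= 0.9
        # the venom-driven planted module's ME is the best venom correlate
        r_venom = res.module_trait_r["venom_gland"]
        best_me = r_venom.idxmax()
        venom_genes = [g for g, m in fx.truth.module.items() if m == 2]
        dominant = res.labels.loc[[g for g in venom_genes if g in res.labels.index]]
        assert f"ME{int(dominant.mode()[0])}" == best_me

    def test_every_assigned_module_meets_min_size(self, full_fixture):
        _, expr = full_fixture
        res = nw.run_network(expr)
        assert all(c >= 30 for c in res.module_sizes.values())
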