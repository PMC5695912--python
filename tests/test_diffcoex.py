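"""Differential co-expression: adjacency, TOM, modules, permutation filters."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from diffconet import (
    CorrelationPair,
    ModuleSpec,
    SyntheticConfig,
    build_module_graph,
    cluster_modules,
    differential_adjacency,
    dispersion_significance,
    filter_gene_pairs,
    generate_paired_expression,
    module_dispersion,
    pairwise_correlation,
    topological_overlap,
)
from diffconet.diffcoex import DispersionResult, ModulePartition
from conftest import make_eset, tom_triple_loop


def corr_pair(c1, c2):
    return CorrelationPair(np.asarray(c1, float), np.asarray(c2, float))


def sym_corr(off_diag: float) -> np.ndarray:
    c = np.array([[1.0, off_diag], [off_diag, 1.0]])
    return c


class TestPairwiseCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        values = np.zeros((3, 6))
        values[0, ::2] = x          # gene0 pre
        values[1, ::2] = 2 * x      # gene1 pre = 2x
        values[2, ::2] = -x         # gene2 pre = -x
        values[:, 1::2] = np.random.default_rng(0).standard_normal((3, 3))
        eset = make_eset(values)
        c = pairwise_correlation(eset, "pre")
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(42)
        m = rng.standard_normal((4, 10))
        eset = make_eset(m)
        c = pairwise_correlation(eset, "pre")
        pre = m[:, ::2]
        for i in range(4):
            for j in range(4):
                xi, xj = pre[i], pre[j]
                cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                r = cov / (xi.std() * xj.std())
                assert abs(c[i, j] - r) < 1e-10

    def test_zero_variance_gene_named(self):
        values = np.ones((2, 6))
        values[1] = np.random.default_rng(0).standard_normal(6)
        eset = make_eset(values, gene_ids=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pairwise_correlation(eset, "pre")

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((3, 12))
        eset = make_eset(m)
        c = pairwise_correlation(eset, "pre", method="spearman")
        from scipy.stats import spearmanr

        expected = spearmanr(m[:, ::2], axis=1).statistic
        np.testing.assert_allclose(c, expected, atol=1e-12)


class TestDifferentialAdjacency:
    def test_identical_conditions_zero(self):
        c = sym_corr(0.7)
        a = differential_adjacency(corr_pair(c, c), beta=6)
        np.testing.assert_array_equal(a, 0.0)

    def test_full_sign_flip_unit(self):
        a = differential_adjacency(corr_pair(sym_corr(1.0), sym_corr(-1.0)), beta=1)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 0] == 0.0

    def test_half_change_squared(self):
        a = differential_adjacency(corr_pair(sym_corr(0.8), sym_corr(0.0)), beta=2)
        assert a[0, 1] == pytest.approx(0.16)

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError, match="beta"):
            differential_adjacency(corr_pair(sym_corr(0.5), sym_corr(0.0)), beta=0)


class TestTopologicalOverlap:
    def test_fully_connected_unit(self):
        a = np.ones((3, 3)) - np.eye(3)
        t = topological_overlap(a)
        np.testing.assert_allclose(t, 1.0)

    def test_isolated_gene_zero_overlap(self):
        a = np.array([[0.0, 0.9, 0.0], [0.9, 0.0, 0.0], [0.0, 0.0, 0.0]])
        t = topological_overlap(a)
        assert t[0, 2] == 0.0 and t[1, 2] == 0.0
        assert t[2, 2] == 1.0

    def test_matches_triple_loop_oracle_6x6(self):
        rng = np.random.default_rng(3)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(topological_overlap(a), tom_triple_loop(a), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        t = topological_overlap(a)
        assert ((t >= 0) & (t <= 1)).all()
        np.testing.assert_allclose(t, t.T, atol=1e-14)


class TestClusterModules:
    def test_two_clean_blocks_exact(self):
        n = 40
        tom = np.zeros((n, n))
        tom[:20, :20] = 0.9
        tom[20:, 20:] = 0.9
        np.fill_diagonal(tom, 1.0)
        part = cluster_modules(tom, [f"g{i}" for i in range(n)], min_module_size=10)
        assert len(part.module_ids) == 2
        assert len(set(part.labels[:20])) == 1
        assert len(set(part.labels[20:])) == 1
        assert part.labels[0] != part.labels[20]

    def test_all_zero_tom_all_unassigned(self):
        tom = np.eye(15)
        part = cluster_modules(tom, [f"g{i}" for i in range(15)], min_module_size=5)
        assert part.module_ids == []
        assert (part.labels == 0).all()

    def test_planted_modules_recovered(self):
        cfg = SyntheticConfig(n_genes=300, n_subjects=40, seed=11)
        eset, truth = generate_paired_expression(cfg)
        cp = CorrelationPair.from_expression(eset)
        a = differential_adjacency(cp, beta=6)
        part = cluster_modules(topological_overlap(a), eset.gene_ids)
        ari = adjusted_rand_score(truth.module_labels(eset.gene_ids), part.labels)
        assert ari >= 0.8

    def test_labels_ordered_by_size(self):
        n = 35
        tom = np.zeros((n, n))
        tom[:10, :10] = 0.9   # smaller block first in gene order
        tom[10:30, 10:30] = 0.9
        np.fill_diagonal(tom, 1.0)
        part = cluster_modules(tom, [f"g{i}" for i in range(n)], min_module_size=5)
        sizes = part.module_sizes()
        assert sizes[1] == 20 and sizes[2] == 10

    def test_fewer_genes_than_min_size_warns(self):
        with pytest.warns(UserWarning, match="min_module_size"):
            part = cluster_modules(np.eye(3), ["a", "b", "c"], min_module_size=10)
        assert (part.labels == 0).all()


class TestFilterGenePairs:
    def test_identical_conditions_all_removed(self):
        rng = np.random.default_rng(0)
        pre = rng.standard_normal((20, 10))
        values = np.empty((20, 20))
        values[:, ::2] = pre
        values[:, 1::2] = pre  # post identical to pre
        eset = make_eset(values)
        part = ModulePartition(eset.gene_ids, np.repeat([1, 2], 10), min_module_size=5)
        res = filter_gene_pairs(eset, part, n_perm=99, seed=1)
        assert (res.table["p"] == 1.0).all()
        assert not res.table["retained"].any()
        assert res.filtered_partition.module_ids == []

    def test_planted_flip_pair_attains_min_p(self):
        cfg = SyntheticConfig(
            n_genes=40, n_subjects=50,
            modules=[ModuleSpec(size=2, within_corr_pre=0.9, within_corr_post=-0.9)],
            hub_gene_neighbors_pre=0, hub_gene_neighbors_post=0, seed=21,
        )
        eset, _ = generate_paired_expression(cfg)
        part = ModulePartition(eset.gene_ids,
                               np.array([1, 1] + [0] * 38), min_module_size=2)
        res = filter_gene_pairs(eset, part, n_perm=999, seed=2)
        assert res.table.loc[0, "p"] == pytest.approx(1 / 1000)
        assert res.table.loc[0, "retained"]

    def test_monotone_in_planted_rewiring(self):
        # growing |delta corr| of the planted pair, same seed: p never increases
        pvals = []
        for rho in (0.2, 0.5, 0.8):
            cfg = SyntheticConfig(
                n_genes=30, n_subjects=40,
                modules=[ModuleSpec(size=2, within_corr_pre=rho, within_corr_post=-rho)],
                hub_gene_neighbors_pre=0, hub_gene_neighbors_post=0, seed=33,
            )
            eset, _ = generate_paired_expression(cfg)
            part = ModulePartition(eset.gene_ids,
                                   np.array([1, 1] + [0] * 28), min_module_size=2)
            res = filter_gene_pairs(eset, part, n_perm=199, seed=3)
            pvals.append(res.table.loc[0, "p"])
        assert pvals[0] >= pvals[1] >= pvals[2]

    def test_small_n_perm_warns(self, small_synthetic):
        _, eset, _ = small_synthetic
        part = ModulePartition(eset.gene_ids,
                               np.array([1] * 10 + [0] * (eset.n_genes - 10)),
                               min_module_size=5)
        with pytest.warns(UserWarning, match="resolution"):
            filter_gene_pairs(eset, part, n_perm=49, seed=0)


class TestModuleDispersion:
    def test_identical_conditions_zero(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.5
        d = module_dispersion(corr_pair_4(c), np.array([0, 1]), np.array([2, 3]))
        assert d == 0.0

    def test_single_cross_pair(self):
        c1, c2 = np.eye(2), np.eye(2)
        c1[0, 1] = c1[1, 0] = 0.8
        d = module_dispersion(CorrelationPair(c1, c2), np.array([0]), np.array([1]))
        assert d == pytest.approx(0.4)

    def test_two_pair_hand_value(self):
        # half-differences 0.3 and 0.4 -> sqrt((0.09 + 0.16)/2)
        c1 = np.eye(3)
        c2 = np.eye(3)
        c1[0, 1] = c1[1, 0] = 0.6   # half-diff 0.3 vs 0
        c1[0, 2] = c1[2, 0] = 0.8   # half-diff 0.4 vs 0
        d = module_dispersion(CorrelationPair(c1, c2), np.array([0]), np.array([1, 2]))
        assert d == pytest.approx(np.sqrt((0.09 + 0.16) / 2))

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        c1 = random_corr(rng, 6)
        c2 = random_corr(rng, 6)
        cp = CorrelationPair(c1, c2)
        a, b = np.array([0, 1, 2]), np.array([3, 4])
        assert module_dispersion(cp, a, b) == module_dispersion(cp, b, a)

    def test_singleton_within_module_rejected(self):
        cp = CorrelationPair(np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="2 genes"):
            module_dispersion(cp, np.array([0]), np.array([0]))


def corr_pair_4(c):
    return CorrelationPair(c.copy(), c.copy())


def random_corr(rng, n):
    m = rng.standard_normal((n, n + 5))
    c = np.corrcoef(m)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2


class TestDispersionSignificance:
    def test_identical_conditions_no_edges(self):
        rng = np.random.default_rng(0)
        pre = rng.standard_normal((30, 10))
        values = np.empty((30, 20))
        values[:, ::2] = pre
        values[:, 1::2] = pre
        eset = make_eset(values)
        part = ModulePartition(eset.gene_ids, np.repeat([1, 2, 3], 10), min_module_size=5)
        results = dispersion_significance(eset, part, n_random=100, seed=1)
        assert all(r.d == 0.0 for r in results)
        assert not any(r.significant for r in results)

    def test_co_rewired_modules_linked_at_min_p(self):
        mods = [ModuleSpec(group=1), ModuleSpec(group=1), ModuleSpec(), ModuleSpec()]
        cfg = SyntheticConfig(n_genes=300, n_subjects=40, modules=mods,
                              hub_gene_neighbors_pre=0, hub_gene_neighbors_post=0,
                              seed=2)
        eset, truth = generate_paired_expression(cfg)
        part = ModulePartition(eset.gene_ids, truth.module_labels(eset.gene_ids))
        results = dispersion_significance(eset, part, n_random=200, seed=1)
        cross = {(r.module_a, r.module_b): r for r in results if r.module_a != r.module_b}
        linked = cross[(1, 2)]
        min_p = min(r.p for r in cross.values())
        assert linked.p == min_p
        assert linked.significant
        # independent module pairs stay unlinked
        assert not cross[(3, 4)].significant

    def test_graph_assembly(self):
        part = ModulePartition([f"g{i}" for i in range(9)],
                               np.repeat([1, 2, 3], 3), min_module_size=2)
        results = [
            DispersionResult(1, 2, 0.5, 0.001, 0.01, True),
            DispersionResult(1, 3, 0.4, 0.002, 0.02, True),
            DispersionResult(2, 3, 0.1, 0.9, 0.9, False),
            DispersionResult(1, 1, 0.6, 0.001, 0.01, True),
        ]
        g = build_module_graph(part, results)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g.nodes[1]["size"] == 3
        assert g.nodes[1]["within_d"] == 0.6

    def test_edgeless_graph_keeps_nodes(self):
        part = ModulePartition(["a", "b", "c", "d"], np.array([1, 1, 2, 2]),
                               min_module_size=2)
        g = build_module_graph(part, [DispersionResult(1, 2, 0.1, 0.5, 0.5, False)])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0
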