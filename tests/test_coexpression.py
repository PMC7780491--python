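"""Network construction: brute-force oracles and planted-structure recovery."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from migmod.coexpression import (
    GREY,
    ModuleAssignment,
    adjacency_matrix,
    consensus_tom,
    detect_modules,
    pick_soft_threshold,
    select_top_connected,
    tom_dissimilarity,
)
from migmod.io_formats import ExpressionMatrix
from migmod.synthetic import simulate_modular_expression


def brute_force_tom_dissimilarity(adj):
    """Triple-loop reference for the topological overlap dissimilarity."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            denom = min(k_i, k_j) + 1.0 - a[i, j]
            d[i, j] = 1.0 if denom <= 0 else 1.0 - (l_ij + a[i, j]) / denom
    return d


def random_adjacency(n, rng):
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def make_expression(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestSelectTopConnected:
    def test_identity_when_k_equals_n(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.standard_normal((5, 10)))
        out = select_top_connected(expr, 5)
        assert out.gene_ids == expr.gene_ids
        np.testing.assert_array_equal(out.values, expr.values)

    def test_duplicated_genes_outrank_noise(self):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(30)
        values = np.vstack(
            [shared, shared + 1e-9 * rng.standard_normal(30), rng.standard_normal(30)]
        )
        expr = make_expression(values)
        out = select_top_connected(expr, 2)
        # brute-force connectivity agrees: the duplicate pair wins
        cor = np.abs(np.corrcoef(values))
        conn = cor.sum(axis=1) - 1.0
        assert set(out.gene_ids) == {"g0", "g1"}
        assert np.argsort(-conn)[:2].tolist() in ([0, 1], [1, 0])

    def test_order_preserved_among_survivors(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.standard_normal((6, 20)))
        out = select_top_connected(expr, 4)
        original_order = [g for g in expr.gene_ids if g in set(out.gene_ids)]
        assert out.gene_ids == original_order

    def test_zero_variance_gene_warns(self):
        values = np.vstack([np.ones(10), np.random.default_rng(3).standard_normal((2, 10))])
        with pytest.warns(UserWarning, match="zero-variance"):
            select_top_connected(make_expression(values), 2)


class TestAdjacency:
    def test_identical_genes_beta_one(self):
        shared = np.random.default_rng(4).standard_normal(15)
        expr = make_expression(np.vstack([shared, shared]))
        adj = adjacency_matrix(expr, 1)
        assert adj[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_squared(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        # construct y with exact cor(x, y) = -0.5
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        zc = z - z.mean() - xc * (xc @ (z - z.mean()))
        zc /= np.linalg.norm(zc)
        y = -0.5 * xc + np.sqrt(1 - 0.25) * zc
        expr = make_expression(np.vstack([x, y]))
        adj = adjacency_matrix(expr, 2)
        assert adj[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((6, 20))
        adj = adjacency_matrix(make_expression(values), 3)
        for i in range(6):
            for j in range(6):
                expected = 1.0 if i == j else abs(np.corrcoef(values[i], values[j])[0, 1]) ** 3
                assert adj[i, j] == pytest.approx(expected, abs=1e-12)


class TestTomDissimilarity:
    def test_complete_graph_zero_dissimilarity(self):
        adj = np.ones((3, 3))
        np.testing.assert_allclose(tom_dissimilarity(adj), np.zeros((3, 3)), atol=1e-12)

    def test_empty_graph_unit_dissimilarity(self):
        adj = np.eye(4)
        d = tom_dissimilarity(adj)
        off = d[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        adj = random_adjacency(8, rng)
        np.testing.assert_allclose(
            tom_dissimilarity(adj), brute_force_tom_dissimilarity(adj), atol=1e-12
        )

    def test_entries_bounded_and_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = tom_dissimilarity(random_adjacency(12, rng))
            assert d.min() >= 0 and d.max() <= 1
            np.testing.assert_allclose(d, d.T, atol=1e-12)


class TestSoftThreshold:
    def test_planted_modules_reach_target(self, planted_expression, soft_threshold_fit):
        fit = soft_threshold_fit
        chosen = fit.fit_table[fit.fit_table["power"] == fit.chosen_power]
        assert fit.target_reached
        assert chosen["signed_r2"].iloc[0] >= 0.8

    def test_chosen_is_smallest_reaching_target(self, soft_threshold_fit):
        table = soft_threshold_fit.fit_table
        reaching = table[table["signed_r2"] >= 0.8]["power"]
        assert soft_threshold_fit.chosen_power == reaching.min()

    def test_mean_connectivity_strictly_decreasing(self, soft_threshold_fit):
        mc = soft_threshold_fit.fit_table["mean_connectivity"].to_numpy()
        assert (np.diff(mc) < 0).all()

    def test_identical_profiles_degenerate(self):
        shared = np.random.default_rng(8).standard_normal(20)
        expr = make_expression(np.vstack([shared] * 5))
        with pytest.raises(ValueError, match="degenerate"):
            pick_soft_threshold(expr, [2, 4])


class TestConsensusTom:
    def test_no_leave_out_equals_full_tom(self):
        expr, _ = simulate_modular_expression(10, [5], 30, 0.6, seed=10)
        net = consensus_tom(expr, beta=4, n_resamples=7, leave_out_fraction=0.0, seed=1)
        full = tom_dissimilarity(adjacency_matrix(expr, 4))
        np.testing.assert_array_equal(net.consensus_dissimilarity, full)

    def test_equals_mean_of_recomputed_resamples(self):
        expr, _ = simulate_modular_expression(0, [5], 20, 0.6, seed=11)
        seed = 33
        net = consensus_tom(expr, beta=2, n_resamples=3, leave_out_fraction=0.1, seed=seed)
        # independently replay the resampling stream
        rng = np.random.default_rng(seed)
        n_keep = int(np.ceil(0.9 * expr.n_samples))
        toms = []
        for _ in range(3):
            subset = np.sort(rng.choice(expr.n_samples, size=n_keep, replace=False))
            sub = expr.subset_samples(subset)
            toms.append(tom_dissimilarity(adjacency_matrix(sub, 2)))
        expected = np.mean(toms, axis=0)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(net.consensus_dissimilarity, expected, atol=1e-12)

    def test_consensus_within_resample_envelope(self):
        expr, _ = simulate_modular_expression(5, [5], 25, 0.6, seed=12)
        seed = 44
        net = consensus_tom(expr, beta=3, n_resamples=5, leave_out_fraction=0.2, seed=seed)
        rng = np.random.default_rng(seed)
        n_keep = int(np.ceil(0.8 * expr.n_samples))
        toms = [
            tom_dissimilarity(
                adjacency_matrix(
                    expr.subset_samples(
                        np.sort(rng.choice(expr.n_samples, size=n_keep, replace=False))
                    ),
                    3,
                )
            )
            for _ in range(5)
        ]
        lo, hi = np.min(toms, axis=0), np.max(toms, axis=0)
        assert (net.consensus_dissimilarity >= lo - 1e-12).all()
        assert (net.consensus_dissimilarity <= hi + 1e-12).all()

    def test_bit_reproducible(self):
        expr, _ = simulate_modular_expression(5, [5], 25, 0.6, seed=13)
        a = consensus_tom(expr, 3, 4, 0.2, seed=9)
        b = consensus_tom(expr, 3, 4, 0.2, seed=9)
        np.testing.assert_array_equal(a.consensus_dissimilarity, b.consensus_dissimilarity)

    def test_excessive_leave_out_rejected(self):
        expr, _ = simulate_modular_expression(5, [5], 10, 0.6, seed=14)
        with pytest.raises(ValueError, match="leave"):
            consensus_tom(expr, 3, 4, leave_out_fraction=0.9, seed=0)


class TestDetectModules:
    def test_planted_recovery(self, planted_expression, recovery_network, recovery_modules):
        _, truth = planted_expression
        genes = recovery_network.gene_ids
        ari = adjusted_rand_score(
            [truth.true_module_labels[g] for g in genes],
            [recovery_modules.labels[g] for g in genes],
        )
        assert ari >= 0.8

    def test_small_cluster_goes_grey(self):
        # a planted 29-gene block below the 30-gene minimum is unassigned
        expr, truth = simulate_modular_expression(100, [29, 50], 100, 0.8, seed=15)
        net = consensus_tom(expr, beta=6, n_resamples=20, leave_out_fraction=0.1, seed=1)
        modules = detect_modules(net, min_module_size=30)
        small_block = [g for g, b in truth.true_module_labels.items() if b == "block1"]
        assert all(modules.labels[g] == GREY for g in small_block)

    def test_turquoise_is_largest(self, recovery_modules):
        sizes = recovery_modules.module_sizes()
        non_grey = {m: s for m, s in sizes.items() if m != GREY}
        assert non_grey["turquoise"] == max(non_grey.values())

    def test_gene_order_invariance(self):
        expr, truth = simulate_modular_expression(60, [40, 35], 80, 0.7, seed=16)
        net = consensus_tom(expr, beta=6, n_resamples=10, leave_out_fraction=0.1, seed=2)
        modules = detect_modules(net)
        rng = np.random.default_rng(17)
        perm = rng.permutation(expr.n_genes)
        expr_p = ExpressionMatrix(
            gene_ids=[expr.gene_ids[i] for i in perm],
            sample_ids=list(expr.sample_ids),
            values=expr.values[perm],
        )
        net_p = consensus_tom(expr_p, beta=6, n_resamples=10, leave_out_fraction=0.1, seed=2)
        modules_p = detect_modules(net_p)
        genes = expr.gene_ids
        ari = adjusted_rand_score(
            [modules.labels[g] for g in genes], [modules_p.labels[g] for g in genes]
        )
        assert ari == pytest.approx(1.0)

    def test_within_module_overlap_exceeds_between(self, recovery_network, recovery_modules):
        similarity = 1.0 - recovery_network.consensus_dissimilarity
        gene_index = {g: i for i, g in enumerate(recovery_network.gene_ids)}
        for module in recovery_modules.module_names():
            idx = np.array([gene_index[g] for g in recovery_modules.genes_in(module)])
            other = np.array(
                [i for g, i in gene_index.items() if recovery_modules.labels[g] != module]
            )
            within = similarity[np.ix_(idx, idx)]
            within_mean = (within.sum() - np.trace(within)) / (len(idx) * (len(idx) - 1))
            between_mean = similarity[np.ix_(idx, other)].mean()
            assert within_mean > between_mean

    def test_fewer_genes_than_min_size_all_grey(self):
        expr, _ = simulate_modular_expression(0, [10], 30, 0.7, seed=18)
        net = consensus_tom(expr, beta=3, n_resamples=5, leave_out_fraction=0.1, seed=3)
        with pytest.warns(UserWarning, match="grey"):
            modules = detect_modules(net, min_module_size=30)
        assert set(modules.labels.values()) == {GREY}
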