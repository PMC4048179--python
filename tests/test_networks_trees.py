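"""Network builders, scale-free fit, glasso, trees, overlap."""

import numpy as np
import pytest

from structmap.networks import (
    correlation_network,
    glasso_network,
    network_overlap,
    scale_free_fit,
    softpower_network,
)
from structmap.trees import hclust_tree

from .conftest import trait_matrix


class TestCorrelationNetwork:
    def test_perfect_correlation_weight_one(self, rng):
        y = rng.normal(size=50)
        t = trait_matrix(np.column_stack([y, 2 * y, rng.normal(size=50)]))
        net = correlation_network(t, threshold=0.9)
        assert net.graph.has_edge("trait0", "trait1")
        assert net.graph["trait0"]["trait1"]["weight"] == pytest.approx(1.0)

    def test_independent_traits_no_edges(self, rng):
        t = trait_matrix(rng.normal(size=(100, 5)))
        net = correlation_network(t, threshold=0.99)
        assert net.n_edges == 0

    def test_matches_all_pairs_oracle(self, rng):
        V = rng.normal(size=(30, 6))
        V[:, 3] = V[:, 0] * 0.9 + rng.normal(size=30) * 0.2
        t = trait_matrix(V)
        thr = 0.4
        net = correlation_network(t, threshold=thr)
        R = np.corrcoef(V, rowvar=False)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = abs(R[i, j]) >= thr
                assert net.graph.has_edge(f"trait{i}", f"trait{j}") == expect
                if expect:
                    w = net.graph[f"trait{i}"][f"trait{j}"]["weight"]
                    assert w == pytest.approx(abs(R[i, j]))

    def test_zero_variance_trait_excluded_with_warning(self, rng):
        V = rng.normal(size=(20, 3))
        V[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            net = correlation_network(trait_matrix(V), threshold=0.1)
        assert "trait1" not in net.nodes


class TestSoftpower:
    def test_beta_one_equals_correlation_threshold_zero(self, rng):
        V = rng.normal(size=(40, 5))
        t = trait_matrix(V)
        net = softpower_network(t, beta_grid=[1], r2_target=0.0, min_weight=0.0)
        assert net.params["beta"] == 1
        R = np.abs(np.corrcoef(V, rowvar=False))
        for i in range(5):
            for j in range(i + 1, 5):
                w = net.graph[f"trait{i}"][f"trait{j}"]["weight"]
                assert w == pytest.approx(R[i, j])

    def test_equal_correlations_closed_form(self, rng):
        # three traits sharing one factor: all |r| roughly equal c, a_ij = c^beta
        f = rng.normal(size=300)
        V = np.column_stack([f + rng.normal(size=300) for _ in range(3)])
        t = trait_matrix(V)
        with pytest.warns(UserWarning):
            net = softpower_network(t, beta_grid=[3], r2_target=1.01)
        R = np.abs(np.corrcoef(V, rowvar=False))
        for i in range(3):
            for j in range(i + 1, 3):
                w = net.graph[f"trait{i}"][f"trait{j}"]["weight"]
                assert w == pytest.approx(R[i, j] ** 3)

    def test_chosen_beta_r2_matches_independent_fit(self, rng):
        # modular data: 3 blocks of correlated traits
        blocks = []
        for _ in range(3):
            f = rng.normal(size=120)
            blocks.append(np.column_stack([f + 0.5 * rng.normal(size=120)
                                           for _ in range(4)]))
        t = trait_matrix(np.hstack(blocks))
        net = softpower_network(t, beta_grid=range(1, 13), r2_target=0.8)
        beta = net.params["beta"]
        R = np.abs(np.corrcoef(t.values, rowvar=False))
        A = R**beta
        np.fill_diagonal(A, 0)
        # independent recomputation of the log-log degree fit
        assert net.params["r2"] == pytest.approx(scale_free_fit(A), abs=1e-12)


class TestGlasso:
    def test_diagonal_truth_large_rho_empty(self, rng):
        t = trait_matrix(rng.normal(size=(60, 4)))
        net = glasso_network(t, rho=0.9)
        assert net.n_edges == 0

    def test_two_traits_closed_form_pattern(self, rng):
        # analytic 2x2: glasso keeps the edge iff |r| > rho
        f = rng.normal(size=200)
        V = np.column_stack([f + 0.4 * rng.normal(size=200),
                             f + 0.4 * rng.normal(size=200)])
        t = trait_matrix(V)
        r = abs(np.corrcoef(V, rowvar=False)[0, 1])
        assert glasso_network(t, rho=0.95 * r).n_edges == 1
        assert glasso_network(t, rho=1.05 * r).n_edges == 0

    def test_kkt_stationarity(self, rng):
        from sklearn.covariance import graphical_lasso

        V = rng.normal(size=(80, 5))
        V[:, 1] += V[:, 0]
        t = trait_matrix(V)
        rho = 0.2
        glasso_network(t, rho=rho)  # builds without error
        R = np.corrcoef(V, rowvar=False)
        cov, prec = graphical_lasso(R, alpha=rho, tol=1e-10, max_iter=1000)
        # KKT of the penalized likelihood: |S - W| <= rho off-diagonal,
        # equality with sign at non-zeros
        G = R - cov
        off = ~np.eye(5, dtype=bool)
        nz = (np.abs(prec) > 1e-8) & off
        assert np.all(np.abs(G[off]) <= rho + 1e-4)
        assert np.allclose(G[nz], -rho * np.sign(prec[nz]), atol=1e-4)

    def test_rho_zero_rejected(self, rng):
        t = trait_matrix(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            glasso_network(t, rho=0.0)


class TestHclustTree:
    def test_identical_traits_merge_at_zero(self, rng):
        y = rng.normal(size=30)
        t = trait_matrix(np.column_stack([y, y, rng.normal(size=30)]))
        tree = hclust_tree(t)
        first = min(tree.internal_nodes(), key=lambda v: v.height)
        assert first.members == {"trait0", "trait1"}
        assert first.height == pytest.approx(0.0, abs=1e-12)

    def test_three_leaf_merge_order_hand_computed(self):
        # dissimilarities: d(0,1)=0.1, d(0,2)=0.8, d(1,2)=0.9
        # average linkage merges {0,1} first, then at (0.8+0.9)/2
        from structmap.networks import TraitNetwork
        net = TraitNetwork.from_edges(
            ["a", "b", "c"],
            [("a", "b", 0.9), ("a", "c", 0.2), ("b", "c", 0.1)],
        )
        tree = hclust_tree(net)
        internals = sorted(tree.internal_nodes(), key=lambda v: v.height)
        assert internals[0].members == {"a", "b"}
        assert internals[0].height == pytest.approx(0.1)
        assert internals[1].height == pytest.approx((0.8 + 0.9) / 2)

    def test_leaves_equal_trait_set(self, rng):
        t = trait_matrix(rng.normal(size=(20, 7)))
        tree = hclust_tree(t)
        leaves = {tid for leaf in tree.leaves() for tid in leaf.members}
        assert leaves == set(t.trait_ids)
        assert tree.root.members == frozenset(t.trait_ids)

    def test_newick_round_trip_preserves_structure(self, rng):
        from structmap.trees import TraitTree

        t = trait_matrix(rng.normal(size=(15, 4)))
        tree = hclust_tree(t)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        again = TraitTree.from_newick(nwk)
        assert again.root.members == tree.root.members
        assert sorted(round(v.weight, 6) for v in again.internal_nodes()) == \
            sorted(round(v.weight, 6) for v in tree.internal_nodes())


class TestNetworkOverlap:
    def test_identical_networks_100_percent(self, rng):
        t = trait_matrix(rng.normal(size=(30, 5)))
        net = correlation_network(t, threshold=0.1)
        out = network_overlap(net, net)
        assert out == {"pct_shared_nodes": 100.0, "pct_shared_edges": 100.0}

    def test_disjoint_edges_zero_percent(self):
        from structmap.networks import TraitNetwork
        a = TraitNetwork.from_edges(["x", "y", "z"], [("x", "y", 0.5)])
        b = TraitNetwork.from_edges(["x", "y", "z"], [("y", "z", 0.5)])
        assert network_overlap(a, b)["pct_shared_edges"] == 0.0

    def test_matches_set_intersection_oracle(self, rng):
        from structmap.networks import TraitNetwork
        nodes = [f"t{i}" for i in range(8)]
        for _ in range(5):
            def rand_edges():
                out = set()
                while len(out) < 6:
                    i, j = rng.choice(8, size=2, replace=False)
                    out.add((min(i, j), max(i, j)))
                return [(f"t{i}", f"t{j}", 0.5) for i, j in out]

            ea, eb = rand_edges(), rand_edges()
            a = TraitNetwork.from_edges(nodes, ea)
            b = TraitNetwork.from_edges(nodes, eb)
            sa = {frozenset((u, v)) for u, v, _ in ea}
            sb = {frozenset((u, v)) for u, v, _ in eb}
            expect = 100.0 * len(sa & sb) / len(sa)
            assert network_overlap(a, b)["pct_shared_edges"] == pytest.approx(expect)
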