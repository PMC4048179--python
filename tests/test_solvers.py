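"""Solver correctness: reductions, KKT, traces, oracle agreement on one
representative instance per model (the 20-instance sweeps live in the
acceptance tests)."""

import numpy as np
import pytest

import structmap as sm
from structmap.preprocess import standardize
from structmap.solvers import (
    fit_gflasso,
    fit_gflasso_spg,
    fit_ggflasso,
    fit_group_lasso,
    fit_lasso,
    fit_mpgl,
    fit_struct_io,
    fit_treelasso,
    kkt_residual_group,
    kkt_residual_lasso,
    kkt_residual_mpgl,
    lam_max,
)
from structmap.networks import TraitNetwork
from structmap.trees import TraitTree, TreeNode

from . import _convex_oracle as oracle
from .conftest import random_regression, trait_matrix


def chain_net(K, weights=(0.9, 0.8, 0.7)):
    ids = [f"trait{i}" for i in range(K)]
    edges = [(ids[i], ids[i + 1], weights[i % len(weights)]) for i in range(K - 1)]
    return TraitNetwork.from_edges(ids, edges), ids


class TestLasso:
    def test_zero_penalty_recovers_least_squares(self, small_xy):
        X, Y = small_xy
        res = fit_lasso(X, Y, 0.0, tol=1e-14, max_iter=50_000)
        B_ls = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(res.dense(), B_ls, atol=1e-6)

    def test_full_shrinkage_bound(self, small_xy):
        X, Y = small_xy
        res = fit_lasso(X, Y, lam_max(X, Y) * 1.0001, tol=1e-10)
        assert res.B.nnz == 0

    def test_kkt_residual_small(self, small_xy):
        X, Y = small_xy
        res = fit_lasso(X, Y, 1.0, tol=1e-12)
        assert kkt_residual_lasso(X, Y, res.dense(), 1.0) < 1e-4

    def test_objective_trace_non_increasing(self, small_xy):
        X, Y = small_xy
        tr = np.asarray(fit_lasso(X, Y, 0.5, tol=1e-10).objective)
        assert (np.diff(tr) <= 1e-10).all()

    def test_non_finite_input_errors(self, small_xy):
        X, Y = small_xy
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(X, Y, 0.5)


class TestGroupLasso:
    def test_singleton_groups_equal_lasso(self, small_xy):
        X, Y = small_xy
        groups = [np.array([j]) for j in range(X.shape[1])]
        rg = fit_group_lasso(X, Y, groups, 0.8, tol=1e-10)
        rl = fit_lasso(X, Y, 0.8, tol=1e-10)
        np.testing.assert_allclose(rg.dense(), rl.dense(), atol=1e-8)

    def test_orthogonal_group_zeroed(self, rng):
        # a group orthogonal to Y is zero at any positive lambda (KKT)
        X, _ = standardize(rng.normal(size=(40, 6)))
        Q, _ = np.linalg.qr(X)
        y = Q[:, 0] * 2.0  # in the span of the first columns only
        Xo = np.column_stack([Q[:, :3] @ np.eye(3), Q[:, 3:6]])
        res = fit_group_lasso(Xo, y, [np.arange(3), np.arange(3, 6)], 0.05,
                              tol=1e-12)
        B = res.dense()
        assert np.abs(B[3:]).max() == 0.0

    def test_overlapping_groups_rejected(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError, match="overlap"):
            fit_group_lasso(X, Y, [np.arange(3), np.arange(2, 8)], 0.5)

    def test_kkt_and_trace(self, small_xy):
        X, Y = small_xy
        groups = [np.arange(0, 3), np.arange(3, 5), np.arange(5, 8)]
        res = fit_group_lasso(X, Y, groups, 1.0, tol=1e-12)
        assert kkt_residual_group(X, Y, res.dense(), groups, 1.0) < 1e-4
        tr = np.asarray(res.objective)
        assert (np.diff(tr) <= 1e-10).all()


class TestGFlasso:
    def test_gamma_zero_equals_lasso_exactly(self, small_xy):
        X, Y = small_xy
        net, _ = chain_net(Y.shape[1])
        rg = fit_gflasso(X, Y, net, 0.7, 0.0, tol=1e-10)
        rl = fit_lasso(X, Y, 0.7, tol=1e-10)
        np.testing.assert_allclose(rg.dense(), rl.dense(), atol=1e-8, rtol=0)

    def test_empty_network_warns_behaves_as_lasso(self, small_xy):
        X, Y = small_xy
        net = TraitNetwork.from_edges([f"trait{i}" for i in range(Y.shape[1])], [])
        with pytest.warns(UserWarning, match="no edges"):
            rg = fit_gflasso(X, Y, net, 0.7, 1.0)
        rl = fit_lasso(X, Y, 0.7)
        np.testing.assert_allclose(rg.dense(), rl.dense(), atol=1e-8)

    def test_duplicate_traits_fuse_under_strong_gamma(self, rng):
        X, _ = standardize(rng.normal(size=(30, 6)))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        Y = np.column_stack([y, y, rng.normal(size=30)])
        net = TraitNetwork.from_edges(
            ["trait0", "trait1", "trait2"], [("trait0", "trait1", 1.0)]
        )
        lam = 0.3
        res = fit_gflasso(X, Y, net, lam, 1e3 * lam, tol=1e-10, max_iter=5000)
        B = res.dense()
        assert np.abs(B[:, 0] - B[:, 1]).max() < 1e-5
        assert np.abs(B[:, 0]).max() > 0  # fused, not trivially zero

    def test_variational_cd_and_spg_routes_agree(self, small_xy):
        X, Y = small_xy
        net, _ = chain_net(Y.shape[1])
        a = fit_gflasso(X, Y, net, 1.0, 0.6, tol=1e-10, max_iter=5000)
        b = fit_gflasso_spg(X, Y, net, 1.0, 0.6, tol=1e-10)
        assert a.final_objective == pytest.approx(b.final_objective, rel=1e-5)

    def test_objective_trace_non_increasing(self, small_xy):
        X, Y = small_xy
        net, _ = chain_net(Y.shape[1])
        tr = np.asarray(fit_gflasso(X, Y, net, 0.8, 0.5, tol=1e-10).objective)
        assert (np.diff(tr) <= 1e-10).all()

    def test_signed_fusion_flips_with_negative_correlation(self, rng):
        X, _ = standardize(rng.normal(size=(40, 4)))
        y = X[:, 0] + 0.2 * rng.normal(size=40)
        Y = np.column_stack([y, -y])
        net = TraitNetwork.from_edges(["a", "b"], [("a", "b", 1.0, -1.0)])
        res = fit_gflasso(X, Y, net, 0.2, 200.0, signed=True, tol=1e-10,
                          max_iter=5000, col_ids=["a", "b"])
        B = res.dense()
        assert np.abs(B[:, 0] + B[:, 1]).max() < 1e-5
        assert np.abs(B[:, 0]).max() > 0


class TestTreeLasso:
    def test_star_tree_zero_internal_weight_equals_lasso(self, small_xy):
        X, Y = small_xy
        K = Y.shape[1]
        leaves = [TreeNode(id=i, members=frozenset([f"trait{i}"]), height=0.0,
                           weight=1.0) for i in range(K)]
        root = TreeNode(id=K, members=frozenset(f"trait{i}" for i in range(K)),
                        height=1.0, weight=0.0, children=leaves)
        star = TraitTree(root, leaf_ids=[f"trait{i}" for i in range(K)])
        rt = fit_treelasso(X, Y, star, 0.8, tol=1e-12)
        rl = fit_lasso(X, Y, 0.8, tol=1e-12)
        np.testing.assert_allclose(rt.dense(), rl.dense(), atol=1e-5)

    def test_correlated_traits_share_support(self, rng):
        X, _ = standardize(rng.normal(size=(40, 5)))
        y = X[:, 1] + 0.1 * rng.normal(size=40)
        Y, _ = standardize(np.column_stack([y, y + 0.05 * rng.normal(size=40)]))
        t = trait_matrix(Y)
        tree = sm.hclust_tree(t)
        res = fit_treelasso(X, Y, tree, 1.0, tol=1e-11)
        B = res.dense()
        assert ((B[:, 0] != 0) == (B[:, 1] != 0)).all()

    def test_smoothing_gap_bound(self, small_xy):
        # halving mu changes the exact objective by less than mu * D
        from structmap.solvers.spg import SmoothedPenalty
        from structmap.solvers.treelasso import _tree_terms

        X, Y = small_xy
        t = trait_matrix(Y)
        tree = sm.hclust_tree(t)
        _, groups = _tree_terms(tree, tree.leaf_ids, 1.0)
        pen = SmoothedPenalty(shape=(X.shape[1], Y.shape[1]), groups=groups)
        mu = 1e-3 / (2 * pen.D)
        a = fit_treelasso(X, Y, tree, 1.0, mu=mu, tol=1e-11)
        b = fit_treelasso(X, Y, tree, 1.0, mu=mu / 2, tol=1e-11)
        assert abs(a.final_objective - b.final_objective) <= mu * pen.D + 1e-6

    def test_single_leaf_tree_reduces_to_single_trait_lasso(self, rng):
        X, _ = standardize(rng.normal(size=(20, 4)))
        y, _ = standardize(rng.normal(size=(20, 1)))
        leaf = TreeNode(id=0, members=frozenset(["t"]), height=0.0, weight=1.0)
        tree = TraitTree(leaf, leaf_ids=["t"])
        rt = fit_treelasso(X, y, tree, 0.5, tol=1e-12, col_ids=["t"])
        rl = fit_lasso(X, y, 0.5, tol=1e-12)
        np.testing.assert_allclose(rt.dense(), rl.dense(), atol=1e-5)


class TestMPGL:
    def test_single_population_equals_lasso(self, rng):
        X, Y = random_regression(rng, n=24, J=6, K=1)
        pops = np.zeros(24, dtype=int)
        rm = fit_mpgl(X, Y[:, 0], pops, 0.6, tol=1e-10)
        rl = fit_lasso(X, Y[:, 0], 0.6, tol=1e-10)
        np.testing.assert_allclose(rm.dense().ravel(), rl.dense().ravel(),
                                   atol=1e-8)

    def test_opposite_sign_effects_recovered_where_pooled_lasso_fails(self, rng):
        hits_mpgl = 0
        hits_pooled = 0
        n_seeds = 20
        for s in range(n_seeds):
            r = np.random.default_rng(500 + s)
            n = 120
            pops = np.repeat([0, 1], n // 2)
            X = (r.random((n, 8)) < 0.4).astype(float)
            beta = np.zeros(8)
            y = np.where(pops == 0, 1.0, -1.0) * X[:, 2] * 0.8 + r.normal(size=n)
            Xs, _ = standardize(X)
            ys, _ = standardize(y[:, None])
            rm = fit_mpgl(Xs, ys[:, 0], pops, 6.0, tol=1e-8)
            if np.linalg.norm(rm.dense()[2]) > 1e-6:
                hits_mpgl += 1
            rl = fit_lasso(Xs, ys[:, 0], 6.0, tol=1e-8)
            if abs(rl.dense()[2, 0]) > 1e-6:
                hits_pooled += 1
        assert hits_mpgl >= 15
        assert hits_mpgl > hits_pooled

    def test_kkt_residual(self, rng):
        X, Y = random_regression(rng, n=30, J=6, K=1)
        pops = np.repeat([0, 1, 2], 10)
        res = fit_mpgl(X, Y[:, 0], pops, 0.8, tol=1e-12)
        assert kkt_residual_mpgl(X, Y[:, 0], res.dense(), pops, 0.8) < 1e-4

    def test_zero_variance_population_excluded(self, rng):
        X, Y = random_regression(rng, n=20, J=4, K=1)
        y = Y[:, 0].copy()
        y[10:] = 3.14
        pops = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="zero trait variance"):
            res = fit_mpgl(X, y, pops, 0.5)
        assert res.B.col_ids == ["0"]


class TestStructIO:
    def test_all_singletons_is_lasso_with_summed_weights(self, small_xy):
        X, Y = small_xy
        sg = [np.array([j]) for j in range(X.shape[1])]
        tg = [np.array([k]) for k in range(Y.shape[1])]
        rs = fit_struct_io(X, Y, sg, tg, 0.4, 0.6, tol=1e-13)
        rl = fit_lasso(X, Y, 1.0, tol=1e-13)
        assert rs.final_objective == pytest.approx(rl.final_objective, rel=1e-6)
        np.testing.assert_allclose(rs.dense(), rl.dense(), atol=1e-3)

    def test_planted_block_jointly_recovered(self, rng):
        X, _ = standardize(rng.normal(size=(200, 9)))
        B_true = np.zeros((9, 8))
        B_true[0:3, 0:4] = 1.0
        Y, _ = standardize(X @ B_true + 0.3 * rng.normal(size=(200, 8)))
        sg = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        tg = [np.arange(0, 4), np.arange(4, 8)]
        res = fit_struct_io(X, Y, sg, tg, 1.0, 15.0, tol=1e-11)
        B = res.dense()
        assert np.abs(B[0:3, 0:4]).min() > 0  # causal block active
        assert np.abs(B[3:, :]).max() == 0.0  # null SNP blocks exactly zero

    def test_overlapping_groups_rejected(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError, match="overlap"):
            fit_struct_io(X, Y, [np.arange(5), np.arange(4, 8)],
                          [np.arange(Y.shape[1])], 0.1, 0.1)


class TestAMTL:
    def test_uniform_features_reduce_to_composite_fit(self, small_xy):
        # theta fixed at 0 (single constant feature cannot move it):
        # the B-step equals the unweighted sparse-group fit
        from structmap.datatypes import SNPFeatureTable
        from structmap.solvers import fit_amtl, fit_weighted_sparse_group

        X, Y = small_xy
        J, K = X.shape[1], Y.shape[1]
        feats = SNPFeatureTable(np.ones((J, 1)), ["const"],
                                [f"snp{j}" for j in range(J)])
        res = fit_amtl(X, Y, feats, 0.6, n_outer=1, b_tol=1e-12)
        B_ref, *_ = fit_weighted_sparse_group(
            X, Y, np.ones(J), np.ones(J), [np.arange(K)], 0.6, tol=1e-12
        )
        np.testing.assert_allclose(res.dense(), B_ref, atol=1e-8)

    def test_causal_marking_feature_earns_positive_weight(self):
        from structmap.datatypes import SNPFeatureTable
        from structmap.solvers import fit_amtl

        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            r = np.random.default_rng(900 + s)
            n, J, K = 80, 10, 4
            X, _ = standardize(r.normal(size=(n, J)))
            B_true = np.zeros((J, K))
            B_true[[2, 7], :] = 0.9
            Y, _ = standardize(X @ B_true + r.normal(size=(n, K)))
            F = np.zeros((J, 1))
            F[[2, 7], 0] = 1.0
            feats = SNPFeatureTable(F, ["causal_mark"],
                                    [f"snp{j}" for j in range(J)])
            res = fit_amtl(X, Y, feats, 1.0, n_outer=4, b_tol=1e-9)
            if res.theta[0] > 0:
                wins += 1
        assert wins >= 18

    def test_all_zero_feature_dropped_with_warning(self, small_xy):
        from structmap.datatypes import SNPFeatureTable
        from structmap.solvers import fit_amtl

        X, Y = small_xy
        J = X.shape[1]
        F = np.zeros((J, 2))
        F[:, 0] = 1.0
        feats = SNPFeatureTable(F, ["ok", "allzero"],
                                [f"snp{j}" for j in range(J)])
        with pytest.warns(UserWarning, match="allzero"):
            res = fit_amtl(X, Y, feats, 0.5, n_outer=1)
        assert len(res.theta) == 1


class TestGGFlasso:
    def test_both_gammas_zero_equals_lasso(self, rng):
        Y, Z = random_regression(rng, n=30, J=6, K=3)
        gn = TraitNetwork.from_edges([f"gene{i}" for i in range(6)], [])
        tn = TraitNetwork.from_edges([f"trait{i}" for i in range(3)], [])
        ra = fit_ggflasso(Y, Z, gn, tn, 0.5, 0.0, 0.0, tol=1e-10)
        rl = fit_lasso(Y, Z, 0.5, tol=1e-10)
        np.testing.assert_allclose(ra.dense(), rl.dense(), atol=1e-8)

    def test_duplicated_clinical_traits_fuse(self, rng):
        Y, _ = standardize(rng.normal(size=(40, 5)))
        z = Y[:, 0] + 0.2 * rng.normal(size=40)
        Z = np.column_stack([z, z])
        gn = TraitNetwork.from_edges([f"g{i}" for i in range(5)], [])
        tn = TraitNetwork.from_edges(["t0", "t1"], [("t0", "t1", 1.0)])
        lam = 0.2
        res = fit_ggflasso(Y, Z, gn, tn, lam, 0.0, 1e3 * lam, tol=1e-10,
                           max_iter=5000, row_ids=[f"g{i}" for i in range(5)],
                           col_ids=["t0", "t1"])
        A = res.dense()
        assert np.abs(A[:, 0] - A[:, 1]).max() < 1e-5
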