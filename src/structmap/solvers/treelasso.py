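"""Tree-guided group lasso (TreeLasso) via smoothing proximal gradient.

The penalty is a nested sum of L1/L2 norms over the nodes of a hierarchical
trait tree: for every SNP row j,

    lam * [ sum_{leaves k} w_k |B_jk|
            + sum_{internal v} w_v ||B_{j, G_v}||_2 ]

where G_v is the trait set under node v and w_v its tree weight.  Zeroing a
node's group zeroes every descendant's contribution for that SNP, giving a
hierarchical sparsity pattern that follows the clustering of the traits.

The internal-node terms are non-separable, so they are smoothed in dual form
and the composite objective is minimized by the monotone FISTA engine; the
leaf (weighted L1) terms stay exact in the prox.  A shared entry point
``fit_gflasso_spg`` runs the same engine on the graph-fusion penalty as an
independent second route to the GFlasso solution.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..networks import TraitNetwork
from ..trees import TraitTree
from .common import ZERO_THRESHOLD, FitResult, as_2d, check_finite, make_coeffs
from .gflasso import gflasso_objective, _fusion_edges
from .spg import FusionTerm, GroupTerm, SmoothedPenalty, spg_fista

__all__ = ["fit_treelasso", "treelasso_objective", "fit_gflasso_spg"]


def _tree_terms(tree: TraitTree, col_ids: Sequence[str], lam: float):
    idx = {t: i for i, t in enumerate(col_ids)}
    missing = [t for t in tree.leaf_ids if t not in idx]
    if missing:
        raise ValueError(f"tree leaves not found among trait columns: {missing[:5]}")
    l1 = np.zeros(len(col_ids))
    for leaf in tree.leaves():
        (tid,) = leaf.members
        l1[idx[tid]] = lam * leaf.weight
    groups = []
    for v in tree.internal_nodes():
        if v.weight > 0:
            cols = np.array(sorted(idx[t] for t in v.members), dtype=int)
            groups.append(GroupTerm(cols=cols, weight=lam * v.weight))
    return l1, groups


def treelasso_objective(X, Y, B, tree: TraitTree, lam: float,
                        col_ids: Optional[Sequence[str]] = None) -> float:
    """Exact TreeLasso objective."""
    Y = as_2d(Y)
    if col_ids is None:
        col_ids = tree.leaf_ids
    l1, groups = _tree_terms(tree, col_ids, lam)
    R = Y - X @ B
    obj = 0.5 * float(np.sum(R * R)) + float(np.abs(l1[None, :] * B).sum())
    for g in groups:
        obj += g.weight * float(np.linalg.norm(B[:, g.cols], axis=1).sum())
    return obj


def fit_treelasso(
    X: np.ndarray,
    Y: np.ndarray,
    tree: TraitTree,
    lam: float,
    mu: Optional[float] = None,
    tol: float = 1e-9,
    max_iter: int = 50_000,
    B0: Optional[np.ndarray] = None,
    row_ids: Optional[Sequence[str]] = None,
    col_ids: Optional[Sequence[str]] = None,
) -> FitResult:
    """Fit the tree-guided group lasso.

    ``col_ids`` names Y's columns with the tree's leaf ids (defaults to the
    tree's own leaf order).
    """
    X = np.asarray(X, dtype=float)
    Y = as_2d(Y)
    check_finite(X, Y)
    if col_ids is None:
        col_ids = tree.leaf_ids
    if Y.shape[1] != len(col_ids):
        raise ValueError("column count does not match trait ids")
    l1, groups = _tree_terms(tree, col_ids, lam)
    penalty = SmoothedPenalty(shape=(X.shape[1], Y.shape[1]), groups=groups)
    B, trace, converged, it, mu_used = spg_fista(
        X, Y, l1[None, :] * np.ones((X.shape[1], 1)), penalty,
        mu=mu, tol=tol, max_iter=max_iter, B0=B0,
    )
    B[np.abs(B) < ZERO_THRESHOLD] = 0.0
    prov = {
        "algorithm": "treelasso_spg",
        "lam": lam,
        "mu": mu_used,
        "zero_threshold": ZERO_THRESHOLD,
        "n_groups": len(groups),
    }
    return FitResult(
        B=make_coeffs(B, row_ids, col_ids, prov),
        objective=trace,
        converged=converged,
        n_iter=it,
        final_objective=treelasso_objective(X, Y, B, tree, lam, col_ids),
    )


def fit_gflasso_spg(
    X: np.ndarray,
    Y: np.ndarray,
    net: TraitNetwork,
    lam: float,
    gamma: float,
    signed: bool = False,
    mu: Optional[float] = None,
    tol: float = 1e-9,
    max_iter: int = 50_000,
    B0: Optional[np.ndarray] = None,
    row_ids: Optional[Sequence[str]] = None,
    col_ids: Optional[Sequence[str]] = None,
) -> FitResult:
    """GFlasso solved by the SPG engine (cross-check route for the
    variational coordinate-descent solver)."""
    X = np.asarray(X, dtype=float)
    Y = as_2d(Y)
    check_finite(X, Y)
    K = Y.shape[1]
    if col_ids is None:
        col_ids = net.nodes if len(net.nodes) == K else [f"trait{i}" for i in range(K)]
    ei, ej, ew, es = _fusion_edges(net, col_ids, signed)
    fusions = [
        FusionTerm(m=int(ei[e]), l=int(ej[e]), sign=float(es[e]), weight=gamma * float(ew[e]))
        for e in range(len(ei))
        if gamma * ew[e] > 0
    ]
    penalty = SmoothedPenalty(shape=(X.shape[1], K), fusions=fusions)
    l1 = np.full((X.shape[1], K), lam)
    B, trace, converged, it, mu_used = spg_fista(
        X, Y, l1, penalty, mu=mu, tol=tol, max_iter=max_iter, B0=B0
    )
    B[np.abs(B) < ZERO_THRESHOLD] = 0.0
    prov = {"algorithm": "gflasso_spg", "lam": lam, "gamma": gamma,
            "mu": mu_used, "zero_threshold": ZERO_THRESHOLD}
    return FitResult(
        B=make_coeffs(B, row_ids, col_ids, prov),
        objective=trace,
        converged=converged,
        n_iter=it,
        final_objective=gflasso_objective(X, Y, B, (ei, ej, ew, es), lam, gamma),
    )
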