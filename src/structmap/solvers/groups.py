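"""Group lasso over SNP groups and multi-population group lasso (MPGL).

Both penalties are separable sums of Euclidean norms over disjoint
coefficient blocks, so block coordinate descent with *exact* block updates
converges to the global optimum.  The block subproblem

    min_b  0.5 b' H b - c' b + kappa ||b||_2

is solved in closed form: b = 0 when ||c|| <= kappa (the group KKT
condition), otherwise b = (H + (kappa/nu) I)^{-1} c where nu = ||b|| is the
root of the secular equation  sum_i z_i^2 / (lambda_i + kappa/nu)^2 = nu^2
(z = U'c in H's eigenbasis), found by bisection.  A singleton block
degenerates to the scalar soft threshold — exactly the lasso update — which
is what makes the singleton-groups and single-population reductions exact.

Group lasso groups SNP rows within each trait column (penalty
lam * sum_g w_g ||B_{g,k}||_2, default w_g = sqrt(|g|)); MPGL groups each
SNP's coefficient vector across populations (penalty lam * sum_j
||(beta_j^(1),...,beta_j^(C))||_2) with a population-block-diagonal design,
so a SNP is selected jointly across populations or not at all.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .common import FitResult, as_2d, check_finite, make_coeffs, soft_threshold

__all__ = ["fit_group_lasso", "fit_mpgl", "group_lasso_objective", "mpgl_objective"]


def _validate_partition(groups: Sequence[np.ndarray], J: int, what: str) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=int) for g in groups]
    seen: set[int] = set()
    for g in groups:
        s = set(g.tolist())
        if len(s) != len(g):
            raise ValueError(f"duplicate indices inside a {what} group")
        if seen & s:
            raise ValueError(f"overlapping {what} groups are not supported")
        seen |= s
    if seen != set(range(J)):
        raise ValueError(f"{what} groups must partition 0..{J - 1}")
    return groups


def _secular_root(eigvals: np.ndarray, z: np.ndarray, kappa: float) -> float:
    """Solve ||(H + (kappa/nu) I)^{-1} c|| = nu for nu = ||b|| > 0, written in
    the well-conditioned form psi(nu) = sum_i z_i^2/(lambda_i nu + kappa)^2 - 1
    (psi(0) = ||z||^2/kappa^2 - 1 > 0 at an active group, psi decreasing)."""

    def psi(nu: float) -> float:
        return float(np.sum(z**2 / (eigvals * nu + kappa) ** 2)) - 1.0

    hi = 1.0
    while psi(hi) > 0:
        hi *= 4
        if hi > 1e12:
            raise FloatingPointError("unbounded group subproblem")
    return brentq(psi, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


def _exact_block_update(H_eigvals, H_eigvecs, c: np.ndarray, kappa: float) -> np.ndarray:
    if np.linalg.norm(c) <= kappa:
        return np.zeros_like(c)
    z = H_eigvecs.T @ c
    nu = _secular_root(H_eigvals, z, kappa)
    return H_eigvecs @ (z / (H_eigvals + kappa / nu))


def group_lasso_objective(X, Y, B, groups, lam, weights) -> float:
    R = Y - X @ B
    obj = 0.5 * float(np.sum(R * R))
    for g, w in zip(groups, weights):
        obj += lam * w * float(np.linalg.norm(B[g, :], axis=0).sum())
    return obj


def fit_group_lasso(
    X: np.ndarray,
    Y: np.ndarray,
    groups: Sequence[np.ndarray],
    lam: float,
    weights: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    B0: Optional[np.ndarray] = None,
    row_ids: Optional[Sequence[str]] = None,
    col_ids: Optional[Sequence[str]] = None,
) -> FitResult:
    """Group lasso with SNP groups applied within each trait column."""
    X = np.asarray(X, dtype=float)
    Y = as_2d(Y)
    check_finite(X, Y)
    n, J = X.shape
    K = Y.shape[1]
    groups = _validate_partition(groups, J, "SNP")
    weights = (
        [float(np.sqrt(len(g))) for g in groups] if weights is None else [float(w) for w in weights]
    )

    XtX = X.T @ X
    XtY = X.T @ Y
    eig = []
    for g in groups:
        if len(g) == 1:
            eig.append(None)  # scalar soft-threshold path
        else:
            vals, vecs = np.linalg.eigh(XtX[np.ix_(g, g)])
            eig.append((np.maximum(vals, 0.0), vecs))

    B = np.zeros((J, K)) if B0 is None else np.array(B0, dtype=float)
    trace = [group_lasso_objective(X, Y, B, groups, lam, weights)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for g, w, e in zip(groups, weights, eig):
            kappa = lam * w
            C = XtY[g] - XtX[g] @ B + XtX[np.ix_(g, g)] @ B[g]
            if e is None:
                j = g[0]
                denom = XtX[j, j]
                B[j] = 0.0 if denom <= 0 else soft_threshold(C[0], kappa) / denom
            else:
                vals, vecs = e
                for k in range(K):
                    B[g, k] = _exact_block_update(vals, vecs, C[:, k], kappa)
        f = group_lasso_objective(X, Y, B, groups, lam, weights)
        trace.append(f)
        if abs(trace[-2] - f) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    prov = {"algorithm": "group_lasso_bcd", "lam": lam,
            "weights": list(weights), "n_groups": len(groups)}
    return FitResult(
        B=make_coeffs(B, row_ids, col_ids, prov),
        objective=trace,
        converged=converged,
        n_iter=it,
        final_objective=trace[-1],
    )


def mpgl_objective(X_by_pop, y_by_pop, B, lam) -> float:
    obj = 0.0
    for c, (Xc, yc) in enumerate(zip(X_by_pop, y_by_pop)):
        r = yc - Xc @ B[:, c]
        obj += 0.5 * float(r @ r)
    obj += lam * float(np.linalg.norm(B, axis=1).sum())
    return obj


def fit_mpgl(
    X: np.ndarray,
    y: np.ndarray,
    pops: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    B0: Optional[np.ndarray] = None,
    row_ids: Optional[Sequence[str]] = None,
) -> FitResult:
    """Multi-population group lasso for a single trait.

    ``pops`` is a per-sample population label array; the fit returns a J x C
    coefficient matrix, one column per population, with rows selected jointly
    (L2 row groups).  Populations whose trait values have zero variance are
    excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    check_finite(X, y)
    pops = np.asarray(pops)
    labels = [p for p in np.unique(pops)]
    keep_labels = []
    for p in labels:
        mask = pops == p
        if mask.sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
        if y[mask].std() == 0:
            warnings.warn(f"population {p!r} has zero trait variance; excluded")
        else:
            keep_labels.append(p)
    labels = keep_labels
    if not labels:
        raise ValueError("no usable populations")
    C = len(labels)
    J = X.shape[1]

    X_by_pop = [X[pops == p] for p in labels]
    y_by_pop = [y[pops == p] for p in labels]
    XtX_c = [Xc.T @ Xc for Xc in X_by_pop]
    Xty_c = np.column_stack([Xc.T @ yc for Xc, yc in zip(X_by_pop, y_by_pop)])
    h = np.column_stack([M.diagonal() for M in XtX_c])  # (J, C)

    B = np.zeros((J, C)) if B0 is None else np.array(B0, dtype=float)
    trace = [mpgl_objective(X_by_pop, y_by_pop, B, lam)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(J):
            c_vec = np.array(
                [Xty_c[j, c] - XtX_c[c][j] @ B[:, c] + h[j, c] * B[j, c] for c in range(C)]
            )
            if C == 1:
                denom = h[j, 0]
                B[j, 0] = 0.0 if denom <= 0 else soft_threshold(c_vec[0], lam) / denom
            elif np.linalg.norm(c_vec) <= lam:
                B[j] = 0.0
            else:
                # diagonal Hessian: the secular update needs no eigendecomposition
                nu = _secular_root(h[j], c_vec, lam)
                B[j] = c_vec / (h[j] + lam / nu)
        f = mpgl_objective(X_by_pop, y_by_pop, B, lam)
        trace.append(f)
        if abs(trace[-2] - f) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    prov = {"algorithm": "mpgl_bcd", "lam": lam, "populations": [str(p) for p in labels]}
    return FitResult(
        B=make_coeffs(B, row_ids, [str(p) for p in labels], prov),
        objective=trace,
        converged=converged,
        n_iter=it,
        final_objective=trace[-1],
    )
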