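"""Adaptive multi-task lasso (AMTL): annotation-weighted penalties.

Each SNP j receives its own penalty scales, log-linear in its annotation
feature vector f_j:

    rho_j  = exp(-theta' f_j)   (scales the L1 term)
    rho'_j = exp(-eta' f_j)     (scales the L1/L2 multi-task term)

and the model fits B, theta and eta jointly:

    0.5 ||Y - X B||_F^2
      + lam * sum_j rho_j ||B_{j,.}||_1
      + lam * sum_j rho'_j sum_{h in trait_groups} ||B_{j,h}||_2
      + N(theta, eta)

A SNP whose features look "causal" (e.g. exonic, conserved) earns a small
penalty and is more likely to be selected.  N is a normalization-style
regularizer that keeps the scales from collapsing to zero: we use
c * sum_j theta' f_j + c' * sum_j eta' f_j with self-calibrating scales
c = mean_j(lam * rho_j ||B_j||_1) (and analogously c'), the stationarity
point of a Laplace-prior normalizer — SNPs with large coefficients earn
penalties below average, null SNPs drift to the (clipped) maximum.

Optimization alternates (a) a B-step — FISTA with the exact composite prox
(row-weighted soft threshold, then row-weighted group shrinkage) — with
(b) gradient descent with backtracking on the convex (theta, eta) objective.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from ..datatypes import SNPFeatureTable
from .common import FitResult, as_2d, check_finite, make_coeffs, soft_threshold
from .groups import _validate_partition

__all__ = ["fit_amtl", "fit_weighted_sparse_group", "amtl_b_objective"]

_THETA_BOX = 5.0  # |theta| clip: keeps exp(-theta'f) in a sane range


def amtl_b_objective(X, Y, B, rho, rho2, trait_groups, lam) -> float:
    """B-step objective with the penalty scales frozen."""
    R = Y - X @ B
    obj = 0.5 * float(np.sum(R * R))
    obj += lam * float((rho[:, None] * np.abs(B)).sum())
    for h in trait_groups:
        obj += lam * float((rho2 * np.linalg.norm(B[:, h], axis=1)).sum())
    return obj


def fit_weighted_sparse_group(
    X: np.ndarray,
    Y: np.ndarray,
    l1_row_weights: np.ndarray,
    group_row_weights: np.ndarray,
    trait_groups: Sequence[np.ndarray],
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 50_000,
    B0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list[float], bool, int]:
    """FISTA for the AMTL B-step (row-weighted L1 + row-weighted group terms).

    The composite prox is exact: entrywise soft threshold with per-row
    thresholds, then per-(row, trait-group) L2 shrinkage.
    """
    n, J = X.shape
    K = Y.shape[1]
    XtX = X.T @ X
    XtY = X.T @ Y
    L = max(float(np.linalg.eigvalsh(XtX).max()), 1e-12)
    rho = np.asarray(l1_row_weights, dtype=float)
    rho2 = np.asarray(group_row_weights, dtype=float)

    def objective(M):
        return amtl_b_objective(X, Y, M, rho, rho2, trait_groups, lam)

    def prox(M, step):
        out = soft_threshold(M, (lam * rho * step)[:, None])
        for h in trait_groups:
            blk = out[:, h]
            nrm = np.linalg.norm(blk, axis=1)
            kappa = lam * rho2 * step
            scale = np.where(nrm > kappa, 1 - kappa / np.where(nrm > 0, nrm, 1.0), 0.0)
            out[:, h] = blk * scale[:, None]
        return out

    B = np.zeros((J, K)) if B0 is None else np.array(B0, dtype=float)
    Z = B.copy()
    t_k = 1.0
    trace = [objective(B)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = XtX @ Z - XtY
        cand = prox(Z - grad / L, 1.0 / L)
        f_cand = objective(cand)
        if f_cand <= trace[-1]:
            B_new, f_new = cand, f_cand
        else:
            B_new, f_new = B, trace[-1]
        t_next = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        Z = cand + ((t_k - 1) / t_next) * (cand - B) + (t_k / t_next) * (B_new - cand)
        B = B_new
        t_k = t_next
        trace.append(f_new)
        if it > 4 and abs(trace[-5] - f_new) <= 4 * tol * max(1.0, abs(trace[-5])):
            converged = True
            break
    return B, trace, converged, it


def _weight_step(F: np.ndarray, norms: np.ndarray, lam: float, theta: np.ndarray,
                 n_steps: int = 50) -> np.ndarray:
    """Gradient descent with backtracking on
    R(theta) = lam * sum_j exp(-theta'f_j) * norms_j + c * sum_j theta'f_j,
    c frozen at the current mean penalty mass (convex given c)."""
    rho = np.exp(-np.clip(F @ theta, -_THETA_BOX, _THETA_BOX))
    c = float(np.mean(lam * rho * norms))
    if c <= 0:
        return theta  # B is entirely zero; nothing to adapt to
    fsum = F.sum(axis=0)

    def obj(th):
        r = np.exp(-np.clip(F @ th, -_THETA_BOX, _THETA_BOX))
        return float(lam * (r * norms).sum() + c * (F @ th).sum())

    cur = obj(theta)
    step = 1.0
    for _ in range(n_steps):
        r = np.exp(-np.clip(F @ theta, -_THETA_BOX, _THETA_BOX))
        grad = -lam * F.T @ (r * norms) + c * fsum
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-10:
            break
        while step > 1e-12:
            cand = np.clip(theta - step * grad, -_THETA_BOX, _THETA_BOX)
            f_cand = obj(cand)
            if f_cand <= cur - 1e-4 * step * gnorm**2:
                theta, cur = cand, f_cand
                step *= 1.5
                break
            step *= 0.5
        else:
            break
    return theta


def fit_amtl(
    X: np.ndarray,
    Y: np.ndarray,
    features: SNPFeatureTable,
    lam: float,
    trait_groups: Optional[Sequence[np.ndarray]] = None,
    n_outer: int = 10,
    tol: float = 1e-6,
    b_tol: float = 1e-9,
    max_iter: int = 20_000,
    row_ids: Optional[Sequence[str]] = None,
    col_ids: Optional[Sequence[str]] = None,
) -> FitResult:
    """Fit AMTL by alternating B-steps and feature-weight steps.

    ``trait_groups`` (from clustering the traits) defaults to a single group
    of all traits — the plain multi-task row norm.
    """
    X = np.asarray(X, dtype=float)
    Y = as_2d(Y)
    check_finite(X, Y)
    n, J = X.shape
    K = Y.shape[1]
    if features.values.shape[0] != J:
        raise ValueError("feature table rows must align with SNP columns")
    F = features.values.copy()
    nonzero_cols = np.abs(F).sum(axis=0) > 0
    if not nonzero_cols.all():
        dropped = [f for f, k in zip(features.feature_names, nonzero_cols) if not k]
        warnings.warn(f"dropping all-zero feature column(s): {dropped}")
        F = F[:, nonzero_cols]
    names = [f for f, k in zip(features.feature_names, nonzero_cols) if k]
    nf = F.shape[1]
    trait_groups = (
        [np.arange(K)] if trait_groups is None else _validate_partition(trait_groups, K, "trait")
    )

    theta = np.zeros(nf)
    eta = np.zeros(nf)
    B = np.zeros((J, K))
    trace: list[float] = []
    converged = False
    outer = 0
    for outer in range(1, n_outer + 1):
        rho = np.exp(-np.clip(F @ theta, -_THETA_BOX, _THETA_BOX))
        rho2 = np.exp(-np.clip(F @ eta, -_THETA_BOX, _THETA_BOX))
        B, b_trace, _, _ = fit_weighted_sparse_group(
            X, Y, rho, rho2, trait_groups, lam, tol=b_tol, max_iter=max_iter, B0=B
        )
        trace.append(b_trace[-1])
        l1_norms = np.abs(B).sum(axis=1)
        grp_norms = np.zeros(J)
        for h in trait_groups:
            grp_norms += np.linalg.norm(B[:, h], axis=1)
        theta = _weight_step(F, l1_norms, lam, theta)
        eta = _weight_step(F, grp_norms, lam, eta)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    prov = {"algorithm": "amtl", "lam": lam, "features": names,
            "weight_link": "log_linear", "n_outer": outer}
    return FitResult(
        B=make_coeffs(B, row_ids, col_ids, prov),
        objective=trace,
        converged=converged,
        n_iter=outer,
        final_objective=trace[-1],
        theta=theta,
        eta=eta,
    )
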