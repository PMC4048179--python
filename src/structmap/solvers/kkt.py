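"""KKT (subgradient-inclusion) residuals for the separable-penalty solvers.

For the lasso at a candidate solution B, optimality requires

    X'(XB - Y)_{jk} + lam * sign(B_jk) = 0         when B_jk != 0
    |X'(XB - Y)_{jk}| <= lam                       when B_jk == 0

and the group-penalty analogue replaces the sign with the unit vector of the
group block (non-zero groups) or a norm bound (zero groups).  The residual
returned is the worst violation over coefficients / groups; a converged
solver should report a residual near zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .common import as_2d

__all__ = ["kkt_residual_lasso", "kkt_residual_group", "kkt_residual_mpgl"]


def kkt_residual_lasso(X, Y, B, lam: float) -> float:
    Y = as_2d(Y)
    G = X.T @ (X @ B - Y)
    nz = B != 0
    res_nz = np.abs(G + lam * np.sign(B))[nz].max() if nz.any() else 0.0
    res_z = np.maximum(np.abs(G[~nz]) - lam, 0.0).max() if (~nz).any() else 0.0
    return float(max(res_nz, res_z))


def kkt_residual_group(X, Y, B, groups: Sequence[np.ndarray], lam: float,
                       weights: Sequence[float] | None = None) -> float:
    """Group lasso KKT residual, groups over rows within each column."""
    Y = as_2d(Y)
    G = X.T @ (X @ B - Y)
    weights = [np.sqrt(len(g)) for g in groups] if weights is None else list(weights)
    worst = 0.0
    for g, w in zip(groups, weights):
        kappa = lam * w
        for k in range(B.shape[1]):
            b = B[g, k]
            gr = G[g, k]
            nrm = np.linalg.norm(b)
            if nrm > 0:
                worst = max(worst, float(np.linalg.norm(gr + kappa * b / nrm)))
            else:
                worst = max(worst, float(max(np.linalg.norm(gr) - kappa, 0.0)))
    return worst


def kkt_residual_mpgl(X, y, B, pops, lam: float) -> float:
    """MPGL KKT residual over SNP-row groups across populations."""
    pops = np.asarray(pops)
    labels = list(np.unique(pops))
    y = np.asarray(y, dtype=float).ravel()
    G = np.column_stack(
        [X[pops == p].T @ (X[pops == p] @ B[:, c] - y[pops == p]) for c, p in enumerate(labels)]
    )
    worst = 0.0
    for j in range(B.shape[0]):
        b = B[j]
        nrm = np.linalg.norm(b)
        if nrm > 0:
            worst = max(worst, float(np.linalg.norm(G[j] + lam * b / nrm)))
        else:
            worst = max(worst, float(max(np.linalg.norm(G[j]) - lam, 0.0)))
    return worst
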