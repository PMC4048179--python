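"""Cross-validated hyperparameter selection with a linear search strategy.

Ten-fold cross-validation, searching the two penalty weights one at a time:
first the sparsity weight lambda on a 1-D grid with the fusion weight gamma
fixed at zero, then gamma on its own grid at the selected lambda.  The CV
error of a grid point is the held-out squared prediction error per matrix
entry, averaged over folds (averaging over traits keeps the criterion
comparable across trait-set sizes).  Ties break toward the stronger penalty
(sparser model).  Fold splits are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ..datatypes import Hyperparams
from .common import FitResult, as_2d

__all__ = ["CVResult", "cross_validate", "lasso_fitter", "gflasso_fitter", "default_lambda_grid"]

#: fitter signature: fn(X, Y, lam, gamma, B0) -> FitResult
Fitter = Callable[..., FitResult]


@dataclass
class CVResult:
    records: pd.DataFrame  # columns: lam, gamma, mean_error, stage
    selected: Hyperparams
    folds: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def error_at(self, lam: float, gamma: float) -> float:
        r = self.records
        row = r[(r.lam == lam) & (r.gamma == gamma)]
        return float(row.mean_error.iloc[0])


def default_lambda_grid(X, Y, n_points: int = 6, ratio: float = 0.05) -> np.ndarray:
    """Log-spaced grid from lam_max (all-zero solution) down to ratio*lam_max."""
    lmax = float(np.abs(np.asarray(X).T @ as_2d(np.asarray(Y))).max())
    return np.geomspace(lmax, ratio * lmax, n_points)


def lasso_fitter(**kw) -> Fitter:
    from .lasso import fit_lasso

    def fit(X, Y, lam, gamma=0.0, B0=None):
        return fit_lasso(X, Y, lam, B0=B0, **kw)

    return fit


def gflasso_fitter(net, signed: bool = False, **kw) -> Fitter:
    from .gflasso import fit_gflasso

    def fit(X, Y, lam, gamma=0.0, B0=None):
        return fit_gflasso(X, Y, net, lam, gamma, signed=signed, B0=B0, **kw)

    return fit


def _fold_errors(fitter, X, Y, grid, fixed, vary, folds_idx, warm: bool):
    """Per-fold held-out per-entry squared error for each grid value."""
    errors = np.zeros((len(folds_idx), len(grid)))
    for f, (tr, te) in enumerate(folds_idx):
        Xtr, Ytr, Xte, Yte = X[tr], Y[tr], X[te], Y[te]
        B0 = None
        for i, val in enumerate(grid):
            lam, gamma = (val, fixed) if vary == "lam" else (fixed, val)
            res = fitter(Xtr, Ytr, lam=lam, gamma=gamma, B0=B0)
            B = res.dense()
            if warm:
                B0 = B
            resid = Yte - Xte @ B
            errors[f, i] = float(np.mean(resid**2))
    return errors


def cross_validate(
    fitter: Fitter,
    X: np.ndarray,
    Y: np.ndarray,
    lambda_grid: Sequence[float],
    gamma_grid: Optional[Sequence[float]] = None,
    folds: int = 10,
    seed: int = 0,
    warm_start: bool = True,
    rule: str = "min",
) -> CVResult:
    """Linear-search CV: select lambda at gamma=0, then gamma at that lambda.

    ``rule='min'`` (default) picks the error-minimizing grid point, ties
    broken toward the stronger penalty.  ``rule='1se'`` picks the strongest
    penalty whose mean error is within one standard error (across folds) of
    the minimum — the usual sparser choice when the fit feeds support
    statements rather than predictions.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X = np.asarray(X, dtype=float)
    Y = as_2d(np.asarray(Y))
    n = X.shape[0]
    if not len(lambda_grid):
        raise ValueError("lambda grid must be non-empty")
    if folds > n:
        raise ValueError("more folds than samples")

    lam_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]  # strong -> weak, warm start
    current_seed = seed
    for attempt in range(5):
        kf = KFold(n_splits=folds, shuffle=True, random_state=current_seed)
        folds_idx = list(kf.split(X))
        ok = all(X[tr].std(axis=0).min() > 0 for tr, _ in folds_idx)
        if ok:
            break
        warnings.warn("a fold had a zero-variance training column; re-splitting")
        current_seed += 1

    fold_assignment = np.empty(n, dtype=int)
    for f, (_, te) in enumerate(folds_idx):
        fold_assignment[te] = f

    def _select(grid_vals, fold_err, stronger_first: bool):
        """Index of the selected grid point under the active rule; grid order
        must run from the stronger to the weaker penalty."""
        mean = fold_err.mean(axis=0)
        order = range(len(grid_vals)) if stronger_first else range(len(grid_vals) - 1, -1, -1)
        best = next(iter(order))
        for i in order:
            if mean[i] < mean[best] - 1e-12:
                best = i
        if rule == "1se":
            se = fold_err[:, best].std(ddof=1) / np.sqrt(fold_err.shape[0])
            for i in order:  # first (strongest) point within one SE wins
                if mean[i] <= mean[best] + se:
                    return i
        return best

    records = []
    lam_fold_err = _fold_errors(fitter, X, Y, lam_grid, 0.0, "lam", folds_idx, warm_start)
    lam_err = lam_fold_err.mean(axis=0)
    for lam, e in zip(lam_grid, lam_err):
        records.append({"lam": lam, "gamma": 0.0, "mean_error": e, "stage": "lambda"})
    lam_star = float(lam_grid[_select(lam_grid, lam_fold_err, stronger_first=True)])
    gamma_star = 0.0

    if gamma_grid is not None and len(gamma_grid):
        g_grid = np.sort(np.asarray(gamma_grid, dtype=float))  # weak -> strong, warm start
        g_fold_err = _fold_errors(fitter, X, Y, g_grid, lam_star, "gamma", folds_idx, warm_start)
        g_err = g_fold_err.mean(axis=0)
        for g, e in zip(g_grid, g_err):
            records.append({"lam": lam_star, "gamma": g, "mean_error": e, "stage": "gamma"})
        gamma_star = float(g_grid[_select(g_grid, g_fold_err, stronger_first=False)])

    selected = Hyperparams(lam=lam_star, gamma=gamma_star, seed=current_seed)
    return CVResult(
        records=pd.DataFrame(records),
        selected=selected,
        folds=folds,
        seed=current_seed,
        fold_assignment=fold_assignment,
    )
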