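"""Shared solver plumbing: fit results, soft thresholding, objective helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..datatypes import CoefficientMatrix

__all__ = ["FitResult", "soft_threshold", "squared_loss", "as_2d", "make_coeffs"]

#: Coefficients whose magnitude falls below this after an iterative solve that
#: cannot produce exact zeros (variational / smoothed routes) are set to zero;
#: the threshold is recorded in the result's provenance.
ZERO_THRESHOLD = 1e-8


@dataclass
class FitResult:
    """Outcome of a penalized fit.

    ``objective`` is the per-iteration trace of the objective the optimizer
    monotonically decreases (the exact objective for coordinate-descent
    routes, the smoothed surrogate for the proximal-gradient engine; the
    final exact objective is always available via ``final_objective``).
    """

    B: CoefficientMatrix
    objective: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    final_objective: float = float("nan")
    theta: Optional[np.ndarray] = None
    eta: Optional[np.ndarray] = None

    def dense(self) -> np.ndarray:
        return self.B.toarray()


def soft_threshold(x: np.ndarray, thr) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def squared_loss(X: np.ndarray, Y: np.ndarray, B: np.ndarray) -> float:
    R = Y - X @ B
    return 0.5 * float(np.sum(R * R))


def as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def make_coeffs(
    B: np.ndarray,
    row_ids: Optional[Sequence[str]],
    col_ids: Optional[Sequence[str]],
    provenance: dict,
) -> CoefficientMatrix:
    J, K = B.shape
    return CoefficientMatrix.from_dense(
        B,
        list(row_ids) if row_ids is not None else _default_ids("snp", J),
        list(col_ids) if col_ids is not None else _default_ids("trait", K),
        provenance,
    )


def check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in solver input")
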