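"""Trait preprocessing: missingness filtering, k-NN imputation, standardization.

The preprocessing pipeline mirrors common eQTL practice: drop traits measured
in too few samples, impute the remaining holes from the k nearest samples,
and z-score every column so penalty weights are comparable across traits and
SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import replace as _dc_replace
from typing import Union

import numpy as np

from .datatypes import GenotypeMatrix, TraitMatrix

__all__ = ["filter_missing_traits", "impute_knn", "standardize", "standardize_matrix"]


def filter_missing_traits(T: TraitMatrix, max_missing_frac: float = 0.30) -> TraitMatrix:
    """Drop traits missing in strictly more than ``max_missing_frac`` of samples.

    The default 0.30 reproduces the usual "exclude phenotypes missing in more
    than 30% of individuals" rule; survivors keep their original order.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = T.missing_fraction()
    keep = frac <= max_missing_frac
    return TraitMatrix(
        T.values[:, keep],
        trait_ids=[t for t, k in zip(T.trait_ids, keep) if k],
        sample_ids=list(T.sample_ids),
        kind=T.kind,
        gene_map=None if T.gene_map is None else T.gene_map.loc[
            [t for t, k in zip(T.trait_ids, keep) if k]
        ],
    )


def impute_knn(T: TraitMatrix, k: int = 10) -> TraitMatrix:
    """Fill each missing cell with the mean of that trait over the k nearest samples.

    Distance between two samples is the Euclidean distance over their mutually
    observed traits, scaled by ``sqrt(K / n_shared)`` so that pairs sharing few
    traits are not artificially close.  Neighbors are the k closest samples
    with the target trait observed; ties in distance break by sample order.
    ``k`` is capped at n - 1.
    """
    V = T.values.copy()
    n, K = V.shape
    miss = np.isnan(V)
    if not miss.any():
        return T
    if miss.all(axis=1).any():
        i = int(np.flatnonzero(miss.all(axis=1))[0])
        raise ValueError(f"sample {T.sample_ids[i]!r} has all traits missing")
    k = min(int(k), n - 1)
    if k < 1:
        raise ValueError("k must be >= 1")

    obs = ~miss
    # pairwise scaled Euclidean distance over mutually observed traits
    dist = np.zeros((n, n))
    for a in range(n):
        shared = obs[a] & obs  # (n, K)
        diff = np.where(shared, V[a] - np.where(obs, V, 0.0), 0.0)
        n_shared = shared.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt(np.nansum(diff**2, axis=1) * (K / n_shared))
        d[n_shared == 0] = np.inf
        dist[a] = d
    np.fill_diagonal(dist, np.inf)

    out = V.copy()
    for a, j in np.argwhere(miss):
        candidates = np.where(obs[:, j])[0]
        if candidates.size == 0:
            raise ValueError(f"trait {T.trait_ids[j]!r} observed in no sample")
        # stable sort => distance ties break by sample order
        order = candidates[np.argsort(dist[a, candidates], kind="stable")]
        nn = order[:k]
        out[a, j] = V[nn, j].mean()
    return _dc_replace(T, values=out)


def standardize(M: np.ndarray, mode: str = "zscore") -> tuple[np.ndarray, np.ndarray]:
    """Column-center (and for ``zscore`` scale to unit variance) a matrix.

    Returns ``(standardized, zero_variance_flags)``.  Constant columns are
    centered but left unscaled, and flagged.  Idempotent: applying it twice
    gives the same result as once.
    """
    if mode not in ("center", "zscore"):
        raise ValueError("mode must be 'center' or 'zscore'")
    M = np.asarray(M, dtype=float)
    if np.isnan(M).any():
        raise ValueError("standardize requires complete data; impute first")
    out = M - M.mean(axis=0)
    flags = out.std(axis=0) == 0
    if mode == "zscore":
        sd = out.std(axis=0)
        sd[flags] = 1.0
        out = out / sd
    return out, flags


def standardize_matrix(
    m: Union[GenotypeMatrix, TraitMatrix], mode: str = "zscore"
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize the values of a typed matrix; constant columns flagged."""
    values, flags = standardize(m.values, mode=mode)
    if flags.any():
        ids = m.snp_ids if isinstance(m, GenotypeMatrix) else m.trait_ids
        warnings.warn(
            f"{int(flags.sum())} zero-variance column(s), e.g. "
            f"{[i for i, f in zip(ids, flags) if f][:3]}; left centered only"
        )
    return values, flags
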