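"""Core containers for association-mapping data.

The central objects mirror the quantities of a multi-task association study:
a genotype matrix ``X`` (samples x SNPs, allele dosages), one or more trait
matrices ``Y``/``Z`` (samples x gene expressions or clinical traits), and a
sparse coefficient matrix ``B`` whose non-zero entries are the reported
associations.  Everything downstream (networks, penalized fits, the two-stage
three-way analysis) is expressed in terms of these containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenotypeMatrix",
    "TraitMatrix",
    "SNPFeatureTable",
    "CoefficientMatrix",
    "Hyperparams",
]

#: Allowed allele-dosage codings.  ``haploid`` is a 0/1 cross (e.g. a yeast
#: segregant panel), ``diploid`` is 0/1/2 minor-allele dosage, ``pm1`` is the
#: -1/+1 recoding some pipelines use for haploid crosses.
CODINGS = {
    "haploid": {0.0, 1.0},
    "diploid": {0.0, 1.0, 2.0},
    "pm1": {-1.0, 1.0},
}


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class GenotypeMatrix:
    """n x J allele-dosage matrix with an optional genomic map.

    Parameters
    ----------
    values
        Dosage matrix, one row per sample, one column per SNP.  Missing
        genotypes are rejected: only trait matrices support missingness.
    snp_ids, sample_ids
        Unique labels for columns and rows.
    coding
        One of ``haploid`` (0/1), ``diploid`` (0/1/2) or ``pm1`` (-1/+1).
    snp_map
        Optional DataFrame indexed by ``snp_id`` with columns
        ``chromosome`` (str) and ``position`` (1-based bp, positive int).
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    coding: str = "haploid"
    snp_map: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        self.snp_ids = _check_unique(self.snp_ids, "snp ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        n, J = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != J:
            raise ValueError("id lengths do not match matrix shape")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing genotype at sample {self.sample_ids[i]!r}, "
                f"snp {self.snp_ids[j]!r}; genotype matrices must be complete"
            )
        allowed = CODINGS[self.coding]
        bad = ~np.isin(self.values, list(allowed))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"value {self.values[i, j]!r} at sample {self.sample_ids[i]!r}, "
                f"snp {self.snp_ids[j]!r} not in coding {self.coding!r} set {sorted(allowed)}"
            )
        if self.snp_map is not None:
            self.snp_map = validate_snp_map(self.snp_map, self.snp_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def validate_snp_map(snp_map: pd.DataFrame, snp_ids: Sequence[str]) -> pd.DataFrame:
    missing = [s for s in snp_ids if s not in snp_map.index]
    if missing:
        raise ValueError(f"snp map missing entries for {missing[:5]}")
    snp_map = snp_map.loc[list(snp_ids)].copy()
    snp_map["chromosome"] = snp_map["chromosome"].astype(str)
    snp_map["position"] = snp_map["position"].astype(int)
    if (snp_map["position"] <= 0).any():
        raise ValueError("positions must be positive (1-based bp)")
    return snp_map


@dataclass
class TraitMatrix:
    """n x K matrix of continuous traits (gene expression or clinical).

    Missing entries are NaN and are only permitted before imputation; the
    ``has_missing`` property flags them.  ``gene_map`` optionally carries the
    genomic anchor of expression traits (chromosome, transcription start).
    """

    values: np.ndarray
    trait_ids: list[str]
    sample_ids: list[str]
    kind: str = "expression"
    gene_map: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be 2-D")
        self.trait_ids = _check_unique(self.trait_ids, "trait ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        n, K = self.values.shape
        if len(self.sample_ids) != n or len(self.trait_ids) != K:
            raise ValueError("id lengths do not match matrix shape")
        if self.kind not in ("expression", "clinical"):
            raise ValueError(f"kind must be 'expression' or 'clinical', got {self.kind!r}")
        if self.gene_map is not None:
            missing = [t for t in self.trait_ids if t not in self.gene_map.index]
            if missing:
                raise ValueError(f"gene map missing entries for {missing[:5]}")
            gm = self.gene_map.loc[list(self.trait_ids)].copy()
            gm["chromosome"] = gm["chromosome"].astype(str)
            gm["tx_start"] = gm["tx_start"].astype(int)
            self.gene_map = gm

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def missing_fraction(self) -> np.ndarray:
        """Per-trait fraction of missing samples."""
        return np.isnan(self.values).mean(axis=0)


@dataclass
class SNPFeatureTable:
    """J x F table of per-SNP annotation features.

    Mirrors the feature set used for annotation-adaptive penalties: discrete
    indicators of SNP location (exon, intron, binding site, ...) plus
    continuous scores such as conservation, standardized to zero mean and
    unit variance.
    """

    values: np.ndarray
    feature_names: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        self.feature_names = _check_unique(self.feature_names, "feature names")
        self.snp_ids = _check_unique(self.snp_ids, "snp ids")
        if self.values.shape != (len(self.snp_ids), len(self.feature_names)):
            raise ValueError("feature table shape does not match ids")

    def aligned_to(self, snp_ids: Sequence[str]) -> "SNPFeatureTable":
        """Return a copy whose rows follow ``snp_ids`` order."""
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise ValueError(f"feature table missing SNPs {missing[:5]}")
        order = [idx[s] for s in snp_ids]
        return SNPFeatureTable(self.values[order], list(self.feature_names), list(snp_ids))


@dataclass
class CoefficientMatrix:
    """Sparse association-strength matrix (SNPs x traits, or genes x traits).

    Exact zeros are structural: they come out of soft-threshold / proximal
    steps, or from a post-hoc threshold recorded in ``provenance``
    (key ``"zero_threshold"``).
    """

    matrix: sp.csr_matrix
    row_ids: list[str]
    col_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.row_ids = _check_unique(self.row_ids, "row ids")
        self.col_ids = _check_unique(self.col_ids, "col ids")
        if self.matrix.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("coefficient matrix shape does not match ids")

    @classmethod
    def from_dense(
        cls,
        B: np.ndarray,
        row_ids: Sequence[str],
        col_ids: Sequence[str],
        provenance: Optional[dict] = None,
    ) -> "CoefficientMatrix":
        return cls(sp.csr_matrix(B), list(row_ids), list(col_ids), provenance or {})

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def support(self) -> np.ndarray:
        """Boolean mask of non-zero coefficients."""
        return self.toarray() != 0

    @property
    def nnz(self) -> int:
        return self.matrix.nnz

    def to_frame(self) -> pd.DataFrame:
        """Long-format (row_id, col_id, beta) table of the non-zeros."""
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "row_id": [self.row_ids[i] for i in coo.row],
                "col_id": [self.col_ids[j] for j in coo.col],
                "beta": coo.data,
            }
        )


@dataclass
class Hyperparams:
    """Penalty weights and solver controls shared by all fitters.

    lam      -- L1 sparsity weight (>= 0)
    gamma    -- fusion weight for graph-guided fusion (>= 0)
    gamma_gene, gamma_trait -- the two fusion weights of the three-way model
    mu       -- smoothing parameter of the proximal-gradient engine (> 0 when set)
    tol      -- relative objective-change convergence tolerance
    max_iter -- iteration cap
    seed     -- RNG seed for anything stochastic (fold splits, restarts)
    """

    lam: float = 0.1
    gamma: float = 0.0
    gamma_gene: float = 0.0
    gamma_trait: float = 0.0
    mu: Optional[float] = None
    tol: float = 1e-6
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam", "gamma", "gamma_gene", "gamma_trait"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def replace(self, **kw) -> "Hyperparams":
        return dataclasses.replace(self, **kw)
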