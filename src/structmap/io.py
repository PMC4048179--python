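"""Tab-delimited readers and writers for matrices, maps, graphs and trees.

All matrix files follow the same convention: a header row of entity ids, a
first column of sample ids, UTF-8, tab separated.  Auxiliary tables:

* SNP map:     ``snp_id  chromosome  position``
* gene map:    ``trait_id  chromosome  tx_start``
* edge list:   ``trait_a  trait_b  weight``
* annotations: ``trait_id  term_id`` (one pair per line, GAF-lite)
* features:    header of feature names, first column snp_id
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datatypes import CODINGS, CoefficientMatrix, GenotypeMatrix, SNPFeatureTable, TraitMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_snp_map",
    "read_gene_map",
    "read_feature_table",
    "read_annotation_map",
    "read_edge_list",
    "write_edge_list",
    "write_coefficients",
    "read_coefficients",
]

PathLike = Union[str, Path, _io.IOBase]


def _read_table(path: PathLike) -> pd.DataFrame:
    # read the raw text once: pandas silently renames duplicate header ids,
    # which must instead be a validation error
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    header = text.split("\n", 1)[0].rstrip("\r").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column ids: {dupes[:5]}")
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    return df


def _to_float(df: pd.DataFrame, allow_missing: bool) -> np.ndarray:
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}"
                    ) from None
        raise
    if not allow_missing and np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}")
    return values


def read_matrix(
    path: PathLike,
    role: str = "trait",
    coding: str = "haploid",
    kind: str = "expression",
    snp_map: Optional[pd.DataFrame] = None,
    gene_map: Optional[pd.DataFrame] = None,
) -> Union[GenotypeMatrix, TraitMatrix]:
    """Read a samples-x-entities TSV as a genotype or trait matrix.

    Row/column order is preserved exactly as in the file.  Genotype files may
    not contain missing values; trait files may (they are flagged and must be
    imputed or filtered before model fitting).
    """
    df = _read_table(path)
    if role == "genotype":
        values = _to_float(df, allow_missing=False)
        return GenotypeMatrix(
            values,
            snp_ids=list(df.columns),
            sample_ids=list(df.index),
            coding=coding,
            snp_map=snp_map,
        )
    if role == "trait":
        values = _to_float(df, allow_missing=True)
        return TraitMatrix(
            values,
            trait_ids=list(df.columns),
            sample_ids=list(df.index),
            kind=kind,
            gene_map=gene_map,
        )
    raise ValueError(f"role must be 'genotype' or 'trait', got {role!r}")


def write_matrix(m: Union[GenotypeMatrix, TraitMatrix], path: PathLike) -> None:
    """Write a matrix in the canonical TSV layout (lossless round trip)."""
    if isinstance(m, GenotypeMatrix):
        cols, values = m.snp_ids, m.values
        # genotype dosages are small integers; keep them integral on disk
        df = pd.DataFrame(values, index=m.sample_ids, columns=cols)
        if np.allclose(values, np.round(values)):
            df = df.astype(int)
    else:
        df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.trait_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_snp_map(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["snp_id", "chromosome", "position"]
    df = df.set_index("snp_id")
    df["position"] = df["position"].astype(int)
    return df


def read_gene_map(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["trait_id", "chromosome", "tx_start"]
    df = df.set_index("trait_id")
    df["tx_start"] = df["tx_start"].astype(int)
    return df


def read_feature_table(path: PathLike, standardize_continuous: bool = True) -> SNPFeatureTable:
    """Read a SNP feature table; continuous columns are z-scored.

    A column is treated as continuous when it takes more than two distinct
    values; indicator columns are left untouched.
    """
    df = _read_table(path)
    values = _to_float(df, allow_missing=False)
    if standardize_continuous:
        for j in range(values.shape[1]):
            col = values[:, j]
            if len(np.unique(col)) > 2:
                sd = col.std()
                if sd > 0:
                    values[:, j] = (col - col.mean()) / sd
    return SNPFeatureTable(values, list(df.columns), list(df.index))


def read_annotation_map(path: PathLike) -> dict[str, set[str]]:
    """Read trait -> annotation-term pairs into a dict of term sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["trait_id", "term_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for t, g in df.groupby("trait_id"):
        out[str(t)] = set(g["term_id"])
    return out


def read_edge_list(path: PathLike) -> pd.DataFrame:
    """Edge list TSV: trait_a, trait_b, weight and optionally sign."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = ["trait_a", "trait_b", "weight", "sign"][: df.shape[1]]
    df.columns = cols
    df["weight"] = df["weight"].astype(float)
    if "sign" in df:
        df["sign"] = df["sign"].astype(float)
    return df


def write_edge_list(edges: pd.DataFrame, path: PathLike) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_coefficients(coeffs: CoefficientMatrix, path: PathLike) -> None:
    """Write the non-zeros of a coefficient matrix as sparse TSV."""
    df = coeffs.to_frame()
    df.columns = ["snp_id", "trait_id", "beta"]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_coefficients(
    path: PathLike, row_ids: list[str], col_ids: list[str]
) -> CoefficientMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["snp_id", "trait_id", "beta"]
    B = np.zeros((len(row_ids), len(col_ids)))
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: i for i, c in enumerate(col_ids)}
    for _, rec in df.iterrows():
        B[ri[rec["snp_id"]], ci[rec["trait_id"]]] = float(rec["beta"])
    return CoefficientMatrix.from_dense(B, row_ids, col_ids)
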