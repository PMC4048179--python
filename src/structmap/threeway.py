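"""Two-stage genome -> transcriptome -> phenome association analysis.

Stage 1 maps SNPs to gene expression with GFlasso over the gene network;
stage 2 maps measured expression to clinical traits with gGFlasso over both
the gene and trait networks.  The assembled triplets — (SNP j, gene m,
trait t) with B_jm != 0 and A_mt != 0 — chain the two supports into
candidate mechanistic paths.  Post-processing follows standard eQTL
reporting: cis/trans classification by a 10 Mb same-chromosome window,
merging of associations from SNPs within 2 Mb of each other for the same
gene, and trans-hotspot flagging of SNPs associated with more than 20 genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import CoefficientMatrix, Hyperparams
from .networks import TraitNetwork
from .solvers.gflasso import fit_gflasso, fit_ggflasso

__all__ = [
    "TripletSet",
    "HotspotReport",
    "run_two_stage",
    "assemble_triplets",
    "classify_cis_trans",
    "merge_nearby_snps",
    "detect_hotspots",
]

CIS_WINDOW_BP = 10_000_000
MERGE_WINDOW_BP = 2_000_000
HOTSPOT_MIN_GENES = 20


@dataclass
class TripletSet:
    records: pd.DataFrame  # snp_id, gene_id, trait_id, beta_sg, beta_gt
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_chromosome(self, snp_map: pd.DataFrame) -> pd.Series:
        chrom = self.records["snp_id"].map(snp_map["chromosome"])
        return chrom.value_counts()


@dataclass
class HotspotReport:
    gene_counts: pd.Series  # per snp_id: number of associated genes
    hotspots: list[str]
    min_genes: int

    def __len__(self) -> int:
        return len(self.hotspots)


def assemble_triplets(B: CoefficientMatrix, A: CoefficientMatrix) -> TripletSet:
    """Support product of the two stages: one record per (j, m, t) with
    B_jm != 0 and A_mt != 0."""
    if B.col_ids != A.row_ids:
        raise ValueError("stage-1 columns (genes) must match stage-2 rows")
    Bf = B.to_frame().rename(columns={"row_id": "snp_id", "col_id": "gene_id",
                                      "beta": "beta_sg"})
    Af = A.to_frame().rename(columns={"row_id": "gene_id", "col_id": "trait_id",
                                      "beta": "beta_gt"})
    rec = Bf.merge(Af, on="gene_id", how="inner")
    rec = rec[["snp_id", "gene_id", "trait_id", "beta_sg", "beta_gt"]]
    return TripletSet(rec.reset_index(drop=True))


def run_two_stage(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    gene_net: TraitNetwork,
    trait_net: TraitNetwork,
    hyper: Hyperparams,
    snp_ids: Optional[list[str]] = None,
    gene_ids: Optional[list[str]] = None,
    trait_ids: Optional[list[str]] = None,
    signed: bool = False,
) -> tuple[CoefficientMatrix, CoefficientMatrix, TripletSet]:
    """GFlasso stage 1 (X -> Y), gGFlasso stage 2 (Y -> Z), then triplets.

    Stage 2 regresses the clinical traits on the *measured* expression
    matrix, following the sequential two-stage formulation.
    """
    if not (X.shape[0] == Y.shape[0] == Z.shape[0]):
        raise ValueError("X, Y, Z must share the sample set")
    res1 = fit_gflasso(
        X, Y, gene_net, hyper.lam, hyper.gamma, signed=signed,
        tol=hyper.tol, max_iter=hyper.max_iter,
        row_ids=snp_ids, col_ids=gene_ids,
    )
    res2 = fit_ggflasso(
        Y, Z, gene_net, trait_net, hyper.lam, hyper.gamma_gene, hyper.gamma_trait,
        signed=signed, tol=hyper.tol, max_iter=hyper.max_iter,
        row_ids=gene_ids, col_ids=trait_ids,
    )
    return res1.B, res2.B, assemble_triplets(res1.B, res2.B)


def classify_cis_trans(
    B: CoefficientMatrix,
    snp_map: pd.DataFrame,
    gene_map: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Label every non-zero association cis or trans.

    An association is *cis* when SNP and gene sit on the same chromosome
    within ``window_bp`` (default 10 Mb) of each other — distance measured
    SNP position to transcription start — and *trans* otherwise.  Ids absent
    from a map are labeled ``unknown`` with a warning.
    """
    rec = B.to_frame().rename(columns={"row_id": "snp_id", "col_id": "gene_id"})
    labels = []
    unknown = 0
    for snp, gene in zip(rec["snp_id"], rec["gene_id"]):
        if snp not in snp_map.index or gene not in gene_map.index:
            labels.append("unknown")
            unknown += 1
            continue
        s = snp_map.loc[snp]
        g = gene_map.loc[gene]
        same = str(s["chromosome"]) == str(g["chromosome"])
        if same and abs(int(s["position"]) - int(g["tx_start"])) <= window_bp:
            labels.append("cis")
        else:
            labels.append("trans")
    if unknown:
        warnings.warn(f"{unknown} association(s) with unmapped ids labeled 'unknown'")
    rec["label"] = labels
    return rec


def merge_nearby_snps(
    B: CoefficientMatrix,
    snp_map: pd.DataFrame,
    window_bp: int = MERGE_WINDOW_BP,
) -> pd.DataFrame:
    """Collapse same-gene associations from nearby SNPs into one.

    Per gene, same-chromosome SNPs are chained by single linkage: any two
    SNPs within ``window_bp`` (default 2 Mb) join the same chain, and each
    chain is reported once with the strongest-|beta| SNP as representative.
    """
    rec = B.to_frame().rename(columns={"row_id": "snp_id", "col_id": "gene_id"})
    out = []
    for gene, grp in rec.groupby("gene_id", sort=True):
        sub = grp.copy()
        sub["chromosome"] = sub["snp_id"].map(snp_map["chromosome"])
        sub["position"] = sub["snp_id"].map(snp_map["position"])
        for chrom, chain_grp in sub.groupby("chromosome", sort=True):
            chain_grp = chain_grp.sort_values(["position", "snp_id"], kind="stable")
            pos = chain_grp["position"].to_numpy()
            breaks = np.where(np.diff(pos) > window_bp)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [len(pos)]])
            for s_i, e_i in zip(starts, ends):
                chain = chain_grp.iloc[s_i:e_i]
                rep = chain.loc[chain["beta"].abs().idxmax()]
                out.append({
                    "gene_id": gene,
                    "chromosome": chrom,
                    "snp_id": rep["snp_id"],
                    "beta": rep["beta"],
                    "n_snps_merged": len(chain),
                    "span_start": int(pos[s_i]),
                    "span_end": int(pos[e_i - 1]),
                })
    return pd.DataFrame(out)


def detect_hotspots(B: CoefficientMatrix, min_genes: int = HOTSPOT_MIN_GENES) -> HotspotReport:
    """Flag SNPs associated with strictly more than ``min_genes`` genes."""
    support = B.support()
    counts = pd.Series(support.sum(axis=1), index=B.row_ids, name="n_genes")
    hotspots = list(counts.index[counts > min_genes])
    return HotspotReport(gene_counts=counts, hotspots=hotspots, min_genes=min_genes)


def exclude_chromosome(B: CoefficientMatrix, snp_map: pd.DataFrame,
                       chromosome: str = "X") -> CoefficientMatrix:
    """Optionally drop associations on one chromosome (e.g. X, to avoid
    sex-linked effects); off by default in every pipeline."""
    keep_rows = [i for i, s in enumerate(B.row_ids)
                 if s not in snp_map.index or str(snp_map.loc[s, "chromosome"]) != chromosome]
    dense = B.toarray()[keep_rows, :]
    return CoefficientMatrix.from_dense(
        dense, [B.row_ids[i] for i in keep_rows], B.col_ids,
        {**B.provenance, "excluded_chromosome": chromosome},
    )
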