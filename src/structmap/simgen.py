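"""Synthetic genotype / expression / clinical-trait generator with ground truth.

Emulates the structural features the structured solvers exploit, at desk
scale:

* genotypes from a cross or admixed panel: per-population allele frequencies
  drawn by the Balding-Nichols construction at a configured Fst, and
  within-block LD from a first-order Markov copy process (adjacent SNPs in a
  block share an allele with probability rho, giving adjacent correlation
  ~ rho when the block shares its allele frequency — which it does here);
* modular co-expression: gene modules driven by a shared latent factor whose
  variance is set so the within-module correlation matches the configured
  value, plus sparse SNP effects (including planted trans hotspots that
  regulate many genes);
* a second linear layer from genes to clinical traits, giving planted
  SNP -> gene -> trait chains.

Everything is deterministic given the seed, and the returned
:class:`GroundTruth` records exactly the planted architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, TraitMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimDataset",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_traits",
    "simulate_dataset",
    "yeast_like",
    "mouse_like",
    "eqtl_benchmark_config",
    "threeway_benchmark_config",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``causal`` entries are (snp_indices, module_index, beta): each listed SNP
    affects every gene of the module with effect size beta.  ``hotspots``
    entries are (snp_index, n_genes, beta): the SNP affects the first
    ``n_genes`` genes regardless of module (a planted trans hotspot).
    ``gene_to_trait`` entries are (gene_indices, trait_index, effect).
    """

    n: int = 200
    J: int = 100
    K: int = 50
    q: int = 0
    coding: str = "haploid"
    maf_range: tuple[float, float] = (0.2, 0.5)
    block_size: int = 10
    ld_rho: float = 0.8
    n_modules: int = 5
    module_rho: float = 0.6
    causal: list = field(default_factory=list)
    hotspots: list = field(default_factory=list)
    gene_to_trait: list = field(default_factory=list)
    noise_sd_y: float = 1.0
    noise_sd_z: float = 1.0
    n_pops: int = 1
    fst: float = 0.0
    n_chromosomes: int = 5
    snp_spacing_bp: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.module_rho < 1:
            raise ValueError("module_rho must be in [0, 1)")
        if self.coding not in ("haploid", "diploid"):
            raise ValueError("coding must be haploid or diploid")

    def module_genes(self, m: int) -> np.ndarray:
        """Gene indices of module m (contiguous, equal-sized modules)."""
        size = self.K // self.n_modules
        start = m * size
        end = start + size if m < self.n_modules - 1 else self.K
        return np.arange(start, end)

    def blocks(self) -> list[np.ndarray]:
        return [np.arange(s, min(s + self.block_size, self.J))
                for s in range(0, self.J, self.block_size)]


@dataclass
class GroundTruth:
    B: np.ndarray  # J x K true SNP -> gene effects
    A: np.ndarray  # K x q true gene -> trait effects
    pop_labels: np.ndarray
    module_membership: list[np.ndarray]
    config: SimConfig


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    expression: TraitMatrix
    clinical: Optional[TraitMatrix]
    truth: GroundTruth


def _maps(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genomic maps: SNP blocks and genes laid out across chromosomes."""
    snp_rows = []
    per_chrom = int(np.ceil(cfg.J / cfg.n_chromosomes))
    for j in range(cfg.J):
        chrom = str(1 + j // per_chrom)
        pos = 1 + (j % per_chrom) * cfg.snp_spacing_bp
        snp_rows.append({"snp_id": f"snp{j}", "chromosome": chrom, "position": pos})
    snp_map = pd.DataFrame(snp_rows).set_index("snp_id")
    gene_rows = []
    per_chrom_g = int(np.ceil(cfg.K / cfg.n_chromosomes))
    for k in range(cfg.K):
        chrom = str(1 + k // per_chrom_g)
        pos = 50_000 + (k % per_chrom_g) * cfg.snp_spacing_bp
        gene_rows.append({"trait_id": f"gene{k}", "chromosome": chrom, "tx_start": pos})
    gene_map = pd.DataFrame(gene_rows).set_index("trait_id")
    return snp_map, gene_map


def _haplotypes(cfg: SimConfig, freqs: np.ndarray, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Markov copy process within blocks; ``freqs`` is the per-SNP frequency."""
    H = np.zeros((n, cfg.J))
    for block in cfg.blocks():
        p = freqs[block[0]]  # block-constant frequency keeps adjacent r = rho
        prev = rng.random(n) < p
        H[:, block[0]] = prev
        for j in block[1:]:
            copy = rng.random(n) < cfg.ld_rho
            fresh = rng.random(n) < p
            prev = np.where(copy, prev, fresh)
            H[:, j] = prev
    return H


def simulate_genotypes(cfg: SimConfig, seed: Optional[int] = None
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotype panel with LD blocks and (optionally) population structure."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pop_labels = np.repeat(np.arange(cfg.n_pops), int(np.ceil(cfg.n / cfg.n_pops)))[: cfg.n]

    # ancestral frequency per block, Balding-Nichols divergence per population
    blocks = cfg.blocks()
    anc = np.zeros(cfg.J)
    for block in blocks:
        anc[block] = rng.uniform(*cfg.maf_range)
    pop_freqs = np.zeros((cfg.n_pops, cfg.J))
    for c in range(cfg.n_pops):
        if cfg.fst > 0:
            F = cfg.fst
            for block in blocks:
                p = anc[block[0]]
                drawn = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
                pop_freqs[c, block] = np.clip(drawn, 0.01, 0.99)
        else:
            pop_freqs[c] = anc

    X = np.zeros((cfg.n, cfg.J))
    for c in range(cfg.n_pops):
        idx = np.where(pop_labels == c)[0]
        if len(idx) == 0:
            continue
        H1 = _haplotypes(cfg, pop_freqs[c], len(idx), rng)
        if cfg.coding == "diploid":
            H2 = _haplotypes(cfg, pop_freqs[c], len(idx), rng)
            X[idx] = H1 + H2
        else:
            X[idx] = H1

    snp_map, _ = _maps(cfg)
    G = GenotypeMatrix(
        X,
        snp_ids=[f"snp{j}" for j in range(cfg.J)],
        sample_ids=[f"s{i}" for i in range(cfg.n)],
        coding=cfg.coding,
        snp_map=snp_map,
    )
    return G, pop_labels


def true_effects(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """The planted (B, A) implied by the configured architecture."""
    B = np.zeros((cfg.J, cfg.K))
    for snps, module, beta in cfg.causal:
        for j in np.atleast_1d(snps):
            B[int(j), cfg.module_genes(int(module))] = beta
    for snp, n_genes, beta in cfg.hotspots:
        B[int(snp), : int(n_genes)] = beta
    A = np.zeros((cfg.K, max(cfg.q, 1)))
    for genes, trait, effect in cfg.gene_to_trait:
        A[np.atleast_1d(genes).astype(int), int(trait)] = effect
    return B, A[:, : cfg.q] if cfg.q else np.zeros((cfg.K, 0))


def simulate_expression(G: GenotypeMatrix, cfg: SimConfig, seed: Optional[int] = None
                        ) -> tuple[TraitMatrix, np.ndarray]:
    """Expression layer: sparse SNP effects + module factors + Gaussian noise."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    B, _ = true_effects(cfg)
    Xc = G.values - G.values.mean(axis=0)
    signal = Xc @ B
    # shared module factor calibrated to the target within-module correlation
    if cfg.module_rho > 0:
        v = cfg.module_rho / (1 - cfg.module_rho) * cfg.noise_sd_y**2
        for m in range(cfg.n_modules):
            f = rng.normal(0.0, 1.0, size=cfg.n)
            signal[:, cfg.module_genes(m)] += np.sqrt(v) * f[:, None]
    Y = signal + rng.normal(0.0, cfg.noise_sd_y, size=(cfg.n, cfg.K))
    _, gene_map = _maps(cfg)
    T = TraitMatrix(
        Y,
        trait_ids=[f"gene{k}" for k in range(cfg.K)],
        sample_ids=list(G.sample_ids),
        kind="expression",
        gene_map=gene_map,
    )
    return T, B


def simulate_traits(Y: TraitMatrix, cfg: SimConfig, seed: Optional[int] = None
                    ) -> tuple[TraitMatrix, np.ndarray]:
    """Clinical layer: Z = Yc A + noise, trait clusters from shared parents."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    _, A = true_effects(cfg)
    Yc = Y.values - Y.values.mean(axis=0)
    Z = Yc @ A + rng.normal(0.0, cfg.noise_sd_z, size=(cfg.n, cfg.q))
    T = TraitMatrix(
        Z,
        trait_ids=[f"trait{t}" for t in range(cfg.q)],
        sample_ids=list(Y.sample_ids),
        kind="clinical",
    )
    return T, A


def simulate_dataset(cfg: SimConfig, seed: Optional[int] = None) -> SimDataset:
    G, pops = simulate_genotypes(cfg, seed)
    Y, B = simulate_expression(G, cfg, seed)
    if cfg.q:
        Z, A = simulate_traits(Y, cfg, seed)
    else:
        Z, A = None, np.zeros((cfg.K, 0))
    truth = GroundTruth(
        B=B,
        A=A,
        pop_labels=pops,
        module_membership=[cfg.module_genes(m) for m in range(cfg.n_modules)],
        config=cfg,
    )
    return SimDataset(genotypes=G, expression=Y, clinical=Z, truth=truth)


# ---------------------------------------------------------------------------
# presets

def yeast_like(seed: int = 0) -> SimConfig:
    """A haploid-cross panel at the scale of a classic yeast segregant study:
    112 segregants, 1260 markers, 200 expression traits in 10 modules."""
    return SimConfig(
        n=112, J=1260, K=200, q=0, coding="haploid",
        block_size=20, ld_rho=0.9, n_modules=10, module_rho=0.6,
        causal=[((j,), m, 0.6) for m, j in enumerate(range(10, 1260, 126))],
        n_chromosomes=16, seed=seed,
    )


def mouse_like(seed: int = 0) -> SimConfig:
    """A diploid outbred-stock panel: 218 mice, 1000 markers, 500 expression
    traits, 50 clinical traits, four populations at Fst 0.2."""
    cfg = SimConfig(
        n=218, J=1000, K=500, q=50, coding="diploid",
        block_size=20, ld_rho=0.9, n_modules=20, module_rho=0.6,
        n_pops=4, fst=0.2, n_chromosomes=19, seed=seed,
    )
    cfg.causal = [((j,), m, 0.6) for m, j in enumerate(range(25, 1000, 50))][: cfg.n_modules]
    cfg.gene_to_trait = [(cfg.module_genes(m), m % cfg.q, 0.3) for m in range(cfg.n_modules)]
    return cfg


def eqtl_benchmark_config(seed: int = 0) -> SimConfig:
    """Support-recovery benchmark: n=200, J=100 (10 LD blocks), K=50 (5
    modules), causal SNPs in 3 blocks each driving one module at beta=1.0
    (a major linkage explaining roughly 10% of expression variance)."""
    return SimConfig(
        n=200, J=100, K=50, q=0, coding="haploid",
        block_size=10, ld_rho=0.8, n_modules=5, module_rho=0.6,
        causal=[((5,), 0, 1.0), ((45,), 1, 1.0), ((85,), 2, 1.0)],
        noise_sd_y=1.0, seed=seed,
    )


def threeway_benchmark_config(seed: int = 0) -> SimConfig:
    """Three-way chain benchmark: a 30-gene trans hotspot plus two
    SNP -> module -> trait chains with strong effects."""
    cfg = SimConfig(
        n=200, J=30, K=40, q=6, coding="haploid",
        block_size=5, ld_rho=0.8, n_modules=4, module_rho=0.5,
        hotspots=[(2, 30, 1.2)],
        causal=[((12,), 3, 1.2), ((22,), 3, 1.2)],
        noise_sd_y=1.0, noise_sd_z=1.0, seed=seed,
    )
    cfg.gene_to_trait = [
        (cfg.module_genes(3), 0, 0.3),
        (cfg.module_genes(3), 1, 0.3),
        (cfg.module_genes(0), 2, 0.3),
    ]
    return cfg
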