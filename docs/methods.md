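# Methods

This note records the models, algorithmic choices, defaults and limitations
of `structmap` — the decisions a maintainer or reviewer would want spelled
out, in the package's own words.

## Data model and preprocessing

Genotypes are allele dosages (0/1 haploid cross, 0/1/2 diploid, optionally
±1) with a 1-based genomic map; missing genotypes are rejected at load —
only trait matrices may carry missingness, and only until imputation.
Trait preprocessing follows common eQTL practice: traits missing in
strictly more than 30% of samples are dropped; remaining holes are filled
by k-nearest-neighbour imputation (default k = 10, capped at n − 1) using
Euclidean distance over mutually observed traits scaled by
`sqrt(K / n_shared)`, neighbour ties broken by sample order. Every design
and response matrix is z-scored per column before a penalized fit (constant
columns are centered and flagged), so a single λ is comparable across
columns; the intercept is handled by centering rather than an explicit
column.

## Penalized models

All solvers minimize ½‖Y − XB‖²_F plus penalties (the ½-Frobenius
convention, not 1/(2n); λ values quoted anywhere in the package are on this
scale). The model zoo and its penalties are listed in the README; the
algorithmic substance:

* **Lasso** — cyclic coordinate descent with covariance updates (X'X and
  X'Y precomputed), each coordinate update vectorized across all trait
  columns. Zeros are exact. Convergence: relative objective change < tol
  (default 1e-6), max 10 000 sweeps.
* **Group lasso / MPGL** — block coordinate descent with *exact* block
  minimization: a block is zeroed when its residual correlation norm is
  ≤ λw_g (the group KKT condition), otherwise the block solves
  (H + (κ/ν)I)b = c with ν = ‖b‖ found from the secular equation
  Σ z_i²/(λ_i ν + κ)² = 1 by bisection. A singleton block degenerates to
  the scalar soft threshold — the same arithmetic as the lasso kernel —
  which is why the singleton-group and single-population reductions agree
  with the lasso to machine precision rather than to a solver tolerance.
  MPGL's loss separates by population, so the row-block Hessian is diagonal
  and the same secular update applies without an eigendecomposition.
* **GFlasso / gGFlasso** — fused coordinate descent. Each fusion term
  |u_e| is majorized by u_e²/(2d_e) + d_e/2 at d_e = |u_e| (floored), which
  leaves a smooth quadratic plus the separable L1 term; cyclic
  soft-threshold sweeps minimize it exactly, then the d's are refreshed
  (majorize–minimize, monotone on the exact objective). Two refinements
  make this route accurate rather than merely fast:
  1. *floor annealing* — the d-floor runs 1e-2 → 1e-4 → 1e-6 → 1e-12 so
     coefficients position themselves on progressively less-smoothed
     problems instead of freezing against a near-infinite stiffness;
  2. *tie gluing* — once a fusion difference collapses below 1e-8, the
     entries join a union-find component (with relative signs) that is
     updated jointly as one variable with the aggregated threshold λ·|S|,
     so strongly fused groups can activate, move and zero out together.
  The sweep kernels are numba-compiled (pure-Python fallback included).
  Against an independent smoothed-continuation convex solver the final
  objectives agree to ~1e-6 relative on random instances.
* **TreeLasso** — smoothing proximal gradient: the non-separable internal-
  node group norms are smoothed in dual form with parameter μ (default
  μ = ε/(2D), ε = 1e-4 gap target, D the dual-ball radius term), leaf
  terms stay exact in the prox, and a monotone FISTA variant minimizes the
  result with μ-continuation (100μ → 10μ → μ, warm-started). The smoothing
  duality gap is bounded by μD. The same engine provides an independent
  second route to GFlasso, which the tests cross-check against the fused-CD
  route.
* **Structured input/output** — FISTA with the exact composite prox of the
  sparse-block-group penalty: entrywise soft threshold by λ₁/L, then
  blockwise group shrinkage by λ₂w_gh/L. Default block weight
  w_gh = √(|g||h|), so 1×1 blocks reduce the model to a lasso at λ₁+λ₂.
* **AMTL** — alternating minimization. The B-step is the same exact-prox
  FISTA with per-SNP penalty scales ρ_j = exp(−θᵀf_j) (L1) and
  ρ'_j = exp(−ηᵀf_j) (trait-group L2). The feature-weight step is gradient
  descent with backtracking on the convex objective
  λ Σ_j ρ_j(θ)‖B_j‖₁ + c Σ_j θᵀf_j, where the linear term is the
  normalization-style regularizer that keeps the scales from collapsing to
  zero; its coefficient c is set to the current mean penalty mass (the
  stationarity point of a Laplace-prior normalizer), so SNPs with large
  coefficients earn below-average penalties and features marking causal
  SNPs acquire positive weights. θ is clipped to [−5, 5] to bound the
  scales. The normalization form is a package choice; alternatives shift
  the absolute scale of θ but not the sign behaviour the tests check.

Coordinate orders are fixed and cyclic; convergence is always a relative
objective-change criterion. Solvers whose iterates cannot produce exact
zeros (the SPG route) zero coefficients below 1e-8 on exit, recorded in the
result's provenance.

## Structural priors

Trait networks: thresholded absolute Pearson correlation (default
threshold 0.5); WGCNA-style soft-power adjacency |r|^β with β the smallest
grid value whose connectivity distribution reaches scale-free fit R² ≥ 0.8
(10 log-spaced bins, least squares of log-frequency on log-connectivity;
argmax-R² fallback with a warning); glasso Markov networks via
`sklearn.covariance.graphical_lasso` with edge weights |partial
correlation|. Edge weights are magnitudes; the correlation sign is stored
separately and used only by the optional signed-fusion mode (default
unsigned, since fusion on |r| is the more conservative convention and the
signed variant can be toggled per fit).

Trees: scipy average-linkage agglomeration of 1 − |r| (or 1 − edge weight).
The node-weight scheme is pluggable; the default maps a merge at normalized
height h to weight 1 − h/h_max, so tight clusters are grouped strongly.

Modules: a dynamic program over tree cuts selects at most M disjoint
subtree nodes of size ≥ min_size. The DP value of a node is its *size-
weighted* mean intra-module edge weight (missing pairs count as zero) with
a tiny size² tie-break; the plain mean would provably prefer a module's
tight sub-core over the module itself, and the tie-break settles exact-tie
cases such as perfect cliques. Reported module scores are the plain mean.

Enrichment: one-sided hypergeometric upper tail per term with
Benjamini–Hochberg q-values across terms; the universe defaults to all
annotated traits, and the identical machinery serves eQTL enrichment with
"term" = a SNP's associated-gene set. Terms are flat sets — no ontology
DAG propagation.

## Baseline tests and population structure

Single-marker tests: Wald (squared slope/SE against χ²₁), Welch t between
dosage classes 0 vs > 0, Gaussian likelihood ratio n·log(SST/SSE) against
χ²₁, and the allelic contingency χ² for binary traits. Raw p < 1e-3 flags
"significant" (the classic naive screen); BH q-values are reported
alongside. Monomorphic SNPs are flagged, not computed.

Population structure is estimated by genotype eigen-analysis — top five
eigenvectors of the standardized-genotype covariance, deterministic sign
convention (largest-magnitude coordinate positive) — followed by k-means
with 20 restarts and a fixed seed, labels canonicalized by cluster size.
This PCA+k-means stand-in reproduces the analytical surface (eigenvector
coordinates, discrete labels) that model-based ancestry tools feed into the
comparison of per-population associations; external assignments can be
supplied instead. Heterogeneity of a SNP effect across populations is the
genotype × population interaction F-test in the pooled linear model,
labelled as such in output provenance.

## Synthetic data

The generator produces the structures the methods exploit, with exact
ground truth: Balding–Nichols per-population allele frequencies at a
configured Fst (frequencies constant within an LD block), haplotypes from a
first-order Markov copy process (adjacent correlation ≈ the copy
probability ρ), expression as sparse centred-genotype effects plus a module
factor whose variance is set so the within-module correlation matches the
target (r = v/(v+σ²)), and clinical traits as a second linear layer plus
noise. It does *not* emulate coalescent-accurate LD decay, epistasis,
ascertainment, batch effects or non-Gaussian expression noise — so passing
recovery benchmarks demonstrate correct behaviour under the assumed model,
not performance guarantees on real data.

Benchmark presets (the package's standard evaluation conditions):

* *eQTL support recovery* — n=200, J=100 (blocks of 10, ρ=0.8), K=50 (5
  modules, within-module r=0.6), three causal SNPs each driving one module
  at β=1.0 (≈10% of expression variance, the scale of a major cross eQTL),
  σ_Y=1.
* *three-way chains* — n=200, J=30, K=40 (4 modules), q=6, a 30-gene trans
  hotspot and two SNP→module→trait chains at β=1.2 with per-gene trait
  loadings 0.3.
* *stratification* — n=200, J=200 independent markers, four populations at
  Fst=0.2.
* yeast-like (n=112, J=1260, haploid) and mouse-like (n=218, J=1000,
  K=500, q=50, diploid, four populations) presets ship for larger-scale
  demonstration.

Benchmark analysis choices: support is called at |β| > 1e-3, applied
identically to every method compared; the three-way benchmark selects its
λ's by the one-standard-error CV rule (the fits feed support statements),
counts chains at merged-region resolution (the 2 Mb rule makes markers in
tight LD exchangeable proxies) after screening each region's representative
SNP at the p < 1e-3 convention, and credits hotspot detection to any marker
of the planted hotspot's LD block. Cross-validation defaults to the
error-minimizing rule with ties broken toward the stronger penalty; CV
error is the held-out squared error per matrix entry, averaged over folds
(and hence over traits, keeping the criterion comparable across trait-set
sizes).

## Numerical choices and degenerate inputs

Convergence tolerances default to 1e-6 relative objective change (CV fits
use 1e-4 — model selection does not need more); the fused solvers' d-floor
bottoms at 1e-12 and ties glue below 1e-8; the secular root is bracketed in
the well-conditioned form Σ z²/(λν+κ)² = 1. Degenerate cases: constant
genotype columns get zero coefficients; zero-variance traits are excluded
from networks with a warning; populations with zero trait variance are
excluded from MPGL; a single-leaf tree reduces TreeLasso to a single-trait
lasso; an empty fusion graph reduces GFlasso/gGFlasso to the lasso (with a
warning when γ > 0); frustrated sign cycles in signed fusion are left
unglued.

## Known limitations

No p-values are attached to the penalized fits (significance machinery
covers only the single-marker tests); overlapping groups are not supported;
the fusion solvers return a glued tie as exactly tied even when the true
optimum separates the pair by less than the tie threshold (error bounded by
the threshold); the soft-power β search warns rather than fails when no
grid value reaches the scale-free target, which is common on strongly
modular simulated data; the CLI covers the standard pipeline paths while
group-structured models (group lasso, structured I/O, AMTL) are
library-only, since their group definitions are analysis-specific objects.
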