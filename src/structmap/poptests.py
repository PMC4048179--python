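"""Single-marker association tests and population-stratified analysis.

Baseline PLINK-style tests per (SNP, trait) pair:

* ``wald`` — squared slope / SE from simple linear regression, referred to
  chi-square with 1 df;
* ``ttest`` — two-sided Welch t between genotype classes (dosage 0 vs > 0);
* ``lrt``  — Gaussian likelihood ratio of the one-SNP model against the
  intercept-only model, 2 * (l_full - l_null) ~ chi-square(1);
* ``chisq`` — allelic contingency chi-square for binary traits.

Population structure is handled by genotype eigen-analysis (top five
eigenvectors of the standardized-genotype covariance) followed by k-means —
a PCA stand-in for model-based ancestry assignment whose analytical surface
(eigenvector coordinates, discrete labels) matches what the stratified
association comparison needs.  Heterogeneity of a SNP effect across
populations is assessed by the genotype x population interaction F-test in
a pooled linear model.

Convention: raw p < 1e-3 flags an association "significant" (the classic
naive screen); BH-adjusted q-values are also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import standardize

__all__ = [
    "TestResult",
    "PopulationAssignment",
    "single_marker_test",
    "association_scan",
    "genotype_pca",
    "assign_populations",
    "per_population_association",
    "SIGNIFICANCE_P",
]

SIGNIFICANCE_P = 1e-3


@dataclass
class TestResult:
    statistic: float
    p: float
    test: str
    population: str = "pooled"
    computed: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.computed and self.p < SIGNIFICANCE_P


@dataclass
class PopulationAssignment:
    labels: np.ndarray  # per-sample population label, 0..C-1
    eigvecs: np.ndarray  # n x (<=5) eigenvector coordinates
    eigvals: np.ndarray
    method: str = "kmeans_pca"
    params: dict = field(default_factory=dict)

    @property
    def n_populations(self) -> int:
        return int(len(np.unique(self.labels)))


def _simple_regression(x: np.ndarray, y: np.ndarray):
    """Slope, SE and residual stats of y ~ 1 + x."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return None
    b = float(xc @ yc) / sxx
    resid = yc - b * xc
    sse = float(resid @ resid)
    df = n - 2
    se2 = sse / df / sxx if df > 0 else np.nan
    return b, np.sqrt(se2), sse, float(yc @ yc), df


def single_marker_test(x: np.ndarray, y: np.ndarray, test: str = "wald",
                       population: str = "pooled") -> TestResult:
    """Test association of one SNP dosage vector against one trait."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        return TestResult(np.nan, np.nan, test, population, computed=False,
                          note="monomorphic SNP")
    if test == "wald":
        fit = _simple_regression(x, y)
        if fit is None:
            return TestResult(np.nan, np.nan, test, population, computed=False)
        b, se, *_ = fit
        stat = (b / se) ** 2
        p = float(stats.chi2.sf(stat, df=1))
    elif test == "lrt":
        fit = _simple_regression(x, y)
        if fit is None:
            return TestResult(np.nan, np.nan, test, population, computed=False)
        *_, sse, sst, df = fit
        n = len(x)
        stat = n * np.log(sst / sse) if sse > 0 else np.inf
        p = float(stats.chi2.sf(stat, df=1))
    elif test == "ttest":
        g0 = y[x == 0]
        g1 = y[x > 0]
        if len(g0) < 2 or len(g1) < 2:
            return TestResult(np.nan, np.nan, test, population, computed=False,
                              note="a genotype class has < 2 samples")
        stat, p = stats.ttest_ind(g0, g1, equal_var=False)
        stat, p = float(stat), float(p)
    elif test == "chisq":
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("chisq requires a binary trait")
        # allelic 2 x 2 table: allele counts by case/control
        max_dose = x.max()
        table = np.zeros((2, 2))
        for ci, cls in enumerate(classes):
            sub = x[y == cls]
            table[ci, 0] = sub.sum()                    # minor alleles
            table[ci, 1] = len(sub) * max_dose - sub.sum()  # major alleles
        if (table.sum(axis=0) == 0).any():
            return TestResult(np.nan, np.nan, test, population, computed=False)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        stat, p = float(stat), float(p)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(float(stat), p, test, population)


def association_scan(X: np.ndarray, Y: np.ndarray, test: str = "wald",
                     snp_ids=None, trait_ids=None) -> pd.DataFrame:
    """All-pairs single-marker scan with BH q-values across the whole scan."""
    from statsmodels.stats.multitest import multipletests

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    J, K = X.shape[1], Y.shape[1]
    snp_ids = snp_ids or [f"snp{j}" for j in range(J)]
    trait_ids = trait_ids or [f"trait{k}" for k in range(K)]
    rows = []
    for j in range(J):
        for k in range(K):
            r = single_marker_test(X[:, j], Y[:, k], test=test)
            rows.append({"snp": snp_ids[j], "trait": trait_ids[k],
                         "stat": r.statistic, "p": r.p, "computed": r.computed})
    df = pd.DataFrame(rows)
    ok = df["computed"] & df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = multipletests(df.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = ok & (df["p"] < SIGNIFICANCE_P)
    return df


def genotype_pca(X: np.ndarray, n_components: int = 5):
    """Top eigenvectors/eigenvalues of the standardized-genotype covariance.

    Sign convention: each eigenvector's largest-magnitude coordinate is made
    positive, so the output is invariant to sample order up to that sign.
    Returns ``(eigvecs (n x k), eigvals (k,))``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xs, flags = standardize(X, mode="zscore")
    if flags.all():
        raise ValueError("all genotype columns have zero variance")
    k = min(n_components, n - 1)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    eigvals = (s**2) / (n - 1)
    eigvecs = U[:, :k]
    eigvals = eigvals[:k]
    for i in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, i]))
        if eigvecs[j, i] < 0:
            eigvecs[:, i] = -eigvecs[:, i]
    return eigvecs, eigvals


def assign_populations(eigvecs: np.ndarray, C: int, seed: int = 0,
                       eigvals: Optional[np.ndarray] = None) -> PopulationAssignment:
    """k-means on the top eigenvector coordinates, 20 restarts, fixed seed.

    Labels are canonicalized by decreasing cluster size (ties by first
    occurrence), so the same seed always yields the identical assignment.
    """
    from sklearn.cluster import KMeans

    eigvecs = np.asarray(eigvecs, dtype=float)
    n = eigvecs.shape[0]
    if C < 1:
        raise ValueError("C must be >= 1")
    if C > n:
        raise ValueError("more populations than samples")
    if C == 1:
        raw = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=C, n_init=20, random_state=seed)
        raw = km.fit_predict(eigvecs)
    # canonicalize: relabel by decreasing cluster size, then first occurrence
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    return PopulationAssignment(
        labels=labels,
        eigvecs=eigvecs,
        eigvals=np.asarray(eigvals) if eigvals is not None else np.array([]),
        method="kmeans_pca",
        params={"C": C, "seed": seed, "n_init": 20},
    )


def per_population_association(
    x: np.ndarray,
    y: np.ndarray,
    pops: np.ndarray,
    test: str = "wald",
    min_pop_size: int = 3,
) -> dict:
    """Per-population single-marker tests plus an across-population
    heterogeneity F-test (genotype x population interaction in the pooled
    linear model y ~ population + genotype + genotype:population).

    Populations below ``min_pop_size`` are skipped with a warning; with a
    single usable population the heterogeneity test is flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pops = np.asarray(pops)
    labels = list(np.unique(pops))
    per_pop: dict = {}
    used = []
    for p in labels:
        mask = pops == p
        if mask.sum() < min_pop_size:
            warnings.warn(f"population {p!r} below size floor {min_pop_size}; skipped")
            continue
        per_pop[str(p)] = single_marker_test(x[mask], y[mask], test=test,
                                             population=str(p))
        used.append(p)

    het_p = np.nan
    het_stat = np.nan
    het_defined = len(used) >= 2
    if het_defined:
        mask = np.isin(pops, used)
        xs, ys, ps = x[mask], y[mask], pops[mask]
        C = len(used)
        # full design: per-population intercepts and slopes
        D_full = np.zeros((len(xs), 2 * C))
        for c, p in enumerate(used):
            m = ps == p
            D_full[m, c] = 1.0
            D_full[m, C + c] = xs[m]
        # reduced design: per-population intercepts, common slope
        D_red = np.column_stack([D_full[:, :C], xs])
        sse_full = _sse(D_full, ys)
        sse_red = _sse(D_red, ys)
        df1 = C - 1
        df2 = len(xs) - 2 * C
        if df2 > 0 and sse_full > 0:
            het_stat = ((sse_red - sse_full) / df1) / (sse_full / df2)
            het_p = float(stats.f.sf(het_stat, df1, df2))
    return {
        "per_population": per_pop,
        "heterogeneity_stat": float(het_stat),
        "heterogeneity_p": float(het_p),
        "heterogeneity_defined": het_defined,
        "populations_used": [str(p) for p in used],
    }


def _sse(D: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ coef
    return float(r @ r)


def genotype_frequency_table(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Genotype-class counts by binary trait value (reporting utility)."""
    x = np.asarray(x)
    y = np.asarray(y)
    rows = []
    for cls in np.unique(y):
        sub = x[y == cls]
        counts = pd.Series(sub).value_counts().sort_index()
        rows.append({"trait_value": cls, **{f"dose_{g:g}": int(c) for g, c in counts.items()}})
    return pd.DataFrame(rows).fillna(0)
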