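"""Trait relevance networks: correlation, soft-power (scale-free) and glasso.

A :class:`TraitNetwork` is an undirected weighted graph over trait ids whose
edge weights guide the fusion penalties of the structured solvers.  Weights
are absolute correlations (or powers / partial correlations thereof) in
[0, 1]; the correlation sign is kept separately so the signed fusion variant
can flip coefficients across negatively correlated traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import TraitMatrix

__all__ = [
    "TraitNetwork",
    "correlation_network",
    "softpower_network",
    "glasso_network",
    "network_overlap",
    "scale_free_fit",
]


@dataclass
class TraitNetwork:
    """Undirected weighted relevance graph over traits.

    Each edge carries ``weight`` in [0, 1] (magnitude used by fusion
    penalties) and ``sign`` in {-1, +1} (used only in signed-fusion mode).
    """

    graph: nx.Graph
    builder: str = "correlation"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-edges are not allowed")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight", None)
            if w is None or not (0 <= w <= 1 + 1e-12):
                raise ValueError(f"edge ({u},{v}) weight {w} outside [0,1]")
            d.setdefault("sign", 1.0)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_arrays(self, node_order: Sequence[str]) -> tuple[np.ndarray, ...]:
        """Edges as index arrays (i, j, weight, sign) against ``node_order``."""
        idx = {t: i for i, t in enumerate(node_order)}
        ii, jj, ww, ss = [], [], [], []
        for u, v, d in self.graph.edges(data=True):
            if u in idx and v in idx:
                ii.append(idx[u])
                jj.append(idx[v])
                ww.append(d["weight"])
                ss.append(d.get("sign", 1.0))
        return (
            np.array(ii, dtype=int),
            np.array(jj, dtype=int),
            np.array(ww, dtype=float),
            np.array(ss, dtype=float),
        )

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["weight"], d.get("sign", 1.0))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "weight", "sign"])

    @classmethod
    def from_edges(
        cls,
        nodes: Iterable[str],
        edges: Iterable[tuple],
        builder: str = "external",
        params: Optional[dict] = None,
    ) -> "TraitNetwork":
        """Build from (u, v, weight[, sign]) tuples."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v, w = e[0], e[1], float(e[2])
            s = float(e[3]) if len(e) > 3 else 1.0
            g.add_edge(u, v, weight=w, sign=s)
        return cls(g, builder=builder, params=params or {})


def _correlations(Y: TraitMatrix) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pearson correlation matrix; zero-variance traits excluded with warning."""
    V = Y.values
    if np.isnan(V).any():
        raise ValueError("trait matrix has missing values; impute first")
    sd = V.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [t for t, k in zip(Y.trait_ids, keep) if not k]
        warnings.warn(f"excluding zero-variance trait(s): {dropped[:5]}")
    ids = [t for t, k in zip(Y.trait_ids, keep) if k]
    R = np.corrcoef(V[:, keep], rowvar=False)
    R = np.atleast_2d(R)
    return R, ids, keep


def correlation_network(
    Y: TraitMatrix, threshold: float = 0.5, signed: bool = False
) -> TraitNetwork:
    """Threshold the absolute pairwise Pearson correlation matrix.

    Edge (i, j) is kept iff |r_ij| >= threshold; the edge weight is |r_ij|
    and the correlation sign is stored alongside.
    """
    if Y.n < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    R, ids, _ = _correlations(Y)
    g = nx.Graph()
    g.add_nodes_from(ids)
    K = len(ids)
    for i in range(K):
        for j in range(i + 1, K):
            w = abs(R[i, j])
            if w >= threshold:
                g.add_edge(ids[i], ids[j], weight=min(w, 1.0), sign=float(np.sign(R[i, j]) or 1.0))
    return TraitNetwork(g, builder="correlation", params={"threshold": threshold, "signed": signed})


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution regression (scale-free index).

    Node connectivities (row sums of the adjacency, self term excluded) are
    binned into ``n_bins`` equal-width bins on the log scale; R^2 comes from
    least squares of log10(frequency) on log10(mean connectivity per bin).
    """
    k = adjacency.sum(axis=1) - adjacency.diagonal()
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()) + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def softpower_network(
    Y: TraitMatrix,
    beta_grid: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    min_weight: float = 1e-6,
) -> TraitNetwork:
    """Soft-thresholding (WGCNA-style) co-expression network.

    Adjacency a_ij = |r_ij|^beta with beta the smallest grid value whose
    degree distribution reaches the scale-free fit ``r2_target``; if none
    does, the argmax-R^2 beta is used with a warning.  Edges below
    ``min_weight`` are dropped from the stored graph (the adjacency is dense
    in principle; tiny weights carry no information for fusion penalties).
    """
    if any(int(b) <= 0 for b in beta_grid):
        raise ValueError("beta_grid must contain positive integers")
    R, ids, _ = _correlations(Y)
    A0 = np.abs(R)
    np.fill_diagonal(A0, 0.0)
    r2s = {}
    chosen = None
    for b in beta_grid:
        r2s[int(b)] = scale_free_fit(A0 ** int(b) + np.eye(len(ids)) * 0)
        if r2s[int(b)] >= r2_target:
            chosen = int(b)
            break
    if chosen is None:
        chosen = max(r2s, key=r2s.get)
        warnings.warn(
            f"no beta in grid reached scale-free R^2 {r2_target}; "
            f"using argmax beta={chosen} (R^2={r2s[chosen]:.3f})"
        )
    A = A0 ** chosen
    g = nx.Graph()
    g.add_nodes_from(ids)
    K = len(ids)
    for i in range(K):
        for j in range(i + 1, K):
            if A[i, j] >= min_weight:
                g.add_edge(ids[i], ids[j], weight=min(A[i, j], 1.0),
                           sign=float(np.sign(R[i, j]) or 1.0))
    return TraitNetwork(
        g,
        builder="softpower",
        params={"beta": chosen, "r2": r2s[chosen], "r2_target": r2_target, "r2_by_beta": r2s},
    )


def glasso_network(Y: TraitMatrix, rho: float) -> TraitNetwork:
    """Markov network from the L1-penalized Gaussian inverse covariance.

    Edges are the non-zeros of the glasso precision estimate on the trait
    correlation matrix; the edge weight is the absolute partial correlation.
    """
    from sklearn.covariance import graphical_lasso

    if Y.n <= 3:
        raise ValueError("need more than 3 samples for glasso")
    K_all = Y.n_traits
    if rho <= 0:
        if K_all >= Y.n:
            raise ValueError("rho must be > 0 when K >= n")
        raise ValueError("rho must be > 0")
    R, ids, _ = _correlations(Y)
    _, precision = graphical_lasso(R, alpha=rho, max_iter=500, tol=1e-8)
    g = nx.Graph()
    g.add_nodes_from(ids)
    d = np.sqrt(np.diag(precision))
    K = len(ids)
    for i in range(K):
        for j in range(i + 1, K):
            if abs(precision[i, j]) > 1e-10:
                pc = -precision[i, j] / (d[i] * d[j])
                g.add_edge(ids[i], ids[j], weight=min(abs(pc), 1.0),
                           sign=float(np.sign(pc) or 1.0))
    return TraitNetwork(g, builder="glasso", params={"rho": rho})


def network_overlap(netA: TraitNetwork, netB: TraitNetwork) -> dict[str, float]:
    """Percentage of A's nodes and edges present in B (unordered id pairs)."""
    nodes_a = set(netA.graph.nodes)
    nodes_b = set(netB.graph.nodes)
    edges_a = {frozenset(e) for e in netA.graph.edges}
    edges_b = {frozenset(e) for e in netB.graph.edges}
    pct_nodes = 100.0 * len(nodes_a & nodes_b) / len(nodes_a) if nodes_a else 0.0
    pct_edges = 100.0 * len(edges_a & edges_b) / len(edges_a) if edges_a else 0.0
    return {"pct_shared_nodes": pct_nodes, "pct_shared_edges": pct_edges}
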