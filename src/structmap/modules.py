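"""Gene-module discovery by dynamic programming over tree cuts.

Given a hierarchical trait tree and a relevance network, the connectivity
score of a tree node is the mean edge weight over all trait pairs inside its
member set (absent edges count as weight zero, so loose agglomerations score
poorly).  A dynamic program over the tree picks at most M non-nested nodes
of size >= min_size maximizing the total score — the "top M connected
modules" of a co-expression analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .networks import TraitNetwork
from .trees import TraitTree, TreeNode

__all__ = ["Module", "ModuleSet", "extract_modules", "module_score"]


@dataclass
class Module:
    members: frozenset
    score: float


@dataclass
class ModuleSet:
    modules: list[Module]
    target_count: int
    min_size: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in range(len(self.modules)):
            for b in range(a + 1, len(self.modules)):
                if self.modules[a].members & self.modules[b].members:
                    raise ValueError("modules must be disjoint")
        scores = [m.score for m in self.modules]
        if any(s1 < s2 for s1, s2 in zip(scores, scores[1:])):
            raise ValueError("module scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.modules)

    def member_lists(self) -> list[list[str]]:
        return [sorted(m.members) for m in self.modules]


def module_score(members: frozenset, net: TraitNetwork) -> float:
    """Mean edge weight over all pairs inside ``members`` (missing pairs = 0)."""
    m = sorted(members)
    k = len(m)
    if k < 2:
        return 0.0
    total = 0.0
    g = net.graph
    for i in range(k):
        for j in range(i + 1, k):
            if g.has_edge(m[i], m[j]):
                total += g[m[i]][m[j]]["weight"]
    return total / (k * (k - 1) / 2)


def extract_modules(
    tree: TraitTree, net: TraitNetwork, M: int = 20, min_size: int = 3
) -> ModuleSet:
    """Select the top ``M`` disjoint connected modules by tree-cut DP.

    Returns fewer than M modules (with a warning) when the tree does not
    contain M disjoint subtrees of size >= min_size.
    """
    if M < 1:
        raise ValueError("M must be >= 1")

    scores: dict[int, float] = {}

    def node_score(v: TreeNode) -> float:
        if v.id not in scores:
            scores[v.id] = module_score(v.members, net)
        return scores[v.id]

    def dp_value(v: TreeNode) -> float:
        # size-weighted mean (total connectivity mass per member pair count):
        # a whole coherent module outranks any of its tight sub-cores, which a
        # plain mean would favor.  The tiny size^2 term breaks exact ties
        # (e.g. perfect cliques, where any sub-clique also has mean weight 1)
        # toward the whole module rather than its split halves.
        k = len(v.members)
        return node_score(v) * k + 1e-9 * k * k

    # best(v, m): max total score choosing exactly m disjoint qualifying
    # subtree nodes within v's subtree; None when infeasible.
    def best(v: TreeNode) -> list[tuple[float, list[TreeNode]] | None]:
        out: list[tuple[float, list[TreeNode]] | None] = [(0.0, [])] + [None] * M
        if not v.children:
            child_tables = []
        else:
            child_tables = [best(c) for c in v.children]
            # combine children by convolution
            combined: list[tuple[float, list[TreeNode]] | None] = child_tables[0][:]
            for tab in child_tables[1:]:
                new: list[tuple[float, list[TreeNode]] | None] = [None] * (M + 1)
                for m1 in range(M + 1):
                    if combined[m1] is None:
                        continue
                    for m2 in range(M + 1 - m1):
                        if tab[m2] is None:
                            continue
                        cand = combined[m1][0] + tab[m2][0]
                        if new[m1 + m2] is None or cand > new[m1 + m2][0]:
                            new[m1 + m2] = (cand, combined[m1][1] + tab[m2][1])
                combined = new
            for m in range(1, M + 1):
                if combined[m] is not None:
                    out[m] = combined[m]
        if len(v.members) >= min_size:
            s = dp_value(v)
            if out[1] is None or s > out[1][0]:
                out[1] = (s, [v])
        return out

    table = best(tree.root)
    chosen: list[TreeNode] = []
    for m in range(M, 0, -1):
        if table[m] is not None:
            chosen = table[m][1]
            break
    if len(chosen) < M:
        warnings.warn(
            f"only {len(chosen)} disjoint subtree(s) of size >= {min_size}; "
            f"requested {M}"
        )
    mods = sorted(
        (Module(members=v.members, score=node_score(v)) for v in chosen),
        key=lambda mo: -mo.score,
    )
    return ModuleSet(
        modules=mods,
        target_count=M,
        min_size=min_size,
        provenance={"method": "tree_cut_dp", "network_builder": net.builder},
    )
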