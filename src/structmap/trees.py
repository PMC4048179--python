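"""Hierarchical trait trees for the tree-guided group lasso.

A :class:`TraitTree` is a rooted binary tree over trait ids built by
agglomerative clustering of a dissimilarity (1 - |correlation|, or
1 - edge weight on a network).  Each internal node carries the trait set of
its subtree, the merge height, and a penalty weight used by the tree-guided
group lasso; leaves carry unit weight by default.  The node-weighting scheme
is pluggable (it is recorded in the tree's provenance) — the default maps a
merge at normalized height h to weight 1 - h, so tight clusters are grouped
strongly and loose ones barely at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .datatypes import TraitMatrix
from .networks import TraitNetwork

__all__ = ["TreeNode", "TraitTree", "hclust_tree", "default_node_weight"]


@dataclass
class TreeNode:
    id: int
    members: frozenset
    height: float
    weight: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def default_node_weight(height: float, max_height: float) -> float:
    """Weight 1 - h/h_max for internal nodes: tighter cluster, stronger group."""
    if max_height <= 0:
        return 1.0
    return max(0.0, 1.0 - height / max_height)


@dataclass
class TraitTree:
    """Rooted binary tree over traits with per-node group weights."""

    root: TreeNode
    leaf_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        leaves = {t for t in self.leaf_ids}
        if self.root.members != frozenset(leaves):
            raise ValueError("root members must equal the leaf set")
        self._check_partition(self.root)

    def _check_partition(self, node: TreeNode) -> None:
        if node.children:
            union = frozenset().union(*(c.members for c in node.children))
            sizes = sum(len(c.members) for c in node.children)
            if union != node.members or sizes != len(node.members):
                raise ValueError("child member sets must partition the parent's")
            for c in node.children:
                self._check_partition(c)

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [v for v in self.nodes() if not v.is_leaf]

    def leaves(self) -> list[TreeNode]:
        return [v for v in self.nodes() if v.is_leaf]

    def to_newick(self) -> str:
        """Newick string; internal labels carry the penalty weight."""

        def fmt(v: TreeNode) -> str:
            if v.is_leaf:
                (tid,) = v.members
                return f"{tid}:{v.height:.6g}"
            inner = ",".join(fmt(c) for c in v.children)
            return f"({inner})'w={v.weight:.6g}':{v.height:.6g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "TraitTree":
        """Parse a newick string whose internal labels carry ``w=<weight>``."""
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=False)
        counter = [0]

        def convert(node) -> TreeNode:
            nid = counter[0]
            counter[0] += 1
            children = [convert(c) for c in node.child_nodes()]
            height = float(node.edge.length or 0.0)
            if children:
                label = (node.taxon.label if node.taxon else node.label) or ""
                weight = 1.0
                if label.startswith("w="):
                    weight = float(label[2:])
                members = frozenset().union(*(c.members for c in children))
                return TreeNode(id=nid, members=members, height=height,
                                weight=weight, children=children)
            label = node.taxon.label if node.taxon else node.label
            return TreeNode(id=nid, members=frozenset([label]), height=height,
                            weight=1.0)

        root = convert(dt.seed_node)
        return cls(root, leaf_ids=sorted(root.members),
                   provenance={"source": "newick"})


def _dissimilarity_from_traits(Y: TraitMatrix) -> tuple[np.ndarray, list[str]]:
    V = Y.values
    if np.isnan(V).any():
        raise ValueError("trait matrix has missing values; impute first")
    R = np.corrcoef(V, rowvar=False)
    D = 1.0 - np.abs(np.atleast_2d(R))
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0), list(Y.trait_ids)


def _dissimilarity_from_network(net: TraitNetwork) -> tuple[np.ndarray, list[str]]:
    ids = net.nodes
    K = len(ids)
    D = np.ones((K, K))
    np.fill_diagonal(D, 0.0)
    idx = {t: i for i, t in enumerate(ids)}
    for u, v, d in net.graph.edges(data=True):
        D[idx[u], idx[v]] = D[idx[v], idx[u]] = 1.0 - d["weight"]
    return D, ids


def hclust_tree(
    data: Union[TraitMatrix, TraitNetwork],
    linkage: str = "average",
    weight_fn: Optional[Callable[[float, float], float]] = None,
) -> TraitTree:
    """Agglomerative tree from traits (1 - |correlation|) or a network
    (1 - edge weight), average linkage by default."""
    if isinstance(data, TraitMatrix):
        D, ids = _dissimilarity_from_traits(data)
        source = "traits"
    else:
        D, ids = _dissimilarity_from_network(data)
        source = "network"
    K = len(ids)
    if K < 2:
        raise ValueError("need at least 2 traits")
    Z = sch.linkage(ssd.squareform(D, checks=False), method=linkage)
    max_h = float(Z[:, 2].max()) if len(Z) else 1.0
    wfn = weight_fn or default_node_weight

    nodes: dict[int, TreeNode] = {
        i: TreeNode(id=i, members=frozenset([ids[i]]), height=0.0, weight=1.0)
        for i in range(K)
    }
    for step, (a, b, h, _) in enumerate(Z):
        nid = K + step
        left, right = nodes[int(a)], nodes[int(b)]
        nodes[nid] = TreeNode(
            id=nid,
            members=left.members | right.members,
            height=float(h),
            weight=float(wfn(float(h), max_h)),
            children=[left, right],
        )
    root = nodes[K + len(Z) - 1]
    return TraitTree(
        root,
        leaf_ids=ids,
        provenance={"linkage": linkage, "source": source,
                    "weight_scheme": getattr(wfn, "__name__", "custom")},
    )
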