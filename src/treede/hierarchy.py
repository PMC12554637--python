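"""Cell-type tree: construction from DE-statistic correlation, and newick IO.

Cell types whose genes respond similarly to the tested factor get correlated
DE states.  That correlation structure is summarized by a rooted tree whose
leaves are cell types: an internal node stands for the event "at least one
descendant type is DE".  The tree is built by agglomerative clustering of
``distance(k1, k2) = (1 - cor(tstat_k1, tstat_k2)) / 2``, or supplied by the
user as newick.

Each node can carry two probabilities used by the prior model:

``pi``
    the marginal probability the node's state is 1, and
``p``
    the probability the node is 1 given its parent is 1 (a node whose parent
    is 0 is 0 with probability 1).
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .screening import ScreenResult

__all__ = [
    "TreeNode",
    "CellTypeTree",
    "select_informative_genes",
    "compute_distance_matrix",
    "build_tree",
]

DEFAULT_TSTAT_THRESHOLD = 2.58  # two-sided normal critical value at p = .01


class TreeNode:
    """A node of the cell-type tree; leaves are labeled with cell types."""

    __slots__ = ("label", "children", "pi", "p", "height")

    def __init__(self, label=None, children=None, pi=None, p=None, height=0.0):
        self.label = label
        self.children: list[TreeNode] = children or []
        self.pi = pi  # marginal P(state = 1)
        self.p = p  # P(state = 1 | parent = 1)
        self.height = height

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset:
        """The descendant-leaf set of this node (its Phi set)."""
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaf_labels() for c in self.children))

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.label, [c.copy() for c in self.children], self.pi, self.p, self.height
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = self.label if self.is_leaf else "+".join(sorted(map(str, self.leaf_labels())))
        return f"TreeNode({tag}, pi={self.pi}, p={self.p})"


class CellTypeTree:
    """Rooted tree over K cell types with optional per-node (pi, p) priors."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.root.preorder() if n.is_leaf]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dupes}")
        for node in self.root.preorder():
            if not node.is_leaf:
                child_sets = [c.leaf_labels() for c in node.children]
                union = frozenset().union(*child_sets)
                if union != node.leaf_labels() or sum(map(len, child_sets)) != len(union):
                    raise ValueError("children leaf sets must partition the parent's")

    # -- structure ---------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        """Leaf labels in deterministic (left-to-right) order."""
        return [n.label for n in self.root.preorder() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    def parent_map(self) -> dict[int, TreeNode]:
        out = {}
        for node in self.root.preorder():
            for c in node.children:
                out[id(c)] = node
        return out

    def copy(self) -> "CellTypeTree":
        return CellTypeTree(self.root.copy())

    def has_priors(self) -> bool:
        return self.root.pi is not None and all(
            n.p is not None for n in self.root.preorder() if n is not self.root
        )

    # -- prior arithmetic --------------------------------------------------
    def _path(self, label: str) -> list[TreeNode]:
        def rec(node):
            if node.is_leaf:
                return [node] if node.label == label else None
            for c in node.children:
                sub = rec(c)
                if sub is not None:
                    return [node] + sub
            return None

        path = rec(self.root)
        if path is None:
            raise KeyError(f"no leaf labeled {label!r}")
        return path

    def leaf_marginal(self, label: str) -> float:
        """P(leaf state = 1): root pi times inheritance probs down the path."""
        path = self._path(label)
        prob = path[0].pi
        for node in path[1:]:
            prob *= node.p
        return prob

    def pairwise_overlap(self, a: str, b: str) -> float:
        """P(Z_a = 1, Z_b = 1) / P(Z_a = 1), by path products through the LCA.

        Below their lowest common ancestor the two lineages are independent
        given the LCA is on, so the joint is marginal(LCA) times both branch
        products; the ratio leaves the b-branch product times the part of the
        a-path below the LCA cancelled out.
        """
        pa, pb = self._path(a), self._path(b)
        shared = 0
        while shared < min(len(pa), len(pb)) and pa[shared] is pb[shared]:
            shared += 1
        lca_marg = pa[0].pi
        for node in pa[1:shared]:
            lca_marg *= node.p
        branch_a = np.prod([n.p for n in pa[shared:]])
        branch_b = np.prod([n.p for n in pb[shared:]])
        joint = lca_marg * branch_a * branch_b
        return joint / self.leaf_marginal(a)

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(node):
            if node.is_leaf:
                return str(node.label)
            return "(" + ",".join(rec(c) for c in node.children) + ")"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, expected_labels=None) -> "CellTypeTree":
        """Parse a newick string; branch lengths and internal labels ignored.

        When ``expected_labels`` is given, the leaf set must match it exactly
        (each label once); mismatches are listed in the error.
        """
        try:
            dt = dendropy.Tree.get(file=io.StringIO(text), schema="newick")
        except Exception as exc:  # dendropy has its own exception hierarchy
            raise ValueError(f"could not parse newick (duplicate or malformed labels?): {exc}")

        def convert(dnode) -> TreeNode:
            kids = dnode.child_nodes()
            if not kids:
                return TreeNode(label=dnode.taxon.label if dnode.taxon else dnode.label)
            return TreeNode(children=[convert(c) for c in kids])

        tree = cls(convert(dt.seed_node))
        if expected_labels is not None:
            got, want = set(tree.leaves), set(expected_labels)
            if got != want:
                raise ValueError(
                    f"newick leaves do not match cell types: "
                    f"missing={sorted(want - got)}, unexpected={sorted(got - want)}"
                )
        return tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"CellTypeTree({self.to_newick()})"


def select_informative_genes(
    screen: ScreenResult, threshold: float = DEFAULT_TSTAT_THRESHOLD
) -> pd.Index:
    """Genes with |tstat| above ``threshold`` in at least one cell type."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hit = (screen.tstat.abs() > threshold).any(axis=1)
    genes = screen.tstat.index[hit]
    if len(genes) == 0:
        raise ValueError(
            f"no gene exceeds |tstat| > {threshold}; lower the threshold to build a tree"
        )
    return genes


def compute_distance_matrix(screen: ScreenResult, genes) -> pd.DataFrame:
    """(1 - Pearson cor) / 2 between cell-type tstat columns over ``genes``.

    Correlations are pairwise-complete over missing statistics.
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 informative genes for correlations")
    sub = screen.tstat.loc[genes]
    sd = sub.std(ddof=0)
    flat = sd[~(sd > 0)].index.tolist()
    if flat:
        raise ValueError(f"zero tstat variance over selected genes for cell types {flat}")
    corr = sub.corr(method="pearson")  # pairwise complete
    d = (1.0 - corr) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def build_tree(d: pd.DataFrame, linkage: str = "average") -> CellTypeTree:
    """Agglomerative clustering of the distance matrix into a rooted binary tree.

    Children of every node are ordered by their smallest leaf label so the
    output is deterministic regardless of input leaf order.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    labels = list(d.columns)
    if len(labels) == 1:
        warnings.warn("single cell type: returning a degenerate one-leaf tree")
        return CellTypeTree(TreeNode(label=labels[0]))
    order = np.argsort(labels)  # cluster in sorted-label order for determinism
    labels_sorted = [labels[i] for i in order]
    dm = d.to_numpy()[np.ix_(order, order)]
    Z = sch.linkage(squareform(dm, checks=False), method=linkage)
    nodes = {i: TreeNode(label=lab) for i, lab in enumerate(labels_sorted)}
    n = len(labels_sorted)
    for i, (a, b, height, _) in enumerate(Z):
        kids = sorted(
            [nodes.pop(int(a)), nodes.pop(int(b))], key=lambda t: min(t.leaf_labels())
        )
        nodes[n + i] = TreeNode(children=kids, height=float(height))
    (root,) = nodes.values()
    return CellTypeTree(root)
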