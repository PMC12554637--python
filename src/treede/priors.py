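"""Tree-structured Bernoulli priors over latent DE states.

For each gene there is a binary DE state ``Z_k`` per leaf cell type and a
binary state ``D`` per internal node.  The prior is a top-down Bernoulli
cascade: the root is on with probability ``pi_root``; any other node is on
with probability ``p`` given its parent is on, and off with certainty given
its parent is off.  Marginal node probabilities are estimated genome-wide
from screening p-values (fraction of genes significant in at least one
descendant type), and conditionals by dividing child by parent marginals.

For likelihood evaluation the internal states are collapsed onto the leaves:
``D`` at a node is taken to be the OR of its descendant leaves' ``Z``.  This
makes the joint a function of the 2^K leaf configurations alone.  Under the
collapse the prior over the 2^K configurations carries slightly less than
unit mass (the cascade also allows "node on, all children off" paths, which
the collapse excludes); posteriors are normalized within the 2^K set and are
therefore proper.
"""

from __future__ import annotations

import warnings

import numpy as np

from .hierarchy import CellTypeTree
from .screening import ScreenResult

__all__ = [
    "estimate_priors",
    "joint_prior_logprob",
    "log_prior_table",
    "configuration_matrix",
]


def estimate_priors(
    tree: CellTypeTree, screen: ScreenResult, pval_threshold: float = 0.01
) -> CellTypeTree:
    """Fill (pi, p) on a copy of the tree from genome-wide screening p-values.

    A node's marginal ``pi`` is the fraction of genes whose minimum p-value
    over the node's descendant types falls below ``pval_threshold``.  Because
    a child's descendant set is contained in its parent's, child marginals
    never exceed parent marginals and every conditional ``p`` lies in (0, 1].
    Zero (or one) marginals are floored (ceiled) at ``1/(2G)`` from the
    boundary to keep log-probabilities finite.
    """
    if not (0 < pval_threshold < 1):
        raise ValueError("pval_threshold must be in (0, 1)")
    missing = set(tree.leaves) - set(screen.pval.columns)
    if missing:
        raise ValueError(f"screen lacks cell types required by the tree: {sorted(missing)}")
    G = screen.n_genes
    if G < 1:
        raise ValueError("empty screen")
    eps = 1.0 / (2.0 * G)
    sig = screen.pval < pval_threshold  # NaN compares False: missing => not significant

    out = tree.copy()
    for node in out.root.preorder():
        members = sorted(node.leaf_labels())
        pi = float(sig[members].any(axis=1).mean())
        if pi <= 0.0 or pi >= 1.0:
            warnings.warn(
                f"prior for node {members} at boundary ({pi}); moving by eps={eps:.3g}"
            )
            pi = min(max(pi, eps), 1.0 - eps)
        node.pi = pi
    parents = out.parent_map()
    for node in out.root.preorder():
        if node is out.root:
            node.p = None
            continue
        node.p = min(node.pi / parents[id(node)].pi, 1.0)
    return out


def _or_states(tree: CellTypeTree, Z: np.ndarray) -> dict[int, bool]:
    """OR-collapse: state of every node given the leaf configuration."""
    z = dict(zip(tree.leaves, np.asarray(Z, dtype=bool)))
    return {id(n): bool(any(z[l] for l in n.leaf_labels())) for n in tree.root.preorder()}


def joint_prior_logprob(tree: CellTypeTree, Z) -> float:
    """Log prior probability of one leaf configuration under the cascade.

    Internal node states are the OR of their descendant leaves.
    """
    Z = np.asarray(Z)
    if Z.shape != (tree.n_leaves,):
        raise ValueError(f"Z must have length {tree.n_leaves}")
    if not tree.has_priors():
        raise ValueError("tree priors are not filled; run estimate_priors first")
    state = _or_states(tree, Z)
    parents = tree.parent_map()
    logp = 0.0
    with np.errstate(divide="ignore"):  # p == 1 makes "node off" impossible (-inf)
        for node in tree.root.preorder():
            s = state[id(node)]
            if node is tree.root:
                logp += np.log(node.pi) if s else np.log1p(-node.pi)
                continue
            if not state[id(parents[id(node)])]:
                continue  # parent off => node off with probability 1
            logp += np.log(node.p) if s else np.log1p(-node.p)
    return float(logp)


def configuration_matrix(K: int) -> np.ndarray:
    """(2^K, K) boolean matrix; row c is the bit pattern of integer c."""
    c = np.arange(2**K)
    return (c[:, None] >> np.arange(K)[None, :]) & 1 == 1


def log_prior_table(tree: CellTypeTree, leaf_order=None) -> np.ndarray:
    """Log prior of all 2^K leaf configurations, vectorized over configurations.

    Row order follows :func:`configuration_matrix` with leaf ``k`` mapped to
    bit ``k`` of ``leaf_order`` (defaults to the tree's own leaf order).
    """
    if not tree.has_priors():
        raise ValueError("tree priors are not filled; run estimate_priors first")
    leaves = list(leaf_order) if leaf_order is not None else tree.leaves
    if set(leaves) != set(tree.leaves):
        raise ValueError("leaf_order does not match the tree's leaves")
    K = len(leaves)
    Zmat = configuration_matrix(K)
    col = {lab: j for j, lab in enumerate(leaves)}
    # state of each node over all configurations = OR over member leaf bits
    node_state = {
        id(n): Zmat[:, [col[l] for l in n.leaf_labels()]].any(axis=1)
        for n in tree.root.preorder()
    }
    parents = tree.parent_map()
    logp = np.zeros(2**K)
    with np.errstate(divide="ignore"):
        for node in tree.root.preorder():
            s = node_state[id(node)]
            if node is tree.root:
                logp += np.where(s, np.log(node.pi), np.log1p(-node.pi))
                continue
            par_on = node_state[id(parents[id(node)])]
            term = np.where(s, np.log(node.p), np.log1p(-node.p))
            logp += np.where(par_on, term, 0.0)
    return logp
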