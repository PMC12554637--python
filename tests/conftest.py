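import numpy as np
import pandas as pd
import pytest

import treede
from treede.hierarchy import CellTypeTree, TreeNode
from treede.types import CellCountMatrix, DesignInfo


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def toy_counts():
    """12 genes, 2 subjects x 2 cell types, 3 cells per pair; dense ints."""
    rng = np.random.default_rng(7)
    n_cells = 12
    counts = rng.poisson(3.0, size=(12, n_cells))
    subj = np.array(["s1"] * 6 + ["s2"] * 6)
    ctype = np.tile(np.repeat(["A", "B"], 3), 2)
    return CellCountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(12)]),
        cell_subject=subj,
        cell_type=ctype,
    )


@pytest.fixture(scope="session")
def toy_design():
    return DesignInfo(subjects=np.array(["s1", "s2"]), A=np.array([0.0, 1.0]))


@pytest.fixture(scope="session")
def chain_tree():
    """3-leaf caterpillar ((a,b),c) with hand-set priors."""
    a = TreeNode("a", p=0.9)
    b = TreeNode("b", p=0.8)
    ab = TreeNode(children=[a, b], p=0.7)
    c = TreeNode("c", p=0.6)
    return CellTypeTree(TreeNode(children=[ab, c], pi=0.5))


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated study reused by slow-ish integration tests."""
    scen = treede.default_scenario(
        n_genes=400, total_cells=6000, subjects_per_group=8
    )
    return treede.simulate_dataset(scen, seed=11)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = treede.TreeBayesDE(min_cells=5).fit(
            small_dataset.counts, small_dataset.design
        )
    return est


def brute_force_posteriors(tree, ll0, ll1):
    """Independent oracle: literal sum over all 2^K configurations.

    ``ll0``/``ll1`` are (G, K) arrays in the order of ``tree.leaves``.
    Internal node states are the OR of descendant leaves; the prior of a
    configuration is the explicit product of Bernoulli terms walked node by
    node.  Deliberately naive (python loops, exp space with max-shift).
    """
    import itertools

    leaves = tree.leaves
    K = len(leaves)
    G = ll0.shape[0]
    parents = tree.parent_map()
    configs = list(itertools.product([0, 1], repeat=K))
    logpriors = []
    for z in configs:
        zmap = dict(zip(leaves, z))
        lp = 0.0
        for node in tree.root.preorder():
            state = int(any(zmap[l] for l in node.leaf_labels()))
            if node is tree.root:
                prob = node.pi if state else 1.0 - node.pi
            else:
                par_state = int(
                    any(zmap[l] for l in parents[id(node)].leaf_labels())
                )
                if par_state == 0:
                    prob = 1.0  # forced off
                else:
                    prob = node.p if state else 1.0 - node.p
            lp += np.log(prob) if prob > 0 else -np.inf
        logpriors.append(lp)
    post = np.zeros((G, K))
    for g in range(G):
        logjoint = np.array(
            [
                sum(ll1[g, k] if z[k] else ll0[g, k] for k in range(K)) + lp
                for z, lp in zip(configs, logpriors)
            ]
        )
        m = logjoint.max()
        w = np.exp(logjoint - m)
        total = w.sum()
        for k in range(K):
            post[g, k] = sum(
                wi for zi, wi in zip(configs, w) if zi[k]
            ) / total
    return post
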