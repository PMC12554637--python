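"""Negative-binomial scRNA-seq simulator with tree-correlated DE states.

The generator emulates a two-group whole-blood style study with six immune
cell types of very unequal abundance.  Per gene and cell type a latent DE
state is drawn top-down through a cell-type tree (root Bernoulli(pi), each
descendant Bernoulli(p) given its parent is on), which induces the designed
overlap of DE gene sets between related types.  Counts follow an NB2 law:

    X ~ NB(s * mu, phi),   Var = s*mu + phi*(s*mu)^2

with per-cell size factors ``s ~ U(0, 0.12)`` (shallow droplet-style depth),
gene dispersion ``phi = 0.01/mu + 0.05`` computed from the unscaled mean,
and group-2 means multiplied by ``2^lfc`` where the log2 fold change is
``N(0.065, 0.12^2)`` for DE entries and ``N(0, 0.001^2)`` otherwise.

Baseline means are synthetic (no reference dataset is read): a gene-level
log-normal mean crossed with a per-(gene, subject) multiplicative log-normal
effect.  The subject-level term makes cells from one subject correlated,
which is exactly the pseudo-replication that inflates cell-level tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hierarchy import CellTypeTree, TreeNode
from .types import CellCountMatrix, DesignInfo

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "default_tree",
    "independent_tree",
    "default_scenario",
    "sample_de_states",
    "simulate_dataset",
]

DEFAULT_PROPORTIONS = {
    # only the DC abundance (0.01) is a fixed reference point; the rest are
    # realistic whole-blood defaults and freely configurable
    "NK": 0.08,
    "B": 0.10,
    "CD4": 0.35,
    "CD8": 0.28,
    "Mono": 0.18,
    "DC": 0.01,
}


def default_tree() -> CellTypeTree:
    """The six-leaf immune tree with its generative priors.

    Topology ``((NK,(B,(CD4,CD8))),(Mono,DC))``; the (pi, p) values imply a
    20% marginal DE rate per leaf and pairwise DE overlaps of 0.90
    (CD4-CD8, Mono-DC), 0.75 (B vs CD4/CD8), 0.60 (NK vs CD4/CD8) and 0.40
    across the two main clusters.
    """
    cd4 = TreeNode("CD4", p=0.9)
    cd8 = TreeNode("CD8", p=0.9)
    t34 = TreeNode(children=[cd4, cd8], p=0.833)
    b = TreeNode("B", p=0.75)
    t234 = TreeNode(children=[b, t34], p=0.8)
    nk = TreeNode("NK", p=0.6)
    t1234 = TreeNode(children=[nk, t234], p=0.667)
    mono = TreeNode("Mono", p=0.9)
    dc = TreeNode("DC", p=0.9)
    t56 = TreeNode(children=[mono, dc], p=0.444)
    root = TreeNode(children=[t1234, t56], pi=0.5)
    return CellTypeTree(root)


def independent_tree(marginal: float = 0.2, labels=None) -> CellTypeTree:
    """A star tree whose leaves are independent Bernoulli(``marginal``).

    The root is always on (pi = 1) so each leaf fires independently with
    probability ``marginal`` — the no-information-sharing control.
    """
    labels = list(labels) if labels is not None else list(DEFAULT_PROPORTIONS)
    root = TreeNode(children=[TreeNode(l, p=marginal) for l in labels], pi=1.0)
    return CellTypeTree(root)


@dataclass
class SimulationScenario:
    """All laws and sizes of one simulated study; defaults are the reference
    study conditions (13,653 genes, 200,000 cells, 20 subjects per group)."""

    tree: CellTypeTree = field(default_factory=default_tree)
    n_genes: int = 13653
    subjects_per_group: int = 20
    total_cells: int = 200000
    cell_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    lfc_de: tuple[float, float] = (0.065, 0.12)  # N(mean, sd) log2 fold change
    lfc_null: tuple[float, float] = (0.0, 0.001)
    size_factor_range: tuple[float, float] = (0.0, 0.12)  # per-cell U(a, b)
    dispersion: tuple[float, float] = (0.01, 0.05)  # phi = a/mu + b
    gene_mean_log: tuple[float, float] = (np.log(5.0), 1.2)  # LogNormal params
    gene_mean_floor: float = 0.05
    subject_sd: float = 0.25  # per-(gene, subject) LogNormal sdlog

    def __post_init__(self) -> None:
        total = sum(self.cell_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"cell proportions sum to {total}, expected 1")
        if set(self.cell_proportions) != set(self.tree.leaves):
            raise ValueError("cell_proportions keys must match the tree's leaves")
        for name in ("size_factor_range", "dispersion", "gene_mean_log"):
            lo, hi = getattr(self, name)
            if hi <= 0:
                raise ValueError(f"{name} scale must be positive")

    def scaled(self, **overrides) -> "SimulationScenario":
        """Copy with some fields replaced (sizes, tree, laws)."""
        return replace(self, **overrides)


def default_scenario(**overrides) -> SimulationScenario:
    """The reference scenario; keyword overrides shrink or modify it."""
    return SimulationScenario().scaled(**overrides) if overrides else SimulationScenario()


@dataclass
class SimulatedDataset:
    """Counts plus the ground truth the benchmarks score against."""

    counts: CellCountMatrix
    design: DesignInfo
    truth_Z: pd.DataFrame  # genes x cell types, bool
    truth_lfc: pd.DataFrame  # genes x cell types, realized log2 fold changes
    scenario: SimulationScenario


def sample_de_states(scenario: SimulationScenario, seed) -> pd.DataFrame:
    """Draw the genes x cell-types truth matrix by the top-down cascade.

    This is the full generative draw (a node can be on with every child
    off), not the OR-collapsed version used for likelihood evaluation.
    """
    rng = np.random.default_rng(seed)
    tree = scenario.tree
    if not (tree.root.pi is not None):
        raise ValueError("scenario tree must carry generative priors")
    G = scenario.n_genes
    states: dict[int, np.ndarray] = {}
    parents = tree.parent_map()
    for node in tree.root.preorder():
        if node is tree.root:
            states[id(node)] = rng.random(G) < node.pi
        else:
            par = states[id(parents[id(node)])]
            states[id(node)] = par & (rng.random(G) < node.p)
    gene_ids = [f"g{j:05d}" for j in range(G)]
    Z = {n.label: states[id(n)] for n in tree.root.preorder() if n.is_leaf}
    return pd.DataFrame(Z, index=gene_ids, columns=tree.leaves)


def simulate_dataset(scenario: SimulationScenario, seed) -> SimulatedDataset:
    """Generate a full two-group single-cell count dataset with ground truth.

    Identical (scenario, seed) pairs reproduce the dataset bit for bit.
    """
    rng = np.random.default_rng(seed)
    tree = scenario.tree
    G = scenario.n_genes
    types = tree.leaves
    n_per_group = scenario.subjects_per_group
    N = 2 * n_per_group
    subjects = np.array([f"s{i:03d}" for i in range(N)])
    group = np.repeat([0, 1], n_per_group)  # j=1 -> A=0, j=2 -> A=1

    truth_Z = sample_de_states(scenario, rng)
    gene_ids = np.asarray(truth_Z.index)

    mu_de, sd_de = scenario.lfc_de
    mu_n, sd_n = scenario.lfc_null
    lfc = np.where(
        truth_Z.to_numpy(),
        rng.normal(mu_de, sd_de, size=(G, len(types))),
        rng.normal(mu_n, sd_n, size=(G, len(types))),
    )
    truth_lfc = pd.DataFrame(lfc, index=gene_ids, columns=types)

    # baseline means: gene level x subject level, drawn per (gene, subject,
    # cell type) so cells within a subject-type block are correlated while
    # types stay conditionally independent (the model's own assumption)
    mlog, slog = scenario.gene_mean_log
    gene_mean = np.maximum(rng.lognormal(mlog, slog, size=G), scenario.gene_mean_floor)
    subj_eff = rng.lognormal(0.0, scenario.subject_sd, size=(G, N, len(types)))
    m = gene_mean[:, None, None] * subj_eff  # (G, N, K)
    if np.any(m <= 0):
        raise ValueError("non-positive baseline mean")

    cells_per = {
        k: int(round(scenario.total_cells * scenario.cell_proportions[k] / N))
        for k in types
    }
    for k, n_ik in cells_per.items():
        if n_ik == 0:
            warnings.warn(f"proportion for {k!r} yields zero cells per subject")

    a_sf, b_sf = scenario.size_factor_range
    a_d, b_d = scenario.dispersion
    blocks, subj_lab, type_lab = [], [], []
    for i in range(N):
        for kj, k in enumerate(types):
            n_ik = cells_per[k]
            if n_ik == 0:
                continue
            mu = m[:, i, kj].copy()
            if group[i] == 1:
                mu = mu * np.exp2(lfc[:, kj])
            phi = a_d / mu + b_d  # dispersion from the unscaled mean
            s = rng.uniform(a_sf, b_sf, size=n_ik)
            mean = mu[:, None] * s[None, :]
            lam = rng.gamma(shape=1.0 / phi[:, None], scale=phi[:, None] * mean)
            x = rng.poisson(lam)
            blocks.append(sp.csr_matrix(x))
            subj_lab.append(np.repeat(subjects[i], n_ik))
            type_lab.append(np.repeat(k, n_ik))
    counts = sp.hstack(blocks, format="csr")
    ccm = CellCountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_subject=np.concatenate(subj_lab),
        cell_type=np.concatenate(type_lab),
    )
    design = DesignInfo(subjects=subjects, A=group.astype(float))
    return SimulatedDataset(
        counts=ccm, design=design, truth_Z=truth_Z, truth_lfc=truth_lfc, scenario=scenario
    )
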