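"""The tree-guided Bayesian DE estimator.

:class:`TreeBayesDE` runs the full procedure: low-expression filtering,
pseudo-bulk aggregation and log-normalization, per-type DE screening,
cell-type tree construction (or a user tree), genome-wide prior estimation
on the tree, per-gene Gaussian model fits, and exact posterior computation
over all 2^K DE-state configurations.  It follows scikit-learn conventions
(constructor parameters, ``fit``, trailing-underscore fitted attributes,
``get_params``/``set_params``) so it composes with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import hierarchy, inference, priors, pseudobulk, screening
from .hierarchy import CellTypeTree
from .types import CellCountMatrix, DesignInfo

__all__ = ["TreeBayesDE"]


class TreeBayesDE(BaseEstimator):
    """Joint DE caller across correlated cell types.

    Parameters
    ----------
    screen_method
        ``"nb_wald"`` (NB GLM on raw pseudo-bulk, default) or ``"ols_t"``.
    tstat_threshold
        |tstat| cut for selecting informative genes when building the tree;
        the default 2.58 is the two-sided normal critical value at p = .01.
    pval_threshold
        Screening p-value cut used to estimate tree priors (default .01).
    linkage
        Agglomeration rule for the tree: average / complete / single.
    cutoff
        Posterior probability above which a gene is called DE (default .95).
    min_cells
        A gene must be expressed in at least this many cells of a type to be
        analyzed there (default 10).
    scale_factor
        Library-size scale in the log-normalization (default 1e4).
    tree
        Optional user tree (CellTypeTree or newick string); bypasses
        construction.  Leaf labels must match the data's cell types.
    kmax
        Refuse enumeration beyond this many leaves (2^K configurations).

    Attributes
    ----------
    posterior_ : DataFrame (genes x cell types)
        ``P(Z_gk = 1 | Y_g)``.
    tree_ : CellTypeTree
        The tree used, with estimated priors attached.
    screen_ : ScreenResult
        First-pass statistics and p-values.
    de_genes_ : dict of DataFrame
        Per-type ranked calls at ``cutoff``.
    """

    def __init__(
        self,
        screen_method: str = "nb_wald",
        tstat_threshold: float = 2.58,
        pval_threshold: float = 0.01,
        linkage: str = "average",
        cutoff: float = 0.95,
        min_cells: int = 10,
        scale_factor: float = 1e4,
        tree: CellTypeTree | str | None = None,
        kmax: int = inference.K_MAX_DEFAULT,
    ):
        self.screen_method = screen_method
        self.tstat_threshold = tstat_threshold
        self.pval_threshold = pval_threshold
        self.linkage = linkage
        self.cutoff = cutoff
        self.min_cells = min_cells
        self.scale_factor = scale_factor
        self.tree = tree
        self.kmax = kmax

    # ------------------------------------------------------------------
    def _coerce_input(self, X, design) -> tuple[CellCountMatrix, DesignInfo]:
        if not isinstance(X, CellCountMatrix):
            try:
                import anndata
            except ImportError:  # pragma: no cover
                anndata = None
            if anndata is not None and isinstance(X, anndata.AnnData):
                X = CellCountMatrix.from_anndata(X)
            else:
                raise TypeError(
                    "X must be a CellCountMatrix or an AnnData with obs columns "
                    "'subject' and 'cell_type'"
                )
        if isinstance(design, pd.DataFrame):
            design = DesignInfo.from_dataframe(design)
        if not isinstance(design, DesignInfo):
            raise TypeError("design must be a DesignInfo or a subject-indexed DataFrame")
        return X, design

    def fit(self, X, design):
        """Run the full pipeline on counts ``X`` and a per-subject design."""
        ccm, design = self._coerce_input(X, design)
        filt = pseudobulk.filter_low_expression(ccm, min_cells=self.min_cells)
        shared = filt.shared.to_numpy()
        if not shared.any():
            raise ValueError("no gene passes the expression filter in every cell type")
        ccm_f = ccm.restrict_genes(shared)
        pb = pseudobulk.lognormalize(
            pseudobulk.aggregate_counts(ccm_f, design), scale_factor=self.scale_factor
        )
        screen = screening.screen_all(pb, method=self.screen_method)
        if self.tree is not None:
            tree = (
                CellTypeTree.from_newick(self.tree, expected_labels=pb.cell_types)
                if isinstance(self.tree, str)
                else self.tree
            )
            if set(tree.leaves) != set(pb.cell_types):
                raise ValueError("user tree leaves do not match the data's cell types")
            self.tree_source_ = "user"
        else:
            genes = hierarchy.select_informative_genes(screen, self.tstat_threshold)
            dist = hierarchy.compute_distance_matrix(screen, genes)
            tree = hierarchy.build_tree(dist, linkage=self.linkage)
            self.tree_source_ = "estimated"
        tree = priors.estimate_priors(tree, screen, pval_threshold=self.pval_threshold)
        fits = inference.fit_gene_models(pb)
        inf = inference.compute_posteriors(fits, tree, kmax=self.kmax)

        self.filter_masks_ = filt.masks
        self.pseudobulk_ = pb
        self.screen_ = screen
        self.tree_ = tree
        self.fits_ = fits
        self.inference_ = inf
        self.posterior_ = inf.posterior
        self.delta_ = inf.delta
        self.log_marginal_ = inf.log_marginal
        self.cell_types_ = list(inf.posterior.columns)
        self.gene_ids_ = np.asarray(inf.posterior.index)
        self.de_genes_ = inference.call_de_genes(inf, cutoff=self.cutoff)
        return self

    def de_genes(self, cutoff: float | None = None) -> dict[str, pd.DataFrame]:
        """Per-type ranked DE calls, optionally at a non-default cutoff."""
        self._check_fitted()
        if cutoff is None:
            return self.de_genes_
        return inference.call_de_genes(self.inference_, cutoff=cutoff)

    def score_frame(self) -> pd.DataFrame:
        """Posterior matrix (genes x types), the natural ranking scores."""
        self._check_fitted()
        return self.posterior_

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("estimator is not fitted; call fit first")
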