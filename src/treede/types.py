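"""Core in-memory containers shared across the package.

The pipeline operates on three pieces of data: a gene x cell count matrix
with per-cell subject and cell-type labels (:class:`CellCountMatrix`), a
per-subject design (:class:`DesignInfo`), and the per-cell-type pseudo-bulk
matrices derived from them (:class:`PseudoBulkSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellCountMatrix", "DesignInfo", "PseudoBulkSet"]


@dataclass
class CellCountMatrix:
    """Raw UMI/read counts for G genes across all cells of a study.

    Parameters
    ----------
    counts
        ``(G, n_cells)`` non-negative integer matrix, dense or scipy sparse.
    gene_ids
        Length-G gene identifiers, unique.
    cell_subject
        Length-``n_cells`` subject label per cell.
    cell_type
        Length-``n_cells`` cell-type label per cell.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_subject: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_subject = np.asarray(self.cell_subject)
        self.cell_type = np.asarray(self.cell_type)
        g, c = self.counts.shape
        if g == 0 or c == 0:
            raise ValueError("count matrix is empty")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.cell_subject) != c or len(self.cell_type) != c:
            raise ValueError("cell label length does not match number of cells")
        if len(np.unique(self.gene_ids)) != g:
            raise ValueError("gene ids must be unique")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and (np.min(data) < 0 or np.any(np.mod(data, 1) != 0)):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.cell_subject)

    @property
    def cell_types(self) -> np.ndarray:
        return np.unique(self.cell_type)

    def restrict_genes(self, mask: np.ndarray) -> "CellCountMatrix":
        """Return a copy restricted to genes where ``mask`` is True (or an index set)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_subject=self.cell_subject,
            cell_type=self.cell_type,
        )

    @classmethod
    def from_anndata(cls, adata, subject_key: str = "subject", type_key: str = "cell_type"):
        """Build from an AnnData (cells x genes, as scanpy stores it)."""
        X = adata.X.T if sp.issparse(adata.X) else np.asarray(adata.X).T
        return cls(
            counts=X.tocsr() if sp.issparse(X) else X,
            gene_ids=np.asarray(adata.var_names),
            cell_subject=np.asarray(adata.obs[subject_key]),
            cell_type=np.asarray(adata.obs[type_key]),
        )


@dataclass
class DesignInfo:
    """Per-subject design: tested factor(s) A and nuisance covariates C.

    ``A`` may be a length-N vector (binary or continuous) or an ``(N, R)``
    matrix for multi-column tested factors.  ``C`` is ``(N, Q)`` with Q >= 0.
    """

    subjects: np.ndarray
    A: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.shape[0] == 1 and len(self.subjects) != 1:
            self.A = self.A.T
        n = len(self.subjects)
        if len(np.unique(self.subjects)) != n:
            raise ValueError("duplicate subject labels in design")
        if n < 2:
            raise ValueError("need at least two subjects")
        if self.A.shape[0] != n:
            raise ValueError("A length does not match number of subjects")
        if np.isnan(self.A).any():
            raise ValueError("A contains missing values")
        if self.C is None:
            self.C = np.empty((n, 0))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if self.C.shape[0] != n:
            raise ValueError("C rows do not match number of subjects")
        if np.isnan(self.C).any():
            raise ValueError("C contains missing values")
        # a binary factor must have both levels represented
        for j in range(self.A.shape[1]):
            col = self.A[:, j]
            if set(np.unique(col)) <= {0.0, 1.0} and len(np.unique(col)) < 2:
                raise ValueError("binary tested factor has a single level")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_covariates(self) -> int:
        return self.C.shape[1]

    def subset(self, subjects) -> "DesignInfo":
        """Design restricted to the given subjects, in the given order."""
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = np.array([pos[s] for s in subjects])
        return DesignInfo(self.subjects[idx], self.A[idx], self.C[idx])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, a_cols=("A",)) -> "DesignInfo":
        """Build from a subject-indexed table; columns not in ``a_cols`` become covariates."""
        a_cols = list(a_cols)
        c_cols = [c for c in df.columns if c not in a_cols]
        return cls(
            subjects=np.asarray(df.index),
            A=df[a_cols].to_numpy(float),
            C=df[c_cols].to_numpy(float) if c_cols else None,
        )


@dataclass
class PseudoBulkSet:
    """Per-cell-type pseudo-bulk matrices with the shared subject design.

    ``raw[k]`` is the genes x subjects matrix of summed counts for cell type
    ``k``; columns are restricted to subjects with at least one cell of that
    type.  ``Y[k]`` (after log-normalization) is on the natural-log scale.
    Subject/type pairs with zero cells are listed in ``missing`` rather than
    zero-filled.
    """

    raw: dict[str, pd.DataFrame]
    design: DesignInfo
    Y: dict[str, pd.DataFrame] | None = None
    missing: list[tuple] = field(default_factory=list)

    @property
    def cell_types(self) -> list[str]:
        return list(self.raw)

    @property
    def gene_ids(self) -> np.ndarray:
        first = next(iter(self.raw.values()))
        return np.asarray(first.index)

    def design_for(self, cell_type: str) -> DesignInfo:
        """Design restricted to the subjects present for one cell type."""
        return self.design.subset(list(self.raw[cell_type].columns))
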