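"""Pseudo-bulk aggregation, library-size normalization, and gene filtering.

Single-cell counts are summed within each (subject, cell type) pair to form
one bulk-like sample per subject per type.  The downstream Gaussian model
operates on these pseudo-bulk profiles after Seurat-style log-normalization:
``ln(1 + count / libsize * scale_factor)`` with ``scale_factor = 1e4``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CellCountMatrix, DesignInfo, PseudoBulkSet

__all__ = [
    "aggregate_counts",
    "lognormalize",
    "filter_low_expression",
    "FilterResult",
]


def aggregate_counts(
    ccm: CellCountMatrix,
    design: DesignInfo,
    subject_order=None,
    type_order=None,
) -> PseudoBulkSet:
    """Sum single-cell counts into per-(subject, cell type) pseudo-bulk columns.

    Ordering of subjects and types is lexicographic unless explicit orders are
    supplied.  A (subject, type) pair with no cells is recorded in
    ``PseudoBulkSet.missing`` and that subject is simply absent from that
    type's matrix.
    """
    subjects = list(subject_order) if subject_order is not None else sorted(design.subjects)
    types = list(type_order) if type_order is not None else sorted(np.unique(ccm.cell_type))
    if set(np.unique(ccm.cell_subject)) - set(subjects):
        raise ValueError("cells reference subjects absent from the design")

    counts = ccm.counts.tocsc() if sp.issparse(ccm.counts) else np.asarray(ccm.counts)
    raw: dict[str, pd.DataFrame] = {}
    missing: list[tuple] = []
    for k in types:
        in_type = ccm.cell_type == k
        subj_of_cell = ccm.cell_subject[in_type]
        present = [s for s in subjects if np.any(subj_of_cell == s)]
        missing.extend((s, k) for s in subjects if s not in present)
        block = counts[:, np.flatnonzero(in_type)]
        # one-hot cell->subject indicator; matmul does the group-by sum
        col_idx = {s: j for j, s in enumerate(present)}
        ind = sp.csr_matrix(
            (
                np.ones(len(subj_of_cell)),
                (np.arange(len(subj_of_cell)), [col_idx[s] for s in subj_of_cell]),
            ),
            shape=(len(subj_of_cell), len(present)),
        )
        mat = block @ ind
        mat = np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)
        raw[k] = pd.DataFrame(mat, index=ccm.gene_ids, columns=present)
    if missing:
        warnings.warn(f"{len(missing)} (subject, cell type) pairs have no cells: {missing[:5]}")
    return PseudoBulkSet(raw=raw, design=design.subset(subjects), missing=missing)


def lognormalize(
    pb: PseudoBulkSet, scale_factor: float = 1e4, strict: bool = False
) -> PseudoBulkSet:
    """Fill ``pb.Y`` with ``ln(1 + raw / libsize * scale_factor)`` per column.

    The library size is the column sum over the retained genes of that
    cell type's matrix.  Zero-library columns are dropped with a warning
    (or raise when ``strict``).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    Y: dict[str, pd.DataFrame] = {}
    raw_out: dict[str, pd.DataFrame] = {}
    for k, mat in pb.raw.items():
        lib = mat.sum(axis=0)
        bad = lib[lib <= 0].index.tolist()
        if bad:
            if strict:
                raise ValueError(f"zero library size for subjects {bad} in cell type {k!r}")
            warnings.warn(f"dropping zero-library subjects {bad} for cell type {k!r}")
            mat = mat.drop(columns=bad)
            lib = lib.drop(index=bad)
        Y[k] = np.log1p(mat / lib * scale_factor)
        raw_out[k] = mat
    return PseudoBulkSet(raw=raw_out, design=pb.design, Y=Y, missing=list(pb.missing))


@dataclass
class FilterResult:
    """Per-cell-type gene keep-masks from the expressed-cell filter.

    ``masks`` is a genes x types boolean frame; ``shared`` is the AND over
    types — the gene universe on which the joint (all-types) model runs.
    """

    masks: pd.DataFrame
    shared: pd.Series


def filter_low_expression(ccm: CellCountMatrix, min_cells: int = 10) -> FilterResult:
    """Flag genes expressed in fewer than ``min_cells`` cells of a cell type.

    A gene is "expressed" in a cell when its count is nonzero.  The filter is
    applied per cell type; a cell type that would lose every gene raises.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    counts = ccm.counts.tocsc() if sp.issparse(ccm.counts) else np.asarray(ccm.counts)
    masks = {}
    for k in sorted(np.unique(ccm.cell_type)):
        idx = np.flatnonzero(ccm.cell_type == k)
        block = counts[:, idx]
        if sp.issparse(block):
            n_expressed = np.asarray((block > 0).sum(axis=1)).ravel()
        else:
            n_expressed = (block > 0).sum(axis=1)
        keep = n_expressed >= min_cells
        if not keep.any():
            raise ValueError(f"all genes filtered out for cell type {k!r}; lower min_cells")
        masks[k] = keep
    frame = pd.DataFrame(masks, index=ccm.gene_ids)
    return FilterResult(masks=frame, shared=frame.all(axis=1))
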