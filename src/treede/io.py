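"""Reading and writing the on-disk formats: 10x-style MTX triplets + TSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CellCountMatrix, DesignInfo

__all__ = [
    "read_counts_dir",
    "write_counts_dir",
    "read_design",
    "write_pseudobulk",
    "write_run_manifest",
]


def read_counts_dir(path) -> tuple[CellCountMatrix, DesignInfo]:
    """Load a dataset directory.

    Expected files: ``matrix.mtx`` (genes x cells), ``genes.tsv`` (one id per
    line), ``cells.tsv`` (barcode, subject, cell_type), ``subjects.tsv``
    (subject, A, then covariate columns).
    """
    path = Path(path)
    counts = scipy.io.mmread(path / "matrix.mtx").tocsr()
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    ccm = CellCountMatrix(
        counts=counts,
        gene_ids=genes,
        cell_subject=cells["subject"].to_numpy(),
        cell_type=cells["cell_type"].to_numpy(),
    )
    design = read_design(path / "subjects.tsv")
    return ccm, design


def read_design(path) -> DesignInfo:
    df = pd.read_csv(path, sep="\t").set_index("subject")
    return DesignInfo.from_dataframe(df, a_cols=("A",))


def write_counts_dir(path, ccm: CellCountMatrix, design: DesignInfo, truth=None) -> None:
    """Write the dataset directory read by :func:`read_counts_dir`.

    ``truth``, if given, is a dict of genes x types frames written as
    ``truth_<name>.tsv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = ccm.counts if sp.issparse(ccm.counts) else sp.csr_matrix(ccm.counts)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat.tocoo())
    pd.Series(ccm.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "barcode": [f"cell{j}" for j in range(ccm.n_cells)],
            "subject": ccm.cell_subject,
            "cell_type": ccm.cell_type,
        }
    ).to_csv(path / "cells.tsv", sep="\t", index=False)
    subj = pd.DataFrame({"subject": design.subjects})
    for j in range(design.A.shape[1]):
        subj["A" if j == 0 else f"A{j + 1}"] = design.A[:, j]
    for q in range(design.n_covariates):
        subj[f"C{q + 1}"] = design.C[:, q]
    subj.to_csv(path / "subjects.tsv", sep="\t", index=False)
    for name, frame in (truth or {}).items():
        frame.to_csv(path / f"truth_{name}.tsv", sep="\t")


def write_pseudobulk(path, pb) -> None:
    """Per-type raw and normalized pseudo-bulk TSVs (genes x subjects)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, mat in pb.raw.items():
        mat.to_csv(path / f"pseudobulk_raw_{k}.tsv", sep="\t")
    for k, mat in (pb.Y or {}).items():
        mat.to_csv(path / f"pseudobulk_lognorm_{k}.tsv", sep="\t")


def write_run_manifest(path, config: dict, seed=None) -> None:
    import treede

    manifest = {
        "package_version": treede.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
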