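"""Benchmarking utilities: PR curves, observed FDR, overlap, comparators.

These score any per-gene ranking or called-gene set against simulation
truth, and provide the two t-test baselines:

* a pseudo-bulk two-sample t-test (one value per subject — the honest
  baseline), and
* a cell-level two-sample t-test pooling all cells of a group as if they
  were independent — the pseudo-replication straw man whose observed FDR
  blows up when subjects have correlated baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import aggregate_counts, lognormalize
from .types import CellCountMatrix, DesignInfo

__all__ = [
    "pr_auc",
    "observed_fdr",
    "overlap_rate",
    "rediscovery_rate",
    "permute_labels",
    "comparator_ttest",
]


def pr_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and its trapezoidal area for one gene ranking.

    ``scores``: higher means more DE.  ``truth``: binary.  Precision/recall
    are evaluated at every distinct score threshold (ties grouped), the
    curve traversed in descending-score order, and the area integrated over
    recall by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    if truth.all() or not truth.any():
        raise ValueError("truth needs at least one positive and one negative")
    prevalence = truth.mean()
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth[order]
    # last index of each tie group
    boundary = np.flatnonzero(np.diff(s) != 0)
    last = np.append(boundary, len(s) - 1)
    tp = np.cumsum(t)[last]
    n_called = last + 1
    precision = tp / n_called
    recall = tp / truth.sum()
    curve = pd.DataFrame(
        {"threshold": s[last], "precision": precision, "recall": recall}
    )
    if len(last) == 1:
        warnings.warn("all scores identical; PR curve is a single point")
        return curve, float(prevalence)
    # anchor at recall 0 with the top tie-group's precision
    auc = float(
        np.trapezoid(np.r_[precision[0], precision], np.r_[0.0, recall])
    )
    return curve, auc


def observed_fdr(called, truth) -> float:
    """Fraction of called genes that are truly null; 0 when nothing is called.

    ``truth`` is a boolean Series indexed by gene (True = truly DE).
    """
    called = list(called)
    if not called:
        return 0.0
    truth = pd.Series(truth)
    n_false = int((~truth.reindex(called, fill_value=False).astype(bool)).sum())
    return n_false / len(called)


def overlap_rate(reference, other) -> float:
    """|reference ∩ other| / |reference|; 0 when the reference set is empty."""
    ref = set(reference)
    if not ref:
        return 0.0
    return len(ref & set(other)) / len(ref)


def rediscovery_rate(train_called, validation_called) -> float:
    """Fraction of training DE calls re-detected in the validation calls."""
    return overlap_rate(train_called, validation_called)


def permute_labels(design: DesignInfo, seed) -> DesignInfo:
    """Shuffle the tested factor across subjects; covariates untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(design.n_subjects)
    return DesignInfo(subjects=design.subjects, A=design.A[perm], C=design.C.copy())


def _pooled_t_from_moments(n1, s1, ss1, n2, s2, ss2):
    """Equal-variance two-sample t from per-group sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = (ss1 - n1 * m1**2) / max(n1 - 1, 1)
    v2 = (ss2 - n2 * m2**2) / max(n2 - 1, 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(np.maximum(sp2 * (1.0 / n1 + 1.0 / n2), 1e-300))
    t = (m2 - m1) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return t, p


def _cell_lognorm_moments(counts, scale_factor):
    """Per-gene sum and sum-of-squares of log-normalized cell values, sparse-safe."""
    if sp.issparse(counts):
        counts = counts.tocsc()
        lib = np.asarray(counts.sum(axis=0)).ravel()
        lib = np.maximum(lib, 1.0)
        X = counts.multiply(scale_factor / lib[None, :]).log1p()
        s = np.asarray(X.sum(axis=1)).ravel()
        ss = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    else:
        lib = np.maximum(counts.sum(axis=0), 1.0)
        X = np.log1p(counts / lib[None, :] * scale_factor)
        s = X.sum(axis=1)
        ss = (X**2).sum(axis=1)
    return s, ss


def comparator_ttest(
    counts: CellCountMatrix,
    design: DesignInfo,
    level: str = "cell",
    scale_factor: float = 1e4,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Two-sample t-test baseline at cell or pseudo-bulk level, per cell type.

    ``cell`` level log-normalizes each cell by its own library size and pools
    the cells of each outcome group, deliberately ignoring which subject a
    cell came from.  ``pseudobulk`` level aggregates to per-subject columns
    first (equivalent to the OLS screen with no covariates).  Calls use
    Benjamini-Hochberg adjusted p < ``alpha``.  Returns per-type frames with
    columns tstat / pval / padj / called.
    """
    if level not in ("cell", "pseudobulk"):
        raise ValueError(f"unknown level {level!r}")
    a = design.A[:, 0]
    groups = np.unique(a)
    if len(groups) != 2:
        raise ValueError("comparator t-test needs a binary tested factor")
    out: dict[str, pd.DataFrame] = {}
    if level == "pseudobulk":
        pb = lognormalize(aggregate_counts(counts, design), scale_factor=scale_factor)
        for k in pb.cell_types:
            dk = pb.design_for(k)
            ak = dk.A[:, 0]
            Y = pb.Y[k].to_numpy()
            g1, g2 = Y[:, ak == groups[0]], Y[:, ak == groups[1]]
            if g1.shape[1] < 2 or g2.shape[1] < 2:
                warnings.warn(f"cell type {k!r}: a group has < 2 subjects; skipped")
                continue
            t, p = _pooled_t_from_moments(
                g1.shape[1], g1.sum(1), (g1**2).sum(1),
                g2.shape[1], g2.sum(1), (g2**2).sum(1),
            )
            out[k] = _finish_table(pb.gene_ids, t, p, alpha)
        return out

    a_of_cell = pd.Series(dict(zip(design.subjects, a))).reindex(counts.cell_subject)
    a_of_cell = a_of_cell.to_numpy()
    mat = counts.counts.tocsc() if sp.issparse(counts.counts) else counts.counts
    for k in sorted(np.unique(counts.cell_type)):
        sel = counts.cell_type == k
        idx1 = np.flatnonzero(sel & (a_of_cell == groups[0]))
        idx2 = np.flatnonzero(sel & (a_of_cell == groups[1]))
        if len(idx1) < 2 or len(idx2) < 2:
            warnings.warn(f"cell type {k!r}: a group has < 2 cells; skipped")
            continue
        s1, ss1 = _cell_lognorm_moments(mat[:, idx1], scale_factor)
        s2, ss2 = _cell_lognorm_moments(mat[:, idx2], scale_factor)
        t, p = _pooled_t_from_moments(len(idx1), s1, ss1, len(idx2), s2, ss2)
        out[k] = _finish_table(counts.gene_ids, t, p, alpha)
    return out


def _finish_table(gene_ids, t, p, alpha) -> pd.DataFrame:
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    _, padj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"tstat": t, "pval": p, "padj": padj, "called": padj < alpha}, index=gene_ids
    )
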