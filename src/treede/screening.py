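"""First-pass per-gene, per-cell-type DE screening.

The screen supplies the two matrices everything downstream consumes: a G x K
matrix of signed test statistics (used to build the cell-type tree) and a
G x K matrix of p-values (used to estimate the tree priors).  Two backends
are offered:

``nb_wald``
    A negative-binomial GLM Wald test on the raw pseudo-bulk counts with a
    log library-size offset, playing the role a bulk NB tool (DESeq2-style)
    plays in practice.  Per-gene dispersion is estimated by method of
    moments (floored at 1e-8), no shrinkage; the GLM is solved by IRLS
    vectorized across genes.

``ols_t``
    The t statistic of the tested-factor coefficient from OLS of the
    log-normalized pseudo-bulk on (1, C, A).  With no covariates and a
    binary factor this is the classical pooled-variance two-sample t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DesignInfo, PseudoBulkSet

__all__ = ["ScreenResult", "screen_all", "ols_t_screen", "nb_wald_screen"]

_DISP_FLOOR = 1e-8


@dataclass
class ScreenResult:
    """Signed statistics and two-sided p-values on the shared gene universe."""

    tstat: pd.DataFrame  # G x K
    pval: pd.DataFrame  # G x K, in [0, 1]
    method: str

    @property
    def n_genes(self) -> int:
        return self.tstat.shape[0]

    @property
    def cell_types(self) -> list[str]:
        return list(self.tstat.columns)


def _design_matrix(design: DesignInfo, with_a: bool) -> np.ndarray:
    cols = [np.ones((design.n_subjects, 1)), design.C]
    if with_a:
        cols.append(design.A)
    return np.column_stack(cols)


def _check_design(design: DesignInfo, cell_type: str) -> bool:
    """True when the tested factor varies within this type's subject subset."""
    if np.allclose(design.A, design.A[0]):
        warnings.warn(f"tested factor constant within cell type {cell_type!r}; skipped")
        return False
    return True


def ols_t_screen(Y: pd.DataFrame, design: DesignInfo) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS t-test of the (first) A column, all genes at once."""
    X = _design_matrix(design, with_a=True)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} subjects for the OLS screen, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    Ym = Y.to_numpy()
    B = Ym @ pinv.T  # G x p
    resid = Ym - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    # variance floor keeps zero-residual genes finite (exact-fit degenerate case)
    sigma2 = np.maximum(rss / (n - p), 1e-12)
    a_col = p - design.A.shape[1]  # first tested-factor column
    se = np.sqrt(sigma2 * xtx_inv[a_col, a_col])
    t = B[:, a_col] / se
    pv = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    return t, pv


def nb_wald_screen(
    raw: pd.DataFrame, design: DesignInfo, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """NB GLM Wald test with log-libsize offset, IRLS vectorized over genes.

    Model: ``y_gi ~ NB2(exp(o_i + x_i' b_g), alpha_g)`` with
    ``Var = mu + alpha mu^2``.  ``alpha_g`` comes from a method-of-moments
    pass on Poisson fitted means, floored at 1e-8.
    """
    X = _design_matrix(design, with_a=True)
    n, p = X.shape
    Ymat = raw.to_numpy(dtype=float)
    G = Ymat.shape[0]
    lib = Ymat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size column in raw pseudo-bulk")
    offset = np.log(lib)

    def irls(alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # beta: G x p; returns (beta, cov_aa) for the Wald statistic
        beta = np.zeros((G, p))
        beta[:, 0] = np.log(np.maximum(Ymat.mean(axis=1) / np.exp(offset).mean(), 1e-12))
        for _ in range(max_iter):
            eta = offset[None, :] + beta @ X.T
            eta = np.clip(eta, -30.0, 30.0)
            mu = np.exp(eta)
            W = mu / (1.0 + alpha[:, None] * mu)  # NB2 IRLS weights
            z = (eta - offset[None, :]) + (Ymat - mu) / mu
            XtWX = np.einsum("gn,np,nq->gpq", W, X, X)
            XtWz = np.einsum("gn,np,gn->gp", W, X, z)
            XtWX += 1e-10 * np.eye(p)[None, :, :]
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
            step = new - beta
            beta = new
            if np.max(np.abs(step)) < tol:
                break
        cov = np.linalg.inv(XtWX)
        return beta, cov

    # method-of-moments dispersion from a Poisson (alpha=0) pass
    beta0, _ = irls(np.zeros(G))
    mu0 = np.exp(np.clip(offset[None, :] + beta0 @ X.T, -30.0, 30.0))
    num = ((Ymat - mu0) ** 2 - mu0).sum(axis=1)
    den = (mu0**2).sum(axis=1)
    alpha = np.maximum(num / np.maximum(den, 1e-300), _DISP_FLOOR)

    beta, cov = irls(alpha)
    a_col = p - design.A.shape[1]
    se = np.sqrt(np.maximum(cov[:, a_col, a_col], 1e-300))
    t = beta[:, a_col] / se
    pv = 2.0 * stats.norm.sf(np.abs(t))
    return t, pv


def screen_all(pb: PseudoBulkSet, method: str = "nb_wald") -> ScreenResult:
    """Run the screen on every cell type; returns aligned G x K matrices.

    Cell types whose subject subset has a constant tested factor are flagged
    and left as missing (NaN) columns.  Failed per-gene fits are reported and
    left missing.
    """
    if method not in ("nb_wald", "ols_t"):
        raise ValueError(f"unknown screening method {method!r}")
    if method == "ols_t" and pb.Y is None:
        raise ValueError("ols_t screen needs log-normalized matrices; run lognormalize first")
    genes = pb.gene_ids
    tstat = pd.DataFrame(np.nan, index=genes, columns=pb.cell_types)
    pval = pd.DataFrame(np.nan, index=genes, columns=pb.cell_types)
    for k in pb.cell_types:
        design_k = pb.design_for(k)
        if not _check_design(design_k, k):
            continue
        if method == "ols_t":
            t, pv = ols_t_screen(pb.Y[k], design_k)
        else:
            t, pv = nb_wald_screen(pb.raw[k], design_k)
        n_bad = int(np.sum(~np.isfinite(t)))
        if n_bad:
            warnings.warn(f"{n_bad} genes failed the {method} fit in cell type {k!r}")
            pv = np.where(np.isfinite(t), pv, np.nan)
            t = np.where(np.isfinite(t), t, np.nan)
        tstat[k] = t
        pval[k] = np.clip(pv, 0.0, 1.0)
    return ScreenResult(tstat=tstat, pval=pval, method=method)
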