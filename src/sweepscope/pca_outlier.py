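"""PCA-based outlier scan for loci under selection.

The scan standardizes the genotype matrix (impute missing by the SNP mean,
center by 2p, scale by sqrt(2p(1-p))), extracts the top K principal
components, and regresses every SNP on the K components.  The per-SNP vector
of regression t-statistics z_j = (z_j1, ..., z_jK) is summarized by the
Mahalanobis distance

    D_j^2 = (z_j - z_bar)^T  Sigma^{-1}  (z_j - z_bar)

with Sigma the K x K covariance of the z-scores.  Under the null D^2 is
chi-square with K degrees of freedom; a genomic inflation factor
GIF = median(D^2) / median(chi2_K) recalibrates the tail under polygenic or
drift background, and p_j is the upper chi2_K tail of D_j^2 / GIF.  Outliers
are SNPs below a Bonferroni-corrected threshold alpha / L.

Monomorphic and near-monomorphic SNPs (MAF below 1/(2n)) are excluded from
the scan (they remain in the F_ST analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypePanel

__all__ = [
    "PcaModel",
    "standardize_genotypes",
    "fit_pca_zscores",
    "mahalanobis_pvalues",
    "bonferroni_outliers",
    "suggest_k",
]


@dataclass
class PcaModel:
    """Fitted scan state: scores, eigenvalues, z-scores and (later) p-values."""

    k: int
    scores: np.ndarray          # n_samples x K, orthonormal columns
    eigenvalues: np.ndarray     # all min(n, m) eigenvalues, non-increasing
    zscores: np.ndarray         # n_kept_snps x K
    kept: np.ndarray            # indices of scanned SNPs in the panel
    n_excluded: int
    variant_ids: np.ndarray
    sigma: np.ndarray | None = None
    d2: np.ndarray | None = None
    gif: float | None = None
    pvalues: np.ndarray | None = None


def standardize_genotypes(
    dosages: np.ndarray, min_maf: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Impute-by-mean, center by 2p and scale by sqrt(2p(1-p)).

    Returns the standardized matrix restricted to SNPs with MAF above the
    cutoff (default 1/(2n)) and the kept column indices.
    """
    n = dosages.shape[0]
    if min_maf is None:
        min_maf = 1.0 / (2 * n)
    called = dosages != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, np.where(called, dosages, 0).sum(axis=0)
                     / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    kept = np.where((n_called > 0) & (maf >= min_maf))[0]
    sub = dosages[:, kept].astype(float)
    pk = p[kept]
    sub = np.where(sub == MISSING, 2 * pk[None, :], sub)
    X = (sub - 2 * pk[None, :]) / np.sqrt(2 * pk * (1 - pk))[None, :]
    return X, kept


def fit_pca_zscores(panel: GenotypePanel, k: int) -> PcaModel:
    """PCA of the standardized panel and per-SNP regression t-statistic z-scores.

    z_jk is the t-statistic of component k in the K-variate linear regression
    of standardized SNP j on the top-K (orthonormal) sample scores.
    """
    n = panel.n_samples
    if not 1 <= k < n:
        raise ValueError(f"K must satisfy 1 <= K < n_samples ({n})")
    X, kept = standardize_genotypes(panel.dosages)
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs to scan")
    # PCA via SVD of the standardized matrix (columns have exact zero mean)
    U, svals, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = svals**2 / X.shape[1]
    Uk = U[:, :k]  # orthonormal regression design
    beta = Uk.T @ X                      # K x m
    fitted_ss = (beta**2).sum(axis=0)
    total_ss = (X**2).sum(axis=0)
    dof = n - k
    resid_var = np.maximum(total_ss - fitted_ss, 0.0) / dof
    sigma = np.sqrt(np.maximum(resid_var, np.finfo(float).tiny))
    z = (beta / sigma[None, :]).T        # m x K; se(beta_k) = sigma (U'U = I)
    return PcaModel(
        k=k,
        scores=Uk,
        eigenvalues=eigenvalues,
        zscores=z,
        kept=kept,
        n_excluded=panel.n_variants - len(kept),
        variant_ids=panel.variants["id"].to_numpy()[kept],
    )


def _robust_covariance(z: np.ndarray) -> np.ndarray:
    """MAD-based robust covariance: robust scales with rank correlations."""
    med = np.median(z, axis=0)
    mad = np.median(np.abs(z - med), axis=0) * 1.4826
    mad = np.maximum(mad, np.finfo(float).tiny)
    zs = (z - med) / mad
    r = np.corrcoef(zs, rowvar=False)
    return r * np.outer(mad, mad)


def mahalanobis_pvalues(model: PcaModel, robust: bool = False) -> PcaModel:
    """Complete the model: Sigma, D^2, genomic inflation factor and p-values."""
    z = model.zscores
    zbar = z.mean(axis=0)
    if np.allclose(z, zbar, atol=1e-12):
        # zero dispersion: every SNP sits at the centroid, D^2 = 0, p = 1
        model.sigma = np.eye(model.k)
        model.d2 = np.zeros(z.shape[0])
        model.gif = 1.0
        model.pvalues = np.ones(z.shape[0])
        return model
    sigma = _robust_covariance(z) if robust else np.cov(z, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "z-score covariance is singular; try a smaller K"
        ) from exc
    diff = (z - zbar).T
    sol = np.linalg.solve(chol, diff)
    d2 = (sol**2).sum(axis=0)
    gif = float(np.median(d2) / stats.chi2.median(model.k))
    pvals = stats.chi2.sf(d2 / gif, df=model.k)
    pvals = np.maximum(pvals, np.finfo(float).tiny)  # keep p in (0, 1]
    model.sigma = sigma
    model.d2 = d2
    model.gif = gif
    model.pvalues = pvals
    return model


def bonferroni_outliers(model: PcaModel, alpha: float = 0.1) -> pd.DataFrame:
    """SNPs with p < alpha / L, sorted by ascending p."""
    if model.pvalues is None:
        raise ValueError("call mahalanobis_pvalues first")
    L = len(model.pvalues)
    threshold = alpha / L
    hits = np.where(model.pvalues < threshold)[0]
    order = hits[np.argsort(model.pvalues[hits], kind="mergesort")]
    return pd.DataFrame(
        {
            "id": model.variant_ids[order],
            "panel_index": model.kept[order],
            "d2": model.d2[order],
            "p": model.pvalues[order],
        }
    )


def suggest_k(eigenvalues: np.ndarray, tau: float = 0.02) -> int:
    """Scree-plot elbow: largest k with (lam_k - lam_{k+1}) > tau * spectrum range.

    Advisory only — the pipeline takes K from its configuration.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    if (np.diff(lam) > 1e-12).any():
        raise ValueError("eigenvalues must be non-increasing")
    # drop structural ~zero eigenvalues (centering makes the last one exact 0)
    nz = lam > 1e-10 * lam[0]
    if nz.sum() >= 3:
        lam = lam[nz]
    spread = lam[0] - lam[-1]
    if spread <= 0:
        return 1
    drops = lam[:-1] - lam[1:]
    big = np.where(drops > tau * spread)[0]
    return int(big[-1] + 1) if big.size else 1
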