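"""Per-SNP covariate-adjusted association testing and genetic PCs.

A mass-univariate linear-regression GWAS: the phenotype and each dosage
column are residualized on the covariates once, which is algebraically
equivalent to per-SNP joint fits (Frisch-Waugh-Lovell) up to the residual
degrees of freedom; the df correction (n - k_cov - 2 for the slope SE,
counting intercept and the SNP itself) is applied.  P-values come from the
two-sided normal approximation, consistent with the downstream
meta-analysis; at the simulated sample sizes the difference from the t
distribution is negligible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .panel import SUMSTATS_COLUMNS, GenotypePanel

__all__ = ["run_gwas", "compute_pcs", "build_covariates"]


def build_covariates(cohort: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """The standard GWAS covariate set: age, age-squared, sex, array, PCs."""
    cols = {
        "age": cohort["Age"].to_numpy(float),
        "age2": cohort["Age"].to_numpy(float) ** 2,
        "sex": cohort["Sex"].to_numpy(float),
        "array": cohort["array"].to_numpy(float),
    }
    for k in range(1, n_pcs + 1):
        name = f"PC{k}"
        if name in cohort.columns:
            cols[name] = cohort[name].to_numpy(float)
    return pd.DataFrame(cols, index=cohort.index)


def _covariate_q(covariates, n: int):
    """Orthonormal basis of [intercept | covariates]; errors name rank-deficient columns."""
    if covariates is None:
        C = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(covariates, pd.DataFrame):
            names = ["intercept"] + [str(c) for c in covariates.columns]
            C = np.column_stack([np.ones(n), covariates.to_numpy(float)])
        else:
            arr = np.asarray(covariates, float)
            if arr.ndim == 1:
                arr = arr[:, None]
            names = ["intercept"] + [f"covar{j}" for j in range(arr.shape[1])]
            C = np.column_stack([np.ones(n), arr])
    q, r, piv = _qr_with_pivot(C)
    rank = np.sum(np.abs(np.diag(r)) > np.abs(r[0, 0]) * max(C.shape) * np.finfo(float).eps)
    if rank < C.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"covariate matrix is rank deficient; offending columns: {bad}")
    return q[:, : C.shape[1]], C.shape[1]


def _qr_with_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Least-squares GWAS of ``phenotype`` on each variant plus covariates.

    Rows with a missing phenotype are dropped; missing dosages are
    mean-imputed per variant.  A constant (zero-variance) dosage column
    gets the convention beta=0, se=+inf, p=1.
    """
    y = np.asarray(phenotype, float)
    if y.shape[0] != panel.n_samples:
        raise ValueError("phenotype length must equal panel n_samples")
    keep = np.isfinite(y)
    y = y[keep]
    n = int(keep.sum())
    X = panel.dosages[keep].astype(float)
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.loc[keep] if covariates.shape[0] == keep.shape[0] else covariates
    elif covariates is not None:
        covariates = np.asarray(covariates, float)[keep]

    # mean-impute missing dosages per variant
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]

    q, k_cov = _covariate_q(covariates, n)
    if n < k_cov + 2:
        raise ValueError("not enough samples for the covariate set plus one SNP")
    yr = y - q @ (q.T @ y)
    Xr = X - q @ (q.T @ X)

    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    syy = float(yr @ yr)
    if syy <= 1e-12 * n:  # degenerate (constant) phenotype
        sxy = np.zeros_like(sxy)
        syy = 0.0
    const = sxx <= 1e-12 * max(1.0, float(np.max(sxx, initial=1.0)))
    sxx_safe = np.where(const, 1.0, sxx)

    beta = np.where(const, 0.0, sxy / sxx_safe)
    df = n - k_cov - 1
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx_safe)
    se = np.where(const | (syy == 0.0), np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    p = np.where(const, 1.0, p)

    out = panel.variants[
        ["variant_id", "chromosome", "position", "effect_allele", "other_allele"]
    ].copy()
    out["beta"] = beta
    out["standard_error"] = se
    out["p_value"] = p
    out["n"] = n
    out["effect_allele_frequency"] = X.mean(axis=0) / 2.0
    return out[SUMSTATS_COLUMNS]


def compute_pcs(panel: GenotypePanel, k: int) -> np.ndarray:
    """First ``k`` PCs of the column-standardized dosage matrix.

    Columns are pairwise orthogonal and scaled to unit variance.  ``k=0``
    returns an (n, 0) matrix.
    """
    if k < 0 or k > min(panel.n_samples, panel.n_snps):
        raise ValueError("k must be in 0..min(n_samples, n_snps)")
    if k == 0:
        return np.empty((panel.n_samples, 0))
    X = panel.dosages.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(Xs)
    sd_scores = scores.std(axis=0)
    sd_scores[sd_scores == 0] = 1.0
    return scores / sd_scores
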