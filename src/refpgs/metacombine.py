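"""Multi-trait meta-analysis of GWAS summary statistics and union assembly.

Implements the moment-based multi-trait estimator (MTAG-style): each
cohort's per-variant effect is combined by generalized least squares using
a trait-by-trait genetic covariance Omega and a per-variant sampling
covariance Sigma.  The cohorts here are non-overlapping, so Sigma is
diagonal (squared standard errors) and no sample-overlap correction is
applied.  Variants present in the large-cohort subset but missing from the
smaller cohorts are recovered by a second meta-analysis of the subset and
a union assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SUMSTATS_COLUMNS

__all__ = ["MetaInputs", "align_alleles", "mtag_meta", "assemble_union"]

log = logging.getLogger(__name__)


@dataclass
class MetaInputs:
    """Allele-aligned multi-cohort inputs on a shared variant universe."""

    variants: pd.DataFrame          # variant_id/chromosome/position/effect/other allele
    betas: np.ndarray               # (m, T)
    ses: np.ndarray                 # (m, T)
    ns: np.ndarray                  # (m, T)
    labels: list[str]
    n_dropped_mismatch: int = 0

    @property
    def n_traits(self) -> int:
        return self.betas.shape[1]


def align_alleles(inputs: list[pd.DataFrame], labels: list[str] | None = None) -> MetaInputs:
    """Match cohorts by variant_id and harmonize effect alleles.

    The first cohort fixes the reference (effect, other) pair per variant;
    swapped alleles flip the beta sign (and the allele frequency); variants
    whose allele pair matches neither orientation are dropped with a logged
    count.  Only variants present in every cohort are kept.  Aligning an
    already-aligned input set changes nothing (involution).
    """
    if not inputs:
        raise ValueError("need at least one cohort")
    labels = labels or [f"cohort{i}" for i in range(len(inputs))]
    for lab, ss in zip(labels, inputs):
        if ss["variant_id"].duplicated().any():
            raise ValueError(f"duplicate variant ids within cohort {lab}")

    ref = inputs[0].set_index("variant_id")
    common = ref.index
    for ss in inputs[1:]:
        common = common.intersection(pd.Index(ss["variant_id"]))
    common = pd.Index(
        sorted(common, key=lambda v: (ref.loc[v, "chromosome"], ref.loc[v, "position"])),
        name="variant_id",
    )

    m = len(common)
    T = len(inputs)
    betas = np.empty((m, T))
    ses = np.empty((m, T))
    ns = np.empty((m, T))
    drop = np.zeros(m, bool)
    ref_ea = ref.loc[common, "effect_allele"].to_numpy()
    ref_oa = ref.loc[common, "other_allele"].to_numpy()

    for t, ss in enumerate(inputs):
        sub = ss.set_index("variant_id").loc[common]
        ea = sub["effect_allele"].to_numpy()
        oa = sub["other_allele"].to_numpy()
        same = (ea == ref_ea) & (oa == ref_oa)
        swapped = (ea == ref_oa) & (oa == ref_ea)
        drop |= ~(same | swapped)
        sign = np.where(swapped, -1.0, 1.0)
        betas[:, t] = sign * sub["beta"].to_numpy(float)
        ses[:, t] = sub["standard_error"].to_numpy(float)
        ns[:, t] = sub["n"].to_numpy(float)

    n_dropped = int(drop.sum())
    if n_dropped:
        log.info("align_alleles: dropped %d variants with mismatched allele pairs", n_dropped)
    keep = ~drop
    variants = (
        ref.loc[common, ["chromosome", "position", "effect_allele", "other_allele"]]
        .reset_index()
        .loc[keep]
        .reset_index(drop=True)
    )
    return MetaInputs(
        variants=variants,
        betas=betas[keep],
        ses=ses[keep],
        ns=ns[keep],
        labels=list(labels),
        n_dropped_mismatch=n_dropped,
    )


def estimate_omega(meta: MetaInputs) -> np.ndarray:
    """Method-of-moments genetic covariance: mean effect cross-products
    minus the sampling expectation on the diagonal, projected to the
    nearest positive-semidefinite matrix (negative eigenvalues clipped)."""
    B = meta.betas
    omega = (B.T @ B) / B.shape[0]
    omega -= np.diag((meta.ses**2).mean(axis=0))
    vals, vecs = np.linalg.eigh((omega + omega.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def mtag_meta(
    meta: MetaInputs,
    omega: np.ndarray | None = None,
    target: int = 0,
) -> pd.DataFrame:
    """Per-variant GLS combination of trait-specific effects for ``target``.

    For trait t with Omega column w_t and diagonal element w_tt, the
    estimate at variant j is

        beta_j = a' (Omega - w_t w_t'/w_tt + Sigma_j)^{-1} beta_hat_j / D_j,
        a = w_t / w_tt,   D_j = a' (...)^{-1} a,   se_j = 1/sqrt(D_j).

    With a single input the output equals the input.  A singular combined
    covariance at a variant falls back to inverse-variance weighting with a
    logged warning.  Omega is moment-estimated when not supplied.
    """
    T = meta.n_traits
    m = len(meta.variants)
    if T == 1:
        beta = meta.betas[:, 0]
        se = meta.ses[:, 0]
        nvec = meta.ns[:, 0]
    else:
        if omega is None:
            omega = estimate_omega(meta)
        omega = np.asarray(omega, float)
        if omega.shape != (T, T) or not np.allclose(omega, omega.T, atol=1e-10):
            raise ValueError("omega must be a symmetric (T, T) matrix")
        wt = omega[:, target]
        wtt = omega[target, target]
        if wtt <= 0:
            raise ValueError("omega has non-positive variance for the target trait")
        a = wt / wtt
        A = omega - np.outer(wt, wt) / wtt

        Sig = np.zeros((m, T, T))
        idx = np.arange(T)
        Sig[:, idx, idx] = meta.ses**2
        M = A[None, :, :] + Sig

        beta = np.empty(m)
        se = np.empty(m)
        fallback = 0
        # batch solve; variants with singular M fall back to IVW
        try:
            Minv_a = np.linalg.solve(M, np.broadcast_to(a, (m, T)).copy()[:, :, None])[:, :, 0]
            denom = Minv_a @ a
            num = np.einsum("mt,mt->m", Minv_a, meta.betas)
            good = np.isfinite(denom) & (denom > 0)
        except np.linalg.LinAlgError:
            good = np.zeros(m, bool)
            denom = np.zeros(m)
            num = np.zeros(m)
        beta[good] = num[good] / denom[good]
        se[good] = 1.0 / np.sqrt(denom[good])
        bad = ~good
        if bad.any():
            fallback = int(bad.sum())
            wiv = 1.0 / meta.ses[bad] ** 2
            beta[bad] = (wiv * meta.betas[bad]).sum(axis=1) / wiv.sum(axis=1)
            se[bad] = 1.0 / np.sqrt(wiv.sum(axis=1))
            log.warning(
                "mtag_meta: singular combined covariance at %d variants; "
                "fell back to inverse-variance weighting",
                fallback,
            )
        nvec = meta.ns.sum(axis=1)

    z = np.abs(beta / se)
    p = np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    out = meta.variants.copy()
    out["beta"] = beta
    out["standard_error"] = se
    out["p_value"] = p
    out["n"] = nvec
    out["effect_allele_frequency"] = np.nan
    return out[SUMSTATS_COLUMNS]


def assemble_union(
    meta_full: pd.DataFrame,
    meta_subset: pd.DataFrame,
    subset_only_ids,
) -> pd.DataFrame:
    """Two-stage union: all-cohort rows plus subset-only rows.

    ``subset_only_ids`` must be disjoint from ``meta_full``'s ids and a
    subset of ``meta_subset``'s; the output has
    ``len(meta_full) + len(subset_only_ids)`` rows, each traceable to
    exactly one source.
    """
    subset_only = pd.Index(subset_only_ids, name="variant_id")
    if subset_only.duplicated().any():
        raise ValueError("subset_only_ids contains duplicates")
    full_ids = pd.Index(meta_full["variant_id"])
    overlap = full_ids.intersection(subset_only)
    if len(overlap):
        raise ValueError(f"subset_only_ids overlap meta_full, e.g. {list(overlap[:5])}")
    sub_ids = pd.Index(meta_subset["variant_id"])
    missing = subset_only.difference(sub_ids)
    if len(missing):
        raise ValueError(f"subset_only_ids absent from meta_subset, e.g. {list(missing[:5])}")
    extra = meta_subset.set_index("variant_id").loc[subset_only].reset_index()
    out = pd.concat([meta_full, extra[meta_full.columns]], ignore_index=True)
    return out.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
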