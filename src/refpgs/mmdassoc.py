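"""Myopic macular degeneration (MMD) association analysis.

Worse-eye META-PM coding and the severe indicator (C3/C4 vs C0/C2, with C2
folded into "normal" because its grading is unreliable), a family-aware
five-tranche cross-fitted PGS so no participant is scored by a model
trained on them or their relatives, nested logistic models testing the
PGS -> MMD association with and without refractive error in the model
(standard maximum likelihood or Firth bias-reduced), and prevalence
arithmetic.

The refractive-error exposure enters as -avSER so coefficients read "per
diopter more negative" with OR > 1 for myopia, and the PGS is expected to
be standardized and oriented toward myopia risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GRADE_ORDER, GenotypePanel

__all__ = [
    "partition_tranches",
    "crossfit_pgs",
    "worse_eye",
    "severe_indicator",
    "logistic_assoc",
    "fit_firth_logistic",
    "prevalence",
    "MmdResult",
]

log = logging.getLogger(__name__)


def partition_tranches(
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    size_tolerance: float = 0.10,
) -> pd.Series:
    """Assign each participant a tranche label 1..k, families kept whole.

    Families are shuffled (seeded) and greedily placed into the currently
    smallest tranche (ties -> lowest label), which keeps tranche sizes
    within the tolerance for realistic family-size distributions.  A family
    larger than n/k*(1+tolerance) triggers a warning but is still assigned.
    """
    if "family_id" not in cohort.columns:
        raise ValueError("cohort missing family_id")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    fam_sizes = cohort.groupby("family_id").size()
    too_big = fam_sizes[fam_sizes > n / k * (1 + size_tolerance)]
    for fam, s in too_big.items():
        warnings.warn(f"family {fam} (size {s}) exceeds the tranche size tolerance")
    families = fam_sizes.index.to_numpy()
    order = rng.permutation(len(families))
    tranche_of_family = {}
    sizes = np.zeros(k, int)
    for fi in order:
        t = int(np.argmin(sizes))
        tranche_of_family[families[fi]] = t + 1
        sizes[t] += fam_sizes.iloc[fi]
    return cohort["family_id"].map(tranche_of_family).rename("tranche")


def crossfit_pgs(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    partition: pd.Series,
    derive_weights,
) -> np.ndarray:
    """Cross-fitted per-sample PGS: each tranche scored by a model trained
    on all other tranches.

    ``derive_weights(train_mask)`` must return a WeightVector DataFrame
    from data restricted to ``train_mask`` rows (the configured pipeline:
    GWAS -> meta-analysis with fixed external summary statistics ->
    shrinkage with frozen tuning parameters).  Every participant's score
    then derives from a model never trained on them or their relatives.
    """
    from .ldshrink import score_samples

    labels = np.asarray(partition)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("cross-fitting requires at least 2 tranches (training == scoring forbidden)")
    if len(labels) != panel.n_samples or len(labels) != len(cohort):
        raise ValueError("partition must cover all scored samples")
    scores = np.full(panel.n_samples, np.nan)
    for t in uniq:
        test = labels == t
        train = ~test
        weights = derive_weights(train)
        scores[test] = score_samples(panel.subset_samples(np.where(test)[0]), weights)
    return scores


def worse_eye(grade_right, grade_left) -> str:
    """Participant grade = worse eye under C0 < C2 < C3 < C4; one-eyed
    participants use the available eye; both missing is an error."""

    def _norm(g):
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return None
        g = str(g)
        if g not in GRADE_ORDER:
            raise ValueError(f"unknown META-PM grade {g!r}")
        return g

    r, l = _norm(grade_right), _norm(grade_left)
    if r is None and l is None:
        raise ValueError("both eye grades missing")
    if r is None:
        return l
    if l is None:
        return r
    return r if GRADE_ORDER[r] >= GRADE_ORDER[l] else l


def severe_indicator(grade: str) -> bool:
    """C3/C4 -> severe; C0/C2 -> normal (C2 folded into normal)."""
    if grade not in GRADE_ORDER:
        raise ValueError(f"unknown META-PM grade {grade!r}")
    return GRADE_ORDER[grade] >= GRADE_ORDER["C3"]


@dataclass
class MmdResult:
    """Odds ratios from one logistic model of severe MMD."""

    or_pgs: float
    or_pgs_ci: tuple[float, float]
    p_pgs: float
    or_ser: float | None
    or_ser_ci: tuple[float, float] | None
    p_ser: float | None
    include_ser: bool
    firth: bool
    n_cases: int
    n_controls: int
    converged: bool
    coef: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.or_pgs_ci
        if not (lo <= self.or_pgs <= hi):
            raise ValueError("PGS OR CI does not bracket the OR")


def _logistic_ml(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Plain Newton maximum-likelihood logistic fit; returns (beta, cov, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, converged


def fit_firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Firth bias-reduced logistic regression.

    Newton iteration on the Jeffreys-penalized score
    U*(b) = X'(y - p + h (1/2 - p)) with h the leverages of W^{1/2} X;
    returns (beta, cov, converged) with Wald covariance from the penalized
    information.  Yields finite estimates under (quasi-)separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(p * (1 - p), 1e-12, None)
        XW = X * np.sqrt(W)[:, None]
        H = XW.T @ XW
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", XW, Hinv, XW)
        grad = X.T @ (y - p + h * (0.5 - p))
        step = Hinv @ grad
        # step-halving for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step = step * (5.0 / norm)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    W = np.clip(p * (1 - p), 1e-12, None)
    H = (X * W[:, None]).T @ X
    cov = np.linalg.inv(H)
    return beta, cov, converged


def logistic_assoc(
    outcome,
    pgs,
    avser,
    covariates=None,
    include_ser: bool = False,
    firth: bool = False,
) -> MmdResult:
    """Nested logistic models of severe MMD on the PGS (and optionally SER).

    The design is [intercept, PGS, (-avSER if include_ser), covariates];
    ORs are exp(coefficients) with Wald 95% CIs.  Non-convergence of the
    standard fit raises with a suggestion to use ``firth=True``.
    """
    y = np.asarray(outcome).astype(float)
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    s = np.asarray(pgs, float)
    n = len(y)
    cols = [np.ones(n), s]
    names = ["intercept", "pgs"]
    if include_ser:
        cols.append(-np.asarray(avser, float))
        names.append("neg_avser")
    if covariates is not None:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        cnames = (
            [str(c) for c in covariates.columns]
            if isinstance(covariates, pd.DataFrame)
            else [f"covar{j}" for j in range(C.shape[1])]
        )
        cols.append(C)
        names.extend(cnames)
    X = np.column_stack(cols)

    if firth:
        beta, cov, converged = fit_firth_logistic(X, y)
    else:
        beta, cov, converged = _logistic_ml(X, y)
        if not converged or not np.all(np.isfinite(cov)):
            raise RuntimeError(
                "standard logistic fit did not converge (possible separation); try firth=True"
            )
    se = np.sqrt(np.diag(cov))
    zcrit = 1.959963984540054

    def _entry(j):
        with np.errstate(over="ignore"):
            or_ = float(np.exp(beta[j]))
            lo = float(np.exp(beta[j] - zcrit * se[j]))
            hi = float(np.exp(beta[j] + zcrit * se[j]))
        pv = float(2 * stats.norm.sf(abs(beta[j] / se[j]))) if se[j] > 0 else np.nan
        return or_, (lo, hi), pv

    or_pgs, ci_pgs, p_pgs = _entry(names.index("pgs"))
    if include_ser:
        or_ser, ci_ser, p_ser = _entry(names.index("neg_avser"))
    else:
        or_ser = ci_ser = p_ser = None
    return MmdResult(
        or_pgs=or_pgs,
        or_pgs_ci=ci_pgs,
        p_pgs=p_pgs,
        or_ser=or_ser,
        or_ser_ci=ci_ser,
        p_ser=p_ser,
        include_ser=include_ser,
        firth=firth,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        converged=bool(converged),
        coef={nm: float(b) for nm, b in zip(names, beta)},
    )


def prevalence(count: int, n: int, decimals: int = 2) -> float:
    """Percent prevalence 100*count/n rounded to ``decimals``."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= count <= n):
        raise ValueError("count must be in 0..n")
    return round(100.0 * count / n, decimals)
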