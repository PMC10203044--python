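"""Evaluation battery for a refractive-error polygenic score.

Refraction categories (myopia <= -0.50 D, moderate myopia <= -3.00 D,
moderate hyperopia >= +3.00 D, high myopia HM5 <= -5.00 D / HM6 <= -6.00 D),
per-ancestry standardization, incremental adjusted R^2 and AUROC with
percentile bootstrap confidence intervals (2000 replicates by default,
resampling participants; cases and controls are resampled separately for
classification metrics), paired bootstrap ROC comparison, tail odds
ratios, decile absolute risk, relative-performance arithmetic and simple
percentile-band refraction trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "classify",
    "standardize",
    "incremental_r2",
    "auroc",
    "compare_auroc",
    "tail_or",
    "decile_risk",
    "relative_improvement",
    "relative_decrease",
    "trajectory_bands",
    "EvalEstimate",
]

CATEGORY_THRESHOLDS = {
    "myopia": ("le", -0.50),
    "moderate_myopia": ("le", -3.00),
    "moderate_hyperopia": ("ge", 3.00),
    "HM5": ("le", -5.00),
    "HM6": ("le", -6.00),
}


@dataclass
class EvalEstimate:
    """Point estimate with a percentile bootstrap 95% CI."""

    value: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            # bootstrap medians can sit at a CI edge; only reject real violations
            if self.value < self.ci_low - 1e-12 or self.value > self.ci_high + 1e-12:
                raise ValueError("CI does not bracket the point estimate")

    def contains(self, x: float) -> bool:
        return self.ci_low <= x <= self.ci_high


def classify(avser) -> pd.DataFrame:
    """Boolean category flags per participant; boundaries are inclusive.

    HM6 implies HM5 implies moderate myopia implies myopia; moderate
    hyperopia and myopia are mutually exclusive.
    """
    x = np.asarray(avser, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("avSER must be finite")
    out = {}
    for name, (op, thr) in CATEGORY_THRESHOLDS.items():
        out[name] = x <= thr if op == "le" else x >= thr
    return pd.DataFrame(out)


def standardize(scores, groups=None) -> np.ndarray:
    """Z-score within each group (mean 0, sd 1); one group = global z-score."""
    x = np.asarray(scores, float)
    if groups is None:
        groups = np.zeros(len(x), int)
    groups = np.asarray(groups)
    out = np.empty_like(x)
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = x[mask].std()
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance")
        out[mask] = (x[mask] - x[mask].mean()) / sd
    return out


def _as_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        arr = covariates.to_numpy(float)
    else:
        arr = np.asarray(covariates, float)
        if arr.ndim == 1:
            arr = arr[:, None]
    return np.column_stack([np.ones(n), arr])


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    n, k = X.shape  # k includes the intercept
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    r2 = 1.0 - float((resid**2).sum()) / tss
    if n - k <= 0:
        raise ValueError("not enough observations for the design")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def incremental_r2(
    pheno,
    score,
    covariates=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalEstimate:
    """Incremental adjusted R^2 of the score over the covariate-only model.

    Point estimate = bootstrap median; CI = 2.5th/97.5th percentiles over
    ``n_boot`` resamples of participants.  Deterministic given ``seed``.
    """
    y = np.asarray(pheno, float)
    s = np.asarray(score, float)
    n = len(y)
    C = _as_matrix(covariates, n)
    if n < C.shape[1] + 2:
        raise ValueError("not enough observations for covariates plus score")
    full = np.column_stack([C, s])

    def stat(idx):
        return _adj_r2(y[idx], full[idx]) - _adj_r2(y[idx], C[idx])

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[b] = stat(idx)
    lo, med, hi = np.percentile(reps, [2.5, 50.0, 97.5])
    return EvalEstimate(float(med), float(lo), float(hi), n_boot)


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(roc_auc_score(labels, scores))


def _stratified_boot(rng, cases: np.ndarray, controls: np.ndarray):
    i = rng.integers(0, len(cases), len(cases))
    j = rng.integers(0, len(controls), len(controls))
    return cases[i], controls[j]


def auroc(labels, scores, n_boot: int = 2000, seed: int = 0) -> EvalEstimate:
    """AUROC (midrank Mann-Whitney statistic) with stratified bootstrap CI."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    point = _auc(y, s)
    cases = np.where(y == 1)[0]
    controls = np.where(y == 0)[0]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        ci_, co_ = _stratified_boot(rng, cases, controls)
        idx = np.concatenate([ci_, co_])
        reps[b] = _auc(y[idx], s[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return EvalEstimate(point, float(min(lo, point)), float(max(hi, point)), n_boot)


def compare_auroc(labels, scores1, scores2, n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired bootstrap test of AUROC difference on shared labels.

    D = (AUC1 - AUC2) / sd(bootstrap differences); two-sided normal p.
    """
    y = np.asarray(labels).astype(int)
    s1 = np.asarray(scores1, float)
    s2 = np.asarray(scores2, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    d0 = _auc(y, s1) - _auc(y, s2)
    cases = np.where(y == 1)[0]
    controls = np.where(y == 0)[0]
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ci_, co_ = _stratified_boot(rng, cases, controls)
        idx = np.concatenate([ci_, co_])
        diffs[b] = _auc(y[idx], s1[idx]) - _auc(y[idx], s2[idx])
    sd = diffs.std(ddof=1)
    if sd == 0:
        p = 1.0 if d0 == 0 else 0.0
        z = np.inf if d0 != 0 else 0.0
    else:
        z = d0 / sd
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc1": _auc(y, s1), "auc2": _auc(y, s2), "diff": d0, "z": float(z), "p": p}


def tail_or(zscores, labels, tail: float = 0.05, side: str = "low") -> dict:
    """Odds ratio of tail membership vs case status from the 2x2 table.

    Wald CI on log-OR; the Haldane-Anscombe 0.5 correction is applied when
    any cell is zero.
    """
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    z = np.asarray(zscores, float)
    y = np.asarray(labels).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    q = np.quantile(z, tail if side == "low" else 1 - tail)
    in_tail = z <= q if side == "low" else z >= q
    a = float(np.sum(in_tail & (y == 1)))
    b = float(np.sum(~in_tail & (y == 1)))
    c = float(np.sum(in_tail & (y == 0)))
    d = float(np.sum(~in_tail & (y == 0)))
    cells = np.array([a, b, c, d])
    if (cells == 0).any():
        cells = cells + 0.5
        a, b, c, d = cells
    if min(a, b, c, d) <= 0:
        raise ValueError("degenerate 2x2 table after correction")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = or_ * np.exp(-1.959963984540054 * se)
    hi = or_ * np.exp(1.959963984540054 * se)
    return {"or": or_, "ci_low": lo, "ci_high": hi, "table": (a, b, c, d)}


def decile_risk(zscores, labels) -> pd.DataFrame:
    """Per-decile case prevalence with Wilson binomial CIs.

    Deciles are assigned by stable rank (ties go to the lower decile);
    counts across deciles conserve the total case count.
    """
    z = np.asarray(zscores, float)
    y = np.asarray(labels).astype(int)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 observations")
    order = np.argsort(z, kind="stable")
    ranks = np.empty(n, int)
    ranks[order] = np.arange(n)
    decile = np.minimum((ranks * 10) // n, 9)
    rows = []
    for d in range(10):
        mask = decile == d
        nd = int(mask.sum())
        cases = int(y[mask].sum())
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(cases, nd, alpha=0.05, method="wilson")
        rows.append(
            {
                "decile": d + 1,
                "n": nd,
                "cases": cases,
                "prevalence": cases / nd,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overall_prevalence"] = float(y.mean())
    return out


def relative_improvement(r2_new: float, r2_old: float) -> float:
    """100 * (r2_new - r2_old) / r2_old; e.g. (0.190, 0.112) -> ~70%."""
    if r2_old <= 0:
        raise ValueError("reference R^2 must be > 0 for an improvement")
    return 100.0 * (r2_new - r2_old) / r2_old


def relative_decrease(r2: float, r2_reference: float) -> float:
    """100 * (r2_reference - r2) / r2_reference; e.g. (0.020, 0.190) -> ~89%."""
    if r2_reference <= 0:
        raise ValueError("reference R^2 must be > 0 for a decrease")
    return 100.0 * (r2_reference - r2) / r2_reference


def trajectory_bands(
    long: pd.DataFrame,
    zscores: pd.Series,
    percentiles=(5, 25, 50, 75, 95),
    half_width: float = 5.0,
    min_ages: int = 3,
) -> pd.DataFrame:
    """Mean refraction trajectory per PGS percentile band.

    ``long`` has columns (sample_id, age, avSER); ``zscores`` is indexed by
    sample_id.  A band at percentile p contains participants whose PGS
    percentile rank lies within +- ``half_width`` of p; participants with
    fewer than ``min_ages`` distinct ages are excluded.
    """
    for c in ("sample_id", "age", "avSER"):
        if c not in long.columns:
            raise ValueError(f"long table missing column {c!r}")
    counts = long.groupby("sample_id")["age"].nunique()
    eligible = counts[counts >= min_ages].index
    if len(eligible) == 0:
        raise ValueError(f"no participant has >= {min_ages} measurement ages")
    z = zscores.loc[zscores.index.intersection(eligible)]
    pct = z.rank(pct=True) * 100.0
    sub = long[long["sample_id"].isin(z.index)]
    rows = []
    for p in percentiles:
        band_ids = pct.index[(pct >= p - half_width) & (pct <= p + half_width)]
        band = sub[sub["sample_id"].isin(band_ids)]
        means = band.groupby("age")["avSER"].mean()
        for age, m in means.items():
            rows.append({"percentile": p, "age": age, "mean_avSER": m, "n": int(len(band_ids))})
    return pd.DataFrame(rows)
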