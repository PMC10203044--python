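"""Leave-one-chromosome-out (LOCO) inference of refractive error from AOSW.

The inference model regresses avSER on orthogonal polynomial expansions of
AOSW (order 10), Age (order 3) and EduYears (order 2), Sex, a raw
EduYears x AOSW product, a genome-minus-one-chromosome polygenic score
(PGS_loco), and PGS_loco x orthogonal AOSW polynomials up to order 2 —
20 design columns beyond the intercept.  Fitting one model per excluded
chromosome and assembling each chromosome's GWAS from the run that
excluded it ensures a chromosome's own SNPs never inform the phenotype
they are tested against.

Orthogonal polynomial bases are built by QR on the training Vandermonde
matrix of the standardized column and frozen, so out-of-sample application
spans the same monomial space and reproduces training fitted values
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "AoswModelSpec",
    "AoswModel",
    "OrthoPoly",
    "build_loco_weights",
    "LocoWeightSet",
    "infer_phenotype",
    "assemble_loco_gwas",
]


@dataclass
class AoswModelSpec:
    """Shape of the AOSW -> avSER inference model (serializable)."""

    aosw_order: int = 10
    age_order: int = 3
    edu_order: int = 2
    pgs_aosw_order: int = 2
    include_sex: bool = True
    include_edu_aosw: bool = True
    edu_years_degree: float = 21.0

    def __post_init__(self) -> None:
        for name in ("aosw_order", "age_order", "edu_order", "pgs_aosw_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AoswModelSpec":
        return cls(**d)


class OrthoPoly:
    """Orthonormal polynomial basis of one variable, frozen on training data.

    Built by economy QR on the Vandermonde matrix of the standardized
    column (powers 0..order); the intercept column is dropped.  New data
    are mapped through the stored inverse triangular factor, so applying
    the basis to the training column reproduces it exactly and any two
    bases spanning the same monomial space give identical fitted values.
    """

    def __init__(self, order: int):
        self.order = order
        self._mean: float | None = None
        self._sd: float | None = None
        self._rinv: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "OrthoPoly":
        x = np.asarray(x, float)
        self._mean = float(x.mean())
        sd = float(x.std())
        self._sd = sd if sd > 0 else 1.0
        v = np.vander((x - self._mean) / self._sd, N=self.order + 1, increasing=True)
        q, r = np.linalg.qr(v)
        diag = np.abs(np.diag(r))
        if np.any(diag < 1e-10 * diag.max()):
            raise ValueError(
                f"polynomial basis of order {self.order} is numerically collinear "
                "(too few distinct values?)"
            )
        self._rinv = np.linalg.inv(r)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self._rinv is None:
            raise RuntimeError("OrthoPoly must be fit before transform")
        x = np.asarray(x, float)
        v = np.vander((x - self._mean) / self._sd, N=self.order + 1, increasing=True)
        return (v @ self._rinv)[:, 1:]


class AoswModel:
    """The avSER ~ f(AOSW, Age, Sex, EduYears, PGS_loco) inference model.

    scikit-learn shaped: ``fit(cohort, loco_pgs)`` then
    ``predict(cohort, loco_pgs)``.  Fitted attributes carry a trailing
    underscore.  Training rows must have numeric AOSW (never-wearers are
    excluded by the default policy upstream), avSER, Age, Sex and EduYears.
    """

    REQUIRED = ("AOSW", "Age", "Sex", "EduYears")

    def __init__(self, spec: AoswModelSpec | None = None):
        self.spec = spec or AoswModelSpec()

    # -- design construction -------------------------------------------
    def _design(self, cohort: pd.DataFrame, pgs: np.ndarray, fit: bool) -> np.ndarray:
        s = self.spec
        missing = [c for c in self.REQUIRED if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort missing predictor columns: {missing}")
        aosw = cohort["AOSW"].to_numpy(float)
        age = cohort["Age"].to_numpy(float)
        edu = cohort["EduYears"].to_numpy(float)
        if fit:
            self._poly_aosw_ = OrthoPoly(s.aosw_order).fit(aosw)
            self._poly_age_ = OrthoPoly(s.age_order).fit(age)
            self._poly_edu_ = OrthoPoly(s.edu_order).fit(edu)
            self._poly_aosw2_ = OrthoPoly(s.pgs_aosw_order).fit(aosw)
        cols = [self._poly_aosw_.transform(aosw), self._poly_age_.transform(age)]
        names = [f"aosw^{j}" for j in range(1, s.aosw_order + 1)]
        names += [f"age^{j}" for j in range(1, s.age_order + 1)]
        if s.include_sex:
            cols.append(cohort["Sex"].to_numpy(float)[:, None])
            names.append("sex")
        cols.append(self._poly_edu_.transform(edu))
        names += [f"edu^{j}" for j in range(1, s.edu_order + 1)]
        if s.include_edu_aosw:
            # raw (not polynomial) AOSW in the product, per the stated contract
            cols.append((edu * aosw)[:, None])
            names.append("edu_x_aosw")
        cols.append(np.asarray(pgs, float)[:, None])
        names.append("pgs_loco")
        basis2 = self._poly_aosw2_.transform(aosw)
        cols.append(basis2 * np.asarray(pgs, float)[:, None])
        names += [f"pgs_x_aosw^{j}" for j in range(1, s.pgs_aosw_order + 1)]
        if fit:
            self.term_names_ = names
        return np.column_stack(cols)

    def fit(self, cohort: pd.DataFrame, loco_pgs: np.ndarray) -> "AoswModel":
        if "avSER" not in cohort.columns:
            raise ValueError("cohort missing avSER")
        mask = np.isfinite(cohort["AOSW"].to_numpy(float)) & np.isfinite(
            cohort["avSER"].to_numpy(float)
        )
        train = cohort.loc[mask]
        pgs = np.asarray(loco_pgs, float)[mask]
        X = self._design(train, pgs, fit=True)
        Xd = np.column_stack([np.ones(len(train)), X])
        if len(train) < Xd.shape[1]:
            raise ValueError("fewer training rows than design columns")
        rank = np.linalg.matrix_rank(Xd)
        if rank < Xd.shape[1]:
            # identify near-collinear terms by pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(Xd, mode="economic", pivoting=True)
            bad = [(["intercept"] + self.term_names_)[j] for j in piv[rank:]]
            raise ValueError(f"collinear design; dropped terms would be: {bad}")
        y = train["avSER"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        self.coef_ = coef
        fitted = Xd @ coef
        self.train_index_ = train.index.to_numpy()
        self.fitted_values_ = fitted
        resid = y - fitted
        self.train_r2_ = 1.0 - resid.var() / y.var()
        self.n_train_ = len(train)
        return self

    def predict(self, cohort: pd.DataFrame, loco_pgs: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("AoswModel must be fit before predict")
        aosw = cohort["AOSW"].to_numpy(float)
        ok = np.isfinite(aosw)
        out = np.full(len(cohort), np.nan)
        if ok.any():
            X = self._design(cohort.loc[ok], np.asarray(loco_pgs, float)[ok], fit=False)
            out[ok] = self.coef_[0] + X @ self.coef_[1:]
        return out

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "AoswModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def build_loco_weights(
    sumstats: pd.DataFrame,
    method: str = "marginal-scaled",
    excluded: int | None = None,
    *,
    h2: float = 0.3,
    ld=None,
) -> pd.DataFrame:
    """PGS weights for all variants not on the excluded chromosome.

    ``marginal-scaled``: each GWAS beta is shrunk by the infinitesimal
    posterior factor c = (h2/m) / (h2/m + 1/n) — the per-SNP prior variance
    h2/m against the sampling variance 1/n of a standardized effect.
    ``ridge``: per-LD-block closed form (R + m/(n h2) I)^-1 beta on the
    standardized scale, using an :class:`~refpgs.ldshrink.LDBlockSet`
    reference; reduces to marginal-scaled when every block is the identity.
    """
    if excluded is not None and not (1 <= excluded <= 22):
        raise ValueError("excluded chromosome must be in 1..22")
    ss = sumstats
    keep = ss["chromosome"].to_numpy() != excluded if excluded is not None else np.ones(len(ss), bool)
    sub = ss.loc[keep].reset_index(drop=True)
    m = len(sub)
    n = float(np.median(sub["n"].to_numpy(float)))
    beta = sub["beta"].to_numpy(float)

    if method == "marginal-scaled":
        c = (h2 / m) / (h2 / m + 1.0 / n)
        w = c * beta
    elif method == "ridge":
        if ld is None:
            raise ValueError("ridge method requires an LD block set")
        lam = m / (n * h2)
        se = sub["standard_error"].to_numpy(float)
        # standardized effects via z/sqrt(n); converted back through se*sqrt(n)
        z = beta / se
        bstd = z / np.sqrt(sub["n"].to_numpy(float))
        w_std = np.empty(m)
        pos = pd.Series(np.arange(m), index=sub["variant_id"])
        for ids, R in ld.blocks:
            present = [v for v in ids if v in pos.index]
            if not present:
                continue
            bi = pos.loc[present].to_numpy()
            sel = [list(ids).index(v) for v in present]
            Rb = R[np.ix_(sel, sel)]
            w_std[bi] = np.linalg.solve(Rb + lam * np.eye(len(bi)), bstd[bi])
        w = w_std * se * np.sqrt(sub["n"].to_numpy(float))
    else:
        raise ValueError(f"unknown weight method {method!r}")

    return pd.DataFrame(
        {
            "variant_id": sub["variant_id"].to_numpy(),
            "chromosome": sub["chromosome"].to_numpy(),
            "effect_allele": sub["effect_allele"].to_numpy(),
            "other_allele": sub["other_allele"].to_numpy(),
            "effect_weight": w,
        }
    )


class LocoWeightSet:
    """22 weight vectors, entry k excluding every chromosome-k variant."""

    def __init__(self, entries: dict[int, pd.DataFrame]):
        for k, w in entries.items():
            if (w["chromosome"].to_numpy() == k).any():
                raise ValueError(f"weight set for excluded chromosome {k} contains chr {k} variants")
        self.entries = dict(sorted(entries.items()))

    @classmethod
    def from_sumstats(
        cls, sumstats: pd.DataFrame, chromosomes=range(1, 23), **kw
    ) -> "LocoWeightSet":
        return cls({k: build_loco_weights(sumstats, excluded=k, **kw) for k in chromosomes})

    def for_chromosome(self, k: int) -> pd.DataFrame:
        return self.entries[k]

    @property
    def excluded_chromosomes(self) -> list[int]:
        return list(self.entries)


def infer_phenotype(fit: AoswModel, cohort: pd.DataFrame, loco_pgs: np.ndarray) -> np.ndarray:
    """AOSW-inferred avSER per participant (D); never-wearers yield NaN."""
    return fit.predict(cohort, loco_pgs)


def assemble_loco_gwas(runs: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the final LOCO GWAS: chromosome k rows from the run excluding k.

    ``runs`` maps excluded chromosome -> full-genome SumStats from the model
    fit without that chromosome.  A pure row selection: betas and SEs are
    untouched.
    """
    tags = list(runs)
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate exclusion tags")
    pieces = []
    for k, ss in runs.items():
        piece = ss.loc[ss["chromosome"].to_numpy() == k]
        if piece.empty:
            raise ValueError(f"run excluding chromosome {k} has no chromosome-{k} rows")
        pieces.append(piece)
    chroms = {int(c) for ss in runs.values() for c in ss["chromosome"].unique()}
    missing = chroms - set(tags)
    if missing:
        raise ValueError(f"no run excludes chromosome(s) {sorted(missing)}")
    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    if out["variant_id"].duplicated().any():
        raise ValueError("assembled LOCO sumstats contain duplicate variants")
    return out
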