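"""Core data containers: genotype panels, cohort tables, summary statistics.

``GenotypePanel`` holds a dosage matrix plus variant metadata; cohort
phenotypes travel as a pandas DataFrame with fixed column names
(:data:`COHORT_COLUMNS`); GWAS summary statistics and PGS weight vectors
are DataFrames with the column sets below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "VARIANT_COLUMNS",
    "SUMSTATS_COLUMNS",
    "WEIGHT_COLUMNS",
    "COHORT_COLUMNS",
    "GRADES",
    "GRADE_ORDER",
    "validate_sumstats",
]

VARIANT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "allele_frequency",
]

# GWAS-SSF-like summary-statistic dialect used throughout.
SUMSTATS_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "n",
    "effect_allele_frequency",
]

WEIGHT_COLUMNS = ["variant_id", "chromosome", "effect_allele", "other_allele", "effect_weight"]

COHORT_COLUMNS = [
    "sample_id",
    "avSER",
    "AOSW",
    "never_wearer",
    "Age",
    "Sex",
    "EduYears",
    "array",
    "family_id",
    "ancestry",
    "true_genetic_value",
    "eyeR_grade",
    "eyeL_grade",
]

GRADES = ("C0", "C2", "C3", "C4")
GRADE_ORDER = {"C0": 0, "C2": 1, "C3": 2, "C4": 3}


@dataclass
class GenotypePanel:
    """Dosage matrix (n_samples x n_snps, values in [0, 2]) with metadata.

    ``variants`` is a DataFrame with :data:`VARIANT_COLUMNS`, sorted by
    (chromosome, position); ``allele_frequency`` is the effect-allele
    population frequency used by the generator.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    blocks: list[np.ndarray] = field(default_factory=list)  # column-index blocks (LD units)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosages = np.asarray(self.dosages)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows != number of sample_ids")
        if m != len(self.variants):
            raise ValueError("dosage columns != number of variants")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table missing columns: {missing}")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_ids in panel")
        chrom = self.variants["chromosome"].to_numpy()
        pos = self.variants["position"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(m)):
            raise ValueError("variants must be sorted by (chromosome, position)")
        dmin = float(np.nanmin(self.dosages)) if self.dosages.size else 0.0
        dmax = float(np.nanmax(self.dosages)) if self.dosages.size else 0.0
        if dmin < -1e-9 or dmax > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=self.sample_ids[index],
            variants=self.variants.copy(),
            dosages=self.dosages[index],
            blocks=[b.copy() for b in self.blocks],
        )

    def chromosome_mask(self, chromosome: int) -> np.ndarray:
        return (self.variants["chromosome"].to_numpy() == chromosome)

    def subset_variants(self, mask) -> "GenotypePanel":
        """Column subset (boolean mask or index array); LD blocks are remapped
        and blocks left partially selected are truncated to their kept members."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        new_pos = -np.ones(self.n_snps, dtype=int)
        new_pos[idx] = np.arange(len(idx))
        blocks = []
        for b in self.blocks:
            kept = new_pos[b]
            kept = kept[kept >= 0]
            if len(kept):
                blocks.append(kept)
        return GenotypePanel(
            sample_ids=self.sample_ids.copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            blocks=blocks,
        )


def validate_sumstats(ss: pd.DataFrame, *, check_p: bool = True) -> None:
    """Validate the summary-statistic invariants.

    ``p_value`` must be consistent with ``beta / standard_error`` under the
    two-sided normal approximation (1e-6 relative), SEs positive, ids unique.
    """
    from scipy import stats

    missing = [c for c in SUMSTATS_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"sumstats missing columns: {missing}")
    if ss["variant_id"].duplicated().any():
        dup = ss.loc[ss["variant_id"].duplicated(), "variant_id"].head().tolist()
        raise ValueError(f"duplicate variant_ids in sumstats, e.g. {dup}")
    se = ss["standard_error"].to_numpy(float)
    finite = np.isfinite(se)
    if np.any(se[finite] <= 0):
        raise ValueError("standard_error must be > 0")
    p = ss["p_value"].to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p_value must be in (0, 1]")
    if check_p:
        z = np.abs(ss["beta"].to_numpy(float)[finite] / se[finite])
        expected = 2 * stats.norm.sf(z)
        ok = expected > 1e-300
        rel = np.abs(p[finite][ok] - expected[ok]) / expected[ok]
        if rel.size and np.nanmax(rel) > 1e-6:
            raise ValueError("p_value inconsistent with beta/standard_error")
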