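"""Configuration objects for the simulation and pipeline stages.

All randomness in the package flows from a single master seed; each stage
derives a child generator through :func:`child_rng`, a documented counter
scheme built on :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["SimConfig", "ShrinkGrid", "child_rng", "SimConfigError"]


class SimConfigError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


# Stage names -> stable integers for seed derivation.  Appending is fine,
# reordering is not (it would change every derived stream).
_STAGE_IDS = {
    "panel": 0,
    "phenotypes": 1,
    "aosw": 2,
    "mmd": 3,
    "families": 4,
    "gibbs": 5,
    "tranches": 6,
    "bootstrap": 7,
    "ancestry": 8,
    "pipeline": 9,
}


def child_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Derive a per-stage random generator from the master seed.

    The stream is ``SeedSequence(seed, spawn_key=(stage_id, index))`` so that
    stages never share a stream and replicate ``index`` can vary one stage
    without touching the others.
    """
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_IDS[stage], index))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the European adult GWAS cohorts the analysis targets:
    avSER ~ -0.28 D mean, 2.72 D spread, age ~58 y, ~53% female, and a
    severe-MMD (META-PM C3/C4) prevalence around 0.3% driven by an odds
    ratio of 1.28 per diopter more negative refraction.
    """

    n_samples: int = 2000
    n_snps: int = 2200
    n_chromosomes: int = 22
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 10
    ld_rho: float = 0.5
    h2: float = 0.3
    p_causal: float = 0.01
    ser_mean: float = -0.28
    ser_sd: float = 2.72
    # covariate distributions and their effects on avSER (D units)
    age_mean: float = 58.2
    age_sd: float = 8.0
    female_fraction: float = 0.534
    degree_fraction: float = 0.32
    edu_years_degree: float = 21.0
    age_effect: float = 0.01     # D per year of age (hyperopic drift)
    sex_effect: float = 0.10     # D, female vs male
    edu_effect: float = -0.08    # D per education year (education -> myopia)
    array_fraction: float = 0.1  # second genotyping array
    n_pcs: int = 10
    pc_mode: str = "compute"     # "compute" | "zero"
    # spectacle-onset (AOSW) observation model
    onset_intercept: float = 17.0   # years at avSER = 0
    onset_slope: float = 1.5        # years per diopter (positive: myopes earlier)
    onset_noise_sd: float = 3.0
    never_wearer_threshold: float = 0.0  # avSER above this -> never-wearer
    aosw_min: float = 5.0
    # per-eye severe-MMD model: logit(p) = intercept + beta_ser*(-avSER) + beta_direct*pgs
    mmd_intercept: float = -6.8
    mmd_beta_ser: float = math.log(1.28)
    mmd_beta_direct: float = 0.0
    c4_fraction: float = 49.0 / (169.0 + 49.0)  # C4 share among severe eyes
    c2_fraction: float = 0.02                   # C2 share among non-severe eyes
    # family structure
    n_families: int | None = None
    family_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise SimConfigError(f"{name}: {msg}")

        _check(self.n_samples >= 1, "n_samples", "must be >= 1")
        _check(self.n_snps >= 1, "n_snps", "must be >= 1")
        _check(1 <= self.n_chromosomes <= 22, "n_chromosomes", "must be in 1..22")
        _check(
            self.n_snps >= self.n_chromosomes,
            "n_snps",
            "must be >= n_chromosomes so every chromosome is non-empty",
        )
        _check(0 < self.maf_low <= 0.5, "maf_low", "must be in (0, 0.5]")
        _check(
            self.maf_low <= self.maf_high <= 0.5,
            "maf_high",
            "must be in [maf_low, 0.5]",
        )
        _check(self.ld_block_size >= 1, "ld_block_size", "must be >= 1")
        _check(0 <= self.ld_rho < 1, "ld_rho", "must be in [0, 1)")
        _check(0 <= self.h2 <= 1, "h2", "must be in [0, 1]")
        _check(0 < self.p_causal <= 1, "p_causal", "must be in (0, 1]")
        _check(self.ser_sd > 0, "ser_sd", "must be > 0")
        _check(self.onset_noise_sd >= 0, "onset_noise_sd", "must be >= 0")
        _check(0 <= self.c4_fraction <= 1, "c4_fraction", "must be in [0, 1]")
        _check(0 <= self.c2_fraction <= 1, "c2_fraction", "must be in [0, 1]")
        _check(self.n_pcs >= 0, "n_pcs", "must be >= 0")
        _check(self.pc_mode in ("compute", "zero"), "pc_mode", "must be 'compute' or 'zero'")
        if self.n_families is not None:
            _check(
                0 < self.n_families <= self.n_samples,
                "n_families",
                "must be in 1..n_samples",
            )
        probs = self.family_size_probs
        _check(
            len(probs) > 0 and all(k >= 1 for k in probs),
            "family_size_probs",
            "sizes must be >= 1",
        )
        total = sum(probs.values())
        _check(total > 0, "family_size_probs", "probabilities must sum to > 0")
        for fname in ("mmd_intercept", "mmd_beta_ser", "mmd_beta_direct"):
            _check(math.isfinite(getattr(self, fname)), fname, "must be finite")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["family_size_probs"] = {int(k): float(v) for k, v in d["family_size_probs"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "family_size_probs" in d:
            d["family_size_probs"] = {int(k): float(v) for k, v in d["family_size_probs"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ShrinkGrid:
    """The shrinkage tuning grid: heritability x causal fraction x sparsity.

    The causal-fraction axis plays the role the source grid labels a
    "P-value threshold"; grid defaults follow the published tuning grid
    (4 x 6 x 2 = 48 cells).
    """

    h2_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    p_values: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    sparse_values: tuple[bool, ...] = (True, False)
    n_iter: int = 500
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.h2_values = tuple(self.h2_values)
        self.p_values = tuple(self.p_values)
        self.sparse_values = tuple(self.sparse_values)
        if not self.h2_values or not self.p_values or not self.sparse_values:
            raise SimConfigError("ShrinkGrid: all grid axes must be non-empty")
        if not (self.n_iter > self.burn_in >= 0):
            raise SimConfigError("ShrinkGrid: need n_iter > burn_in >= 0")

    def cells(self):
        """Iterate (h2, p, sparse) in a fixed, documented order."""
        for h2 in self.h2_values:
            for p in self.p_values:
                for sparse in self.sparse_values:
                    yield (h2, p, sparse)

    @property
    def n_cells(self) -> int:
        return len(self.h2_values) * len(self.p_values) * len(self.sparse_values)
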