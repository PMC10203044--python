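"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:
genotype dosages over 22 autosomes with block linkage disequilibrium
(Gaussian-copula haplotypes, AR(1) latent correlation within a block), a
polygenic refractive-error trait (avSER, diopters) with covariate effects,
an age-of-onset-of-spectacle-wear (AOSW) observation process, family
clusters, and per-eye META-PM grades for myopic macular degeneration.

Every generator is a pure function of (config, seed): the same
configuration yields byte-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, child_rng
from .panel import GRADES, GenotypePanel

__all__ = [
    "simulate_panel",
    "simulate_phenotypes",
    "simulate_aosw",
    "simulate_mmd",
    "assign_families",
    "simulate_cohort",
    "resample_ancestry_effects",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def _chromosome_sizes(n_snps: int, n_chromosomes: int) -> np.ndarray:
    """Distribute n_snps over chromosomes as evenly as possible (all non-empty)."""
    base = n_snps // n_chromosomes
    rem = n_snps % n_chromosomes
    return np.array([base + (1 if c < rem else 0) for c in range(n_chromosomes)])


def _ar1_latent(rng: np.random.Generator, n: int, sizes: list[int], rho: float) -> np.ndarray:
    """Latent AR(1) Gaussian matrix, independent across the given blocks."""
    m = int(sum(sizes))
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    start = 0
    for size in sizes:
        z[:, start] = eps[:, start]
        for j in range(1, size):
            z[:, start + j] = rho * z[:, start + j - 1] + np.sqrt(1 - rho**2) * eps[:, start + j]
        start += size
    return z


def simulate_panel(config: SimConfig, *, maf: np.ndarray | None = None) -> GenotypePanel:
    """Generate a genotype panel with Hardy-Weinberg block-LD dosages.

    Two haplotypes per sample are drawn from a Gaussian copula: within each
    block of ``ld_block_size`` SNPs the latent variables follow an AR(1)
    correlation ``ld_rho``; blocks never span chromosome boundaries.  An
    allele indicator is 1 where the latent value falls below the MAF
    quantile, so each variant is Binomial(2, maf) marginally.

    ``maf`` optionally fixes the per-variant allele frequencies (used when
    emulating a second ancestry on the same variant universe).
    """
    config.validate()
    rng = child_rng(config.seed, "panel")
    sizes = _chromosome_sizes(config.n_snps, config.n_chromosomes)

    if maf is None:
        maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    else:
        maf = np.asarray(maf, float)
        if maf.shape != (config.n_snps,):
            raise ValueError("maf must have length n_snps")

    records = []
    blocks: list[np.ndarray] = []
    dosages = np.empty((config.n_samples, config.n_snps), dtype=np.float32)
    col = 0
    for chrom_idx, m_c in enumerate(sizes):
        chrom = chrom_idx + 1
        block_sizes = []
        left = int(m_c)
        while left > 0:
            b = min(config.ld_block_size, left)
            block_sizes.append(b)
            left -= b
        thresh = stats.norm.ppf(maf[col : col + m_c])
        hap1 = _ar1_latent(rng, config.n_samples, block_sizes, config.ld_rho) < thresh
        hap2 = _ar1_latent(rng, config.n_samples, block_sizes, config.ld_rho) < thresh
        dosages[:, col : col + m_c] = hap1.astype(np.float32) + hap2.astype(np.float32)
        start = col
        for b in block_sizes:
            blocks.append(np.arange(start, start + b))
            start += b
        for j in range(m_c):
            ea, oa = _ALLELE_PAIRS[(chrom + j) % len(_ALLELE_PAIRS)]
            records.append(
                {
                    "variant_id": f"snp{chrom}_{j}",
                    "chromosome": chrom,
                    "position": (j + 1) * 1000,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "allele_frequency": maf[col + j],
                }
            )
        col += m_c

    variants = pd.DataFrame.from_records(records)
    sample_ids = np.array([f"id{i:06d}" for i in range(config.n_samples)])
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages, blocks=blocks)


def _draw_covariates(rng: np.random.Generator, config: SimConfig, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 40.0, 75.0)
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    degree = rng.random(n) < config.degree_fraction
    edu = np.where(degree, config.edu_years_degree, rng.integers(15, 20, n).astype(float))
    array = (rng.random(n) < config.array_fraction).astype(int)
    return pd.DataFrame({"Age": age, "Sex": sex, "EduYears": edu, "array": array})


def simulate_phenotypes(
    panel: GenotypePanel,
    config: SimConfig,
    *,
    causal: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate avSER and covariates on top of a genotype panel.

    ``p_causal * n_snps`` causal variants receive normal effects, scaled so
    the genetic variance equals ``h2 * ser_sd**2``; covariate terms and
    Gaussian noise fill the remaining variance so the trait variance is
    ``ser_sd**2``.  The realized genetic component is retained as
    ``true_genetic_value`` (simulation truth, for testing only), and the
    causal-effect table is attached as ``cohort.attrs["causal"]``.

    ``causal`` optionally reuses an existing causal-effect table (columns
    ``variant_id``, ``raw_effect``) so a second ancestry can share, or
    partially share, the causal architecture.
    """
    config.validate()
    if panel.n_snps != config.n_snps or panel.n_samples != config.n_samples:
        raise ValueError("panel dimensions do not match config (n_samples, n_snps)")
    rng = child_rng(config.seed, "phenotypes")
    n, m = panel.dosages.shape

    if causal is None:
        n_causal = max(1, int(round(config.p_causal * m)))
        idx = np.sort(rng.choice(m, size=n_causal, replace=False))
        raw_effect = rng.standard_normal(n_causal)
        causal = pd.DataFrame(
            {"variant_id": panel.variants["variant_id"].to_numpy()[idx], "raw_effect": raw_effect}
        )
    pos = panel.variants.reset_index().set_index("variant_id")["index"]
    idx = pos.loc[causal["variant_id"]].to_numpy()
    raw_effect = causal["raw_effect"].to_numpy(float)

    freq = panel.variants["allele_frequency"].to_numpy()[idx]
    centered = panel.dosages[:, idx].astype(float) - 2.0 * freq
    g_raw = centered @ raw_effect
    sd_raw = g_raw.std()
    target_gvar = config.h2 * config.ser_sd**2
    if config.h2 > 0 and sd_raw > 0:
        g = g_raw * np.sqrt(target_gvar) / sd_raw
    else:
        g = np.zeros(n)

    cov = _draw_covariates(rng, config, n)
    cov_term = (
        config.age_effect * (cov["Age"] - cov["Age"].mean())
        + config.sex_effect * (cov["Sex"] - cov["Sex"].mean())
        + config.edu_effect * (cov["EduYears"] - cov["EduYears"].mean())
    ).to_numpy()
    var_left = config.ser_sd**2 - target_gvar - cov_term.var()
    if var_left < 0:
        raise ValueError(
            "h2 plus covariate effects exceed total trait variance ser_sd**2; "
            "reduce h2 or the covariate effect sizes"
        )
    noise = rng.normal(0.0, np.sqrt(var_left), n)
    avser = config.ser_mean + (g - g.mean()) + cov_term + (noise - noise.mean())

    cohort = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "avSER": avser,
            "Age": cov["Age"].to_numpy(),
            "Sex": cov["Sex"].to_numpy(),
            "EduYears": cov["EduYears"].to_numpy(),
            "array": cov["array"].to_numpy(),
            "ancestry": "EUR",
            "true_genetic_value": g,
        }
    )
    if config.pc_mode == "zero":
        for k in range(config.n_pcs):
            cohort[f"PC{k + 1}"] = 0.0
    else:
        from .gwasassoc import compute_pcs

        k = min(config.n_pcs, panel.n_samples, panel.n_snps)
        pcs = compute_pcs(panel, k)
        for j in range(k):
            cohort[f"PC{j + 1}"] = pcs[:, j]
    cohort.attrs["causal"] = causal
    cohort.attrs["g_raw_sd"] = float(sd_raw)
    return cohort


def simulate_aosw(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach AOSW: a monotone-in-myopia spectacle-onset model.

    Expected onset age is ``onset_intercept + onset_slope * avSER`` (more
    negative avSER -> earlier onset), plus Gaussian noise.  Participants
    whose modeled onset exceeds their current age, or whose avSER is above
    ``never_wearer_threshold``, are flagged never-wearers (AOSW = NaN).
    Observed AOSW is clamped to [aosw_min, Age].
    """
    if "avSER" not in cohort.columns:
        raise ValueError("cohort must have avSER before AOSW can be simulated")
    config.validate()
    rng = child_rng(config.seed, "aosw")
    out = cohort.copy()
    avser = out["avSER"].to_numpy(float)
    age = out["Age"].to_numpy(float)
    onset = config.onset_intercept + config.onset_slope * avser
    if config.onset_noise_sd > 0:
        onset = onset + rng.normal(0.0, config.onset_noise_sd, len(out))
    never = (avser > config.never_wearer_threshold) | (onset > age)
    aosw = np.clip(onset, config.aosw_min, age)
    aosw[never] = np.nan
    out["AOSW"] = aosw
    out["never_wearer"] = never
    return out


def simulate_mmd(
    cohort: pd.DataFrame,
    pgs: np.ndarray | None,
    config: SimConfig,
) -> pd.DataFrame:
    """Attach per-eye META-PM grades from a logistic severe-MMD model.

    Each eye is independently severe with
    ``logit(p) = mmd_intercept + mmd_beta_ser * (-avSER) + mmd_beta_direct * pgs``;
    severe eyes are split C3/C4 by ``c4_fraction``, non-severe eyes C0/C2 by
    ``c2_fraction``.  ``pgs`` should be standardized (mean 0, sd 1) and
    oriented so larger values mean greater myopia risk; absent -> treated
    as 0 (no direct genetic path).
    """
    if "avSER" not in cohort.columns:
        raise ValueError("cohort must have avSER before MMD can be simulated")
    config.validate()
    rng = child_rng(config.seed, "mmd")
    out = cohort.copy()
    n = len(out)
    avser = out["avSER"].to_numpy(float)
    score = np.zeros(n) if pgs is None else np.asarray(pgs, float)
    if score.shape != (n,):
        raise ValueError("pgs length must match cohort")
    logit = config.mmd_intercept + config.mmd_beta_ser * (-avser) + config.mmd_beta_direct * score
    p = 1.0 / (1.0 + np.exp(-logit))
    for eye in ("eyeR_grade", "eyeL_grade"):
        severe = rng.random(n) < p
        grade = np.where(
            severe,
            np.where(rng.random(n) < config.c4_fraction, "C4", "C3"),
            np.where(rng.random(n) < config.c2_fraction, "C2", "C0"),
        )
        out[eye] = pd.Categorical(grade, categories=list(GRADES))
    return out


def assign_families(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Partition participants into family clusters.

    Family sizes are drawn from ``family_size_probs``.  When ``n_families``
    is given, exactly that many families are created and sizes are adjusted
    (one member at a time, largest-first removal / round-robin addition) so
    they sum to ``n_samples``; otherwise families are drawn until everyone
    is assigned.
    """
    config.validate()
    n = len(cohort)
    if config.n_families is not None and config.n_families > n:
        raise ValueError("n_families exceeds number of participants")
    rng = child_rng(config.seed, "families")
    sizes_avail = np.array(sorted(config.family_size_probs))
    probs = np.array([config.family_size_probs[s] for s in sizes_avail], float)
    probs = probs / probs.sum()

    if config.n_families is None:
        sizes: list[int] = []
        total = 0
        while total < n:
            s = int(rng.choice(sizes_avail, p=probs))
            s = min(s, n - total)
            sizes.append(s)
            total += s
    else:
        k = config.n_families
        sizes = [int(s) for s in rng.choice(sizes_avail, size=k, p=probs)]
        total = sum(sizes)
        i = 0
        while total < n:  # round-robin additions
            sizes[i % k] += 1
            total += 1
            i += 1
        while total > n:  # trim largest families first, floor at 1
            j = int(np.argmax(sizes))
            if sizes[j] == 1:
                raise ValueError("cannot satisfy n_families with the given size distribution")
            sizes[j] -= 1
            total -= 1

    fam = np.empty(n, dtype=object)
    order = rng.permutation(n)
    start = 0
    for f, s in enumerate(sizes):
        fam[order[start : start + s]] = f"fam{f:05d}"
        start += s
    out = cohort.copy()
    out["family_id"] = fam
    return out


def simulate_cohort(config: SimConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Full generator: panel + phenotypes + AOSW + families (no MMD/PGS yet)."""
    panel = simulate_panel(config)
    cohort = simulate_phenotypes(panel, config)
    cohort = simulate_aosw(cohort, config)
    cohort = assign_families(cohort, config)
    return panel, cohort


def resample_ancestry_effects(
    causal: pd.DataFrame,
    rg: float,
    config: SimConfig,
    *,
    index: int = 0,
) -> pd.DataFrame:
    """Causal effects for a second ancestry with genetic correlation ``rg``.

    New raw effects are ``rg * b + sqrt(1 - rg^2) * e`` with ``e`` standard
    normal, emulating imperfect cross-ancestry transferability; allele
    frequencies of the target ancestry should additionally be re-drawn when
    simulating its panel.
    """
    if not (-1.0 <= rg <= 1.0):
        raise ValueError("rg must be in [-1, 1]")
    rng = child_rng(config.seed, "ancestry", index)
    b = causal["raw_effect"].to_numpy(float)
    e = rng.standard_normal(len(b))
    return pd.DataFrame(
        {"variant_id": causal["variant_id"].to_numpy(), "raw_effect": rg * b + np.sqrt(1 - rg**2) * e}
    )
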