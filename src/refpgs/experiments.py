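"""Reusable study-scale experiments on synthetic cohorts.

These drive the package's headline property checks: the anti-leakage
behavior of the LOCO scheme, mediation recovery in the PGS -> refractive
error -> MMD chain, and end-to-end PGS accuracy against the clumping
baseline and the Daetwyler-style expectation.  They are used by both the
test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import gwasassoc, ldshrink, locoinfer, metacombine, mmdassoc, pgseval, synthdata
from .config import ShrinkGrid, SimConfig

__all__ = [
    "loco_leakage_replicate",
    "mediation_replicate",
    "recovery_replicate",
]


def loco_leakage_replicate(
    seed: int,
    n_gwas: int = 4000,
    n_train: int = 2000,
    m: int = 4400,
    h2: float = 0.3,
) -> dict:
    """One replicate of the LOCO anti-leakage experiment.

    Three AOSW-inferred GWAS pipelines share the same data:

    * ``loco`` — the 22-fold scheme: chromosome k's statistics come from
      the model whose PGS omitted chromosome k;
    * ``bench`` — a fully held-out benchmark: the inference model uses a
      full-genome PGS computed from an independently re-drawn (phantom)
      genotype matrix of the GWAS sample, so the phenotype is uncorrelated
      with the tested genotypes by construction;
    * ``nonloco`` — the deliberate control: the full-genome PGS scored on
      the GWAS sample's own genotypes leaks every chromosome into the
      phenotype.

    Returns the mean association chi-square of each pipeline.
    """
    base = SimConfig(
        n_samples=n_train, n_snps=m, h2=h2, p_causal=0.05, ld_rho=0.5,
        pc_mode="zero", n_pcs=0, seed=seed * 4,
    )
    maf = np.random.default_rng(seed).uniform(base.maf_low, base.maf_high, m)
    panel_a = synthdata.simulate_panel(base, maf=maf)
    cohort_a = synthdata.simulate_phenotypes(panel_a, base)
    causal = cohort_a.attrs["causal"]

    cfg_b = base.replace(seed=seed * 4 + 1)
    panel_b = synthdata.simulate_panel(cfg_b, maf=maf)
    cohort_b = synthdata.simulate_aosw(
        synthdata.simulate_phenotypes(panel_b, cfg_b, causal=causal), cfg_b
    )
    cfg_c = base.replace(n_samples=n_gwas, seed=seed * 4 + 2)
    panel_c = synthdata.simulate_panel(cfg_c, maf=maf)
    cohort_c = synthdata.simulate_aosw(
        synthdata.simulate_phenotypes(panel_c, cfg_c, causal=causal), cfg_c
    )
    # phantom genotypes: same distribution, independent of panel_c
    panel_ph = synthdata.simulate_panel(cfg_c.replace(seed=seed * 4 + 3), maf=maf)

    ss_a = gwasassoc.run_gwas(panel_a, cohort_a["avSER"].to_numpy(), None)
    w_full = locoinfer.build_loco_weights(ss_a, excluded=None, h2=h2)

    def mean_chi2(ss: pd.DataFrame) -> float:
        z = ss["beta"].to_numpy() / ss["standard_error"].to_numpy()
        return float(np.mean(z**2))

    out = {}
    z_b_full = pgseval.standardize(ldshrink.score_samples(panel_b, w_full))
    model_full = locoinfer.AoswModel().fit(cohort_b, z_b_full)
    z_phantom = pgseval.standardize(ldshrink.score_samples(panel_ph, w_full))
    out["bench"] = mean_chi2(
        gwasassoc.run_gwas(panel_c, model_full.predict(cohort_c, z_phantom), None)
    )
    z_own = pgseval.standardize(ldshrink.score_samples(panel_c, w_full))
    out["nonloco"] = mean_chi2(
        gwasassoc.run_gwas(panel_c, model_full.predict(cohort_c, z_own), None)
    )

    vals = []
    for k in range(1, base.n_chromosomes + 1):
        wk = locoinfer.build_loco_weights(ss_a, excluded=k, h2=h2)
        zbk = pgseval.standardize(ldshrink.score_samples(panel_b, wk))
        model_k = locoinfer.AoswModel().fit(cohort_b, zbk)
        zck = pgseval.standardize(ldshrink.score_samples(panel_c, wk))
        yk = model_k.predict(cohort_c, zck)
        sub = panel_c.subset_variants(panel_c.chromosome_mask(k))
        ssk = gwasassoc.run_gwas(sub, yk, None)
        vals.append((ssk["beta"].to_numpy() / ssk["standard_error"].to_numpy()) ** 2)
    out["loco"] = float(np.mean(np.concatenate(vals)))
    return out


def mediation_replicate(
    seed: int,
    beta_direct: float = 0.0,
    n: int = 50000,
    m: int = 110,
) -> dict:
    """One replicate of the PGS -> SER -> severe-MMD mediation analysis.

    The cohort is generated at the population severe-MMD prevalence
    (~0.3%, OR 1.28 per diopter); the standardized myopia-oriented genetic
    value plays the PGS.  Returns the unadjusted and SER-adjusted nested
    logistic fits.
    """
    cfg = SimConfig(
        n_samples=n, n_snps=m, h2=0.3, p_causal=0.1, mmd_beta_direct=beta_direct, seed=seed
    )
    panel = synthdata.simulate_panel(cfg)
    cohort = synthdata.simulate_phenotypes(panel, cfg)
    pgs = pgseval.standardize(-cohort["true_genetic_value"].to_numpy())
    cohort = synthdata.simulate_mmd(cohort, pgs, cfg)
    worse = [
        mmdassoc.worse_eye(r, l) for r, l in zip(cohort["eyeR_grade"], cohort["eyeL_grade"])
    ]
    severe = np.array([mmdassoc.severe_indicator(g) for g in worse], dtype=int)
    covars = pd.DataFrame(
        {
            "age": cohort["Age"],
            "age2": cohort["Age"] ** 2,
            "sex": cohort["Sex"],
        }
    )
    avser = cohort["avSER"].to_numpy()
    return {
        "n_severe": int(severe.sum()),
        "unadjusted": mmdassoc.logistic_assoc(severe, pgs, avser, covars, include_ser=False),
        "adjusted": mmdassoc.logistic_assoc(severe, pgs, avser, covars, include_ser=True),
        "ser_only": mmdassoc.logistic_assoc(
            severe, np.zeros_like(pgs) + 1e-9 * pgs, avser, covars, include_ser=True
        ),
    }


def recovery_replicate(
    seed: int,
    n_train: int = 5000,
    n_tune: int = 1000,
    n_test: int = 1000,
    m: int = 5000,
    h2: float = 0.3,
    p_causal: float = 0.01,
    n_iter: int = 400,
    burn_in: int = 100,
) -> dict:
    """One replicate of the end-to-end PGS parameter-recovery experiment.

    GWAS on the training sample, grid shrinkage tuned on the tuning
    sample, incremental R^2 of the winner and of the tuned clumping +
    thresholding baseline in the test sample, plus the Daetwyler-style
    expectation h2 / (1 + m_eff / (n h2)) with m_eff the LD-block count.
    """
    base = SimConfig(
        n_samples=n_train, n_snps=m, h2=h2, p_causal=p_causal, ld_rho=0.5,
        pc_mode="zero", n_pcs=0, seed=seed * 3,
    )
    maf = np.random.default_rng(seed).uniform(base.maf_low, base.maf_high, m)
    panel_tr = synthdata.simulate_panel(base, maf=maf)
    cohort_tr = synthdata.simulate_phenotypes(panel_tr, base)
    causal = cohort_tr.attrs["causal"]
    cfg_tu = base.replace(n_samples=n_tune, seed=seed * 3 + 1)
    panel_tu = synthdata.simulate_panel(cfg_tu, maf=maf)
    cohort_tu = synthdata.simulate_phenotypes(panel_tu, cfg_tu, causal=causal)
    cfg_te = base.replace(n_samples=n_test, seed=seed * 3 + 2)
    panel_te = synthdata.simulate_panel(cfg_te, maf=maf)
    cohort_te = synthdata.simulate_phenotypes(panel_te, cfg_te, causal=causal)

    ss = gwasassoc.run_gwas(panel_tr, cohort_tr["avSER"].to_numpy(), None)
    ld = ldshrink.build_ld_blocks(panel_tu)
    grid = ShrinkGrid(n_iter=n_iter, burn_in=burn_in, seed=seed)
    candidates = ldshrink.gibbs_grid(ss, ld, grid)
    ct_candidates = [
        ldshrink.clump_threshold(ss, ld, r2_max=0.2, p_max=p)
        for p in grid.p_values
    ]
    ct_candidates = [c for c in ct_candidates if len(c)]
    pheno_tu = cohort_tu["avSER"].to_numpy()
    tuned, report = ldshrink.tune(candidates, panel_tu, pheno_tu, None)
    ct_best, _ = ldshrink.tune(ct_candidates, panel_tu, pheno_tu, None)

    pheno_te = cohort_te["avSER"].to_numpy()
    r2_tuned = ldshrink.incremental_adj_r2(
        pheno_te, ldshrink.score_samples(panel_te, tuned), None
    )
    r2_ct = ldshrink.incremental_adj_r2(
        pheno_te, ldshrink.score_samples(panel_te, ct_best), None
    )
    m_eff = len(ld.blocks)
    return {
        "r2_tuned": float(r2_tuned),
        "r2_clump_threshold": float(r2_ct),
        "daetwyler": ldshrink.daetwyler_r2(h2, m_eff, n_train),
        "tuned_cell": {k: tuned.attrs[k] for k in ("h2", "p", "sparse")},
        "grid_report": report,
    }


def mediation_summary(results: list[dict]) -> dict:
    """Aggregate mediation replicates into the headline counts and means."""
    un = [r["unadjusted"] for r in results]
    ad = [r["adjusted"] for r in results]
    return {
        "n_replicates": len(results),
        "unadjusted_or_mean": float(np.mean([r.or_pgs for r in un])),
        "unadjusted_significant": int(
            sum(1 for r in un if r.or_pgs > 1 and r.p_pgs < 0.05)
        ),
        "adjusted_or_mean": float(np.mean([r.or_pgs for r in ad])),
        "adjusted_ci_contains_1": int(
            sum(1 for r in ad if r.or_pgs_ci[0] <= 1.0 <= r.or_pgs_ci[1])
        ),
        "or_per_diopter_mean": float(np.mean([r.or_ser for r in ad])),
    }
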