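# refpgs

A tested, synthetic-data implementation of the full derivation-and-evaluation
pipeline behind a modern polygenic score (PGS) for refractive error, including
the downstream test of whether such a score predicts myopic macular
degeneration (MMD) beyond refraction itself.

## The problem

Spherical equivalent refractive error (avSER, in diopters; negative = myopia)
is highly polygenic. A PGS — a weighted sum of allele dosages,
`PGS_i = sum_j w_j x_ij` — can flag children at risk of high myopia
(avSER <= -5 D or <= -6 D) long before refraction develops. Deriving a
competitive PGS involves a chain of statistical machinery whose real inputs
(biobank genotypes, consortium summary statistics, graded fundus images) are
access-controlled. This package implements that chain end to end and makes it
testable by generating synthetic cohorts with the statistical structure the
analysis assumes. It is aimed at statistical geneticists who want a runnable,
verifiable reference for each stage:

* **Phenotype amplification via age of onset of spectacle wear (AOSW).**
  Refraction is measured in a minority of a biobank, but AOSW is self-reported
  by most. A regression
  `avSER ~ poly(AOSW,10) + poly(Age,3) + Sex + poly(EduYears,2) + EduYears*AOSW + PGS_loco + PGS_loco*poly(AOSW,2)`
  infers refraction for the larger sample. Because a PGS appears among the
  predictors, a **leave-one-chromosome-out (LOCO)** scheme is used: 22 models
  are fit, each with a PGS omitting one autosome, and the genome-wide
  association study (GWAS) statistics for chromosome k are taken from the
  model whose PGS omitted chromosome k — so no chromosome helps infer the
  phenotype it is tested against.
* **Multi-trait meta-analysis.** Per-cohort GWAS summary statistics are
  combined by the moment-based multi-trait estimator (MTAG-style): a
  generalized-least-squares combination using the genetic covariance Omega and
  the sampling covariance Sigma = diag(se^2), with a two-stage **union
  assembly** for variants missing from the smaller cohorts.
* **LD-aware shrinkage.** Marginal effects are shrunk by a point-normal
  ("spike and slab") Gibbs sampler run per linkage-disequilibrium block
  (LDpred2-grid style) over a grid of heritability h2 in {0.1..0.4}, causal
  fraction p in {1e-5..1} and sparsity {on, off}; the winning cell is chosen
  on a held-out tuning sample by incremental R^2. A clumping + thresholding
  baseline is included.
* **Evaluation.** Per-ancestry standardization, incremental adjusted R^2 and
  AUROC with 2000-replicate bootstrap CIs, tail odds ratios, decile absolute
  risk, refraction-trajectory bands.
* **MMD mediation test.** Per-eye META-PM grades are collapsed worse-eye to a
  severe indicator (C3/C4 vs C0/C2); a family-aware five-tranche cross-fitted
  PGS (nobody scored by a model trained on them or their relatives) enters
  nested logistic models — with and without avSER, standard and Firth
  bias-reduced — to ask whether the PGS carries MMD risk beyond refraction.

## Worked example

```python
import numpy as np
from refpgs.config import SimConfig, ShrinkGrid
from refpgs import synthdata, gwasassoc, ldshrink, pgseval

cfg = SimConfig(n_samples=4000, n_snps=1100, h2=0.3, p_causal=0.05, seed=7)
panel = synthdata.simulate_panel(cfg)
cohort = synthdata.simulate_phenotypes(panel, cfg)

train, test = np.arange(3000), np.arange(3000, 4000)
ss = gwasassoc.run_gwas(panel.subset_samples(train),
                        cohort["avSER"].to_numpy()[train], None)

ld = ldshrink.build_ld_blocks(panel.subset_samples(test))
grid = ShrinkGrid(n_iter=300, burn_in=60, seed=7)
candidates = ldshrink.gibbs_grid(ss, ld, grid)
best, report = ldshrink.tune(candidates, panel.subset_samples(test),
                             cohort["avSER"].to_numpy()[test], None)
print("winning grid cell:", {k: best.attrs[k] for k in ("h2", "p", "sparse")})

z = pgseval.standardize(ldshrink.score_samples(panel.subset_samples(test), best))
inc = pgseval.incremental_r2(cohort["avSER"].to_numpy()[test], z, None,
                             n_boot=500, seed=7)
print(f"incremental R^2 = {inc.value:.3f} (95% CI {inc.ci_low:.3f}-{inc.ci_high:.3f})")

hm6 = pgseval.classify(cohort["avSER"].to_numpy()[test])["HM6"].to_numpy()
auc = pgseval.auroc(hm6, -z, n_boot=500, seed=7)
print(f"AUROC for high myopia (HM6) = {auc.value:.3f} "
      f"(95% CI {auc.ci_low:.3f}-{auc.ci_high:.3f}), {hm6.sum()} cases")
```

prints

```
winning grid cell: {'h2': 0.1, 'p': 0.1, 'sparse': True}
incremental R^2 = 0.284 (95% CI 0.241-0.332)
AUROC for high myopia (HM6) = 0.856 (95% CI 0.769-0.930), 16 cases
```

The tuning step picked a sparse point-normal cell; the resulting score
explains 28% of the variance in avSER in the held-out sample (at this desk
scale the 55 causal variants are well covered by n=3000 training samples, so
accuracy sits above the ~20% seen with a million real SNPs) and ranks
high-myopia cases at AUROC 0.86. The `-z` flips the score so that higher
values mean greater myopia risk.

The full experiment — LOCO AOSW-inferred GWAS, four-cohort meta-analysis with
union assembly, grid shrinkage, cross-ancestry evaluation and the MMD
mediation test — is one call (or `refpgs run --seed 1 --out out/`):

```python
from refpgs.pipeline import PipelineConfig, run_pipeline
bundle = run_pipeline(PipelineConfig(seed=1), outdir="out")
```

Every stage is also exposed as a `refpgs` subcommand (`simulate`, `gwas`,
`loco-infer`, `meta`, `shrink`, `score`, `tune`, `evaluate`, `mmd-test`,
`run`) over the VCF / TSV / PGS-scoring-file formats in `refpgs.io`.

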