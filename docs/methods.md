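# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort generator

The generator (`refpgs.synthdata`) produces the statistical structure every
downstream stage assumes, not a forgery of real human genetic data.

**Genotypes.** Each variant gets a minor-allele frequency drawn uniformly on
[`maf_low`, `maf_high`] (default 0.05–0.5). Two haplotypes per sample come
from a Gaussian copula: within a block of `ld_block_size` SNPs (default 10),
latent normals follow an AR(1) correlation `ld_rho` (default 0.5); an allele
indicator is 1 where the latent value falls below the MAF quantile. Marginally
every variant is Binomial(2, maf) — Hardy–Weinberg holds by construction —
and adjacent dosages correlate at the copula-induced value, which is
attenuated relative to `ld_rho` (the test suite checks it against a direct
Monte-Carlo oracle). Blocks never span chromosome boundaries, and with the
default 22 autosomes variants are spread as evenly as possible.

**Trait.** `p_causal * n_snps` variants (default 1%) receive i.i.d. normal
raw effects. The centered genetic score is rescaled so its variance is
exactly `h2 * ser_sd^2`; covariate terms (age, sex, education years, with
deliberately small defaults) and Gaussian noise fill the remainder, so the
trait has mean `ser_mean = -0.28` D and SD `ser_sd = 2.72` D — the adult
European cohort moments the analysis targets. `h2` defaults to 0.3, the
middle of the heritability grid and consistent with a SNP-heritability of
refraction in the 0.3–0.45 range. The realized genetic component is kept in
the cohort table (`true_genetic_value`) for testing only.

**AOSW observation process.** The source analyses infer refraction *from*
AOSW but never state how AOSW arises; the generator therefore adopts the
simplest model with the right direction: expected onset age
`onset_intercept + onset_slope * avSER` (defaults 17 y and 1.5 y/D, so a
-6 D myope seeks spectacles around age 8) plus Gaussian noise (SD 3 y),
clamped to [5, Age]. Participants whose modeled onset exceeds their age, or
whose avSER is above `never_wearer_threshold` (default 0 D), are flagged
never-wearers with missing AOSW, and the inference-model fit excludes them
(a numeric AOSW is required). These choices are stand-ins, not claims about
any real questionnaire.

**MMD.** Each eye is independently severe with
`logit(p) = mmd_intercept + mmd_beta_ser * (-avSER) + mmd_beta_direct * pgs`.
`mmd_beta_ser` defaults to log(1.28) — the published odds ratio per diopter
more negative refraction — and `mmd_intercept = -6.8` was set analytically
(log-normal moment formula under the default avSER distribution) so the
worse-eye severe prevalence is ~0.3%, matching the published META-PM C3+C4
counts (169 + 49 in 75,869). Severe eyes split C3:C4 at the published
169:49; non-severe eyes are C2 with probability 0.02 (C2 is folded into
"normal" downstream because its grading is unreliable). `mmd_beta_direct`
(default 0) plants a direct genetic path for mediation experiments.

**Families and ancestries.** Family sizes are drawn from a configurable
distribution (default 60/30/10% of sizes 1/2/3); relatedness beyond the label
is not modeled. A second ancestry is emulated by re-drawing allele
frequencies and perturbing causal effects to a target genetic correlation
`rg` (`resample_ancestry_effects`); PC-threshold ancestry definitions on real
ethnicity fields are out of scope.

**Seeds.** One master seed; per-stage child generators derive from
`SeedSequence(seed, spawn_key=(stage_id, index))` with a fixed stage table,
so every generator is a pure function of (config, seed).

What passing tests on these data do **not** show: robustness to realistic
human LD (long-range, variable block sizes), MAF-dependent architectures,
imputation error, cryptic relatedness, or ascertainment — none of which the
generator emulates.

## GWAS stage

A linear-regression GWAS stands in for the mixed-model software used on the
real data: phenotype and dosages are residualized once on the covariates
(age, age², sex, array, 10 PCs by default) — algebraically equivalent to
per-SNP joint fits by Frisch–Waugh–Lovell — with the degrees-of-freedom
correction applied and p-values from the normal approximation (consistent
with the meta-analysis stage; at the simulated n the difference from the t
distribution is negligible). Family confounding is handled by design in the
simulator rather than by a random effect. Missing dosages are mean-imputed
per variant; a constant dosage reports beta=0, se=inf, p=1. PCs are computed
from the column-standardized dosage matrix and rescaled to unit variance.

## LOCO inference of refraction from AOSW

The inference design has 20 columns beyond the intercept: orthogonal
polynomials of AOSW (order 10), Age (3) and EduYears (2), Sex, a raw
EduYears×AOSW product (the rendering is ambiguous between raw and polynomial
AOSW in the product; raw is implemented and fixed), the LOCO PGS, and
PGS×poly(AOSW, 2). Orthogonal bases are built by QR on the Vandermonde matrix
of the standardized training column and frozen; any orthonormal basis
spanning the same monomial space gives identical fitted values, which is the
tested contract. Education years are set to 21 for degree holders in the
generator, mirroring the published coding rule.

The LOCO weight builder substitutes a documented shrinkage for the original
mixed-model predictive betas, which play the same role (a genome-minus-one-
chromosome predictor): `marginal-scaled` multiplies GWAS betas by the
infinitesimal factor `(h2/m) / (h2/m + 1/n)`; `ridge` solves
`(R + m/(n h2) I)^-1 beta` per LD block on the standardized scale. The two
coincide exactly when every block is the identity. Assembly of the final
AOSW-inferred GWAS is a pure row selection — chromosome-k rows from the run
whose PGS excluded chromosome k — with betas and SEs untouched.

The anti-leakage benchmark used in the acceptance experiment deserves a
note: a "fully held-out" pipeline is constructed by scoring the full-genome
PGS on an independently re-drawn (phantom) genotype matrix of the GWAS
sample, so the inferred phenotype has the same distribution but is
uncorrelated with every tested genotype by construction. LOCO is compared to
this benchmark; the deliberate non-LOCO control scores the full-genome PGS on
the sample's own genotypes.

## Meta-analysis

The multi-trait estimator at variant j for target trait t is

    beta_j = a' M_j^{-1} betahat_j / (a' M_j^{-1} a),
    M_j = Omega - w_t w_t'/w_tt + Sigma_j,   a = w_t / w_tt,
    se_j = (a' M_j^{-1} a)^{-1/2},

with Omega the trait-by-trait genetic covariance and Sigma_j = diag(se²)
(the cohorts are non-overlapping, so no overlap correction is implemented —
a documented limitation). Omega, when not supplied, is moment-estimated on
the effect-size scale: mean beta cross-products, minus the mean squared SE on
the diagonal, projected to the nearest PSD matrix by clipping negative
eigenvalues. A single input passes through unchanged; a singular M_j falls
back to inverse-variance weighting with a logged warning. With rg = 1 and a
homogeneous architecture the estimator reduces to fixed-effect IVW (tested to
1e-8). Allele alignment takes the first cohort as reference, flips signs on
swapped alleles, drops incompatible pairs with a count, and is an involution.
Variants absent from the smaller cohorts are rescued by a second meta-analysis
of the largest cohort pair and a union assembly whose row count is exactly
|full| + |subset-only|.

## Shrinkage

The point-normal Gibbs sampler works per LD block on the standardized scale
`betatilde = z / sqrt(n)`. Cell (h2, p) uses slab variance `h2/(m p)`; each
sweep updates SNPs in genome order (fixed, for reproducibility): residual
`bhat_j = betatilde_j - (R b)_j + b_j`, posterior slab `N(mu_j, v_j)` with
`v_j = (n_j + 1/sigma2)^{-1}` and `mu_j = n_j bhat_j v_j`, and inclusion
probability alpha_j from the marginal likelihood ratio of slab vs spike. Defaults are 500
iterations with 100 burn-in, the source method's order of magnitude, exposed
in `ShrinkGrid`.

Two deliberate numerical choices:

* **Rao–Blackwellised posterior means.** The reported weight is the average
  of the analytic conditional mean `alpha_j * mu_j` over kept sweeps, not of
  the sampled values — the same estimand with far less Monte Carlo noise
  (and exactly the closed form when LD is the identity and p = 1).
* **Sparse rule.** The sparse variant of a cell sets a weight exactly to
  zero where the average posterior inclusion probability is below 0.5. The
  source method's exact zeroing rule is unpublished detail; this rule
  reproduces its observable behavior (near-total sparsity under a null with
  small p; identical non-zero support recovery under signal).

PSD repair of empirical block correlations floors eigenvalues at 1e-8 and
rescales back to a correlation matrix. Weights are converted back to allele
units through `se * sqrt(n)`. The grid defaults to the published 4×6×2 cells
(the published "P-value threshold" axis is the causal-fraction parameter p,
per the grid convention of the source method). Tuning maximizes incremental
adjusted R² on a held-out sample and reports the full grid. The clumping +
thresholding baseline selects index SNPs by ascending p (ties to genome
order) within blocks at an r² ceiling, then applies the p threshold to raw
betas. `daetwyler_r2(h2, m_eff, n) = h2/(1 + m_eff/(n h2))` is the classical
accuracy expectation; the acceptance experiment uses the LD-block count as
m_eff (the effective number of independent markers in a block-diagonal
panel), a loose yardstick by design.

## Evaluation

Category thresholds are inclusive: myopia <= -0.50 D, moderate myopia
<= -3.00 D, moderate hyperopia >= +3.00 D, HM5 <= -5.00 D, HM6 <= -6.00 D.
Scores are standardized within each ancestry group. Incremental R² is the
difference of *adjusted* R² between the covariate+score and covariate-only
models (the difference of adjusted values can sit slightly below the raw
difference); the point estimate is the bootstrap median and the CI the
2.5th/97.5th percentiles of 2000 participant resamples by default. AUROC is
the midrank Mann–Whitney statistic (ties get half credit), with a stratified
bootstrap (cases and controls resampled separately, avoiding degenerate
replicates) and a paired bootstrap z-test for comparing two scores by default
(`D = (AUC1-AUC2)/sd(bootstrap differences)`). AUROC is computed score-only;
a covariate-adjusted variant sits behind a flag. Tail odds ratios use the
2×2 table with Wald CIs on the log scale and the Haldane–Anscombe 0.5
correction on zero cells (the exact CI method of the original figures is
unstated). Deciles are assigned by stable rank with ties to the lower decile
(documented because heavily tied synthetic scores otherwise make decile
sizes ambiguous), with Wilson binomial CIs. Trajectory bands are simple
percentile-neighborhood means over participants with >= 3 measurement ages;
the autoregressive mixed trajectory model is out of scope.

## MMD analysis

Worse-eye coding takes the maximum grade under C0 < C2 < C3 < C4 (single-eye
participants use the available eye); severe = C3/C4. Tranche partitioning
shuffles families (seeded) and assigns each greedily to the smallest tranche,
keeping relatives together; cross-fitting derives each tranche's weights from
the other tranches only — the GWAS, the meta-analysis with fixed external
summary statistics, and the shrinkage with tuning parameters frozen from the
main analysis (re-tuning per fold would be valid but slower; the frozen
choice is documented). The nested logistic models use the design
[intercept, PGS, (-avSER), covariates]: the sign convention makes "per
diopter more negative" read as OR > 1 for myopia. Standard fits are plain
Newton maximum likelihood; Firth fits apply the Jeffreys-prior score
modification `U*(b) = X'(y - p + h(1/2 - p))` with hat-matrix leverages h,
which yields finite estimates under separation. CIs are Wald on the log-odds
scale (the original CI method is unnamed); profile-likelihood CIs are not
implemented. The cross-fit PGS is standardized within the analysis sample.

## Pipeline defaults and problem sizes

The end-to-end demonstration (`PipelineConfig`) runs at desk scale as its
own design choice: a 1,100-variant universe over 22 chromosomes, disjoint
samples of 4,000 (avSER GWAS / MMD), 3,000 (AOSW GWAS), 2×2,000 (inference
and LOCO-weight training), 2×1,500 (external cohort stand-ins), 1,000
(tuning) and 1,500 + 1,000 (European and non-European test groups,
cross-ancestry rg = 0.7), with 7% of the universe withheld from the external
cohorts to exercise the union. The MMD stage of the demo raises the severe
prevalence (intercept -5.5, ~1%) for stable case counts at n = 4,000; the
dedicated mediation experiments use the faithful ~0.3% prevalence at
n = 50,000. The acceptance experiments use n = 4,000 / m = 4,400 for the
LOCO property and n = 5,000/1,000/1,000 with m = 5,000 for end-to-end
recovery, ten seeded replicates each.

## Known limitations

* Linear-regression GWAS (no mixed model), diagonal Sigma (no sample
  overlap), and no LD-score-intercept diagnostics.
* Block-diagonal LD with AR(1) structure only; no realistic LD maps, no X
  chromosome, no imputation.
* The sparse-rule detail and the AOSW observation model are the package's
  own documented choices where the source analyses are silent.
* Never-wearers are excluded from inference-model fitting by default; an
  alternative censor-at-age policy is not implemented.
* Firth CIs are Wald, not profile likelihood.
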