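"""End-to-end experiment orchestration on synthetic cohorts.

Mirrors the full derivation-and-evaluation design: disjoint samples drawn
on one variant universe (an avSER GWAS sample that doubles as the MMD
sample, an AOSW sample, an inference-model training sample, a LOCO-PGS
training sample, two external cohort stand-ins, tuning and test samples),
the LOCO AOSW-inferred GWAS, a four-cohort meta-analysis with the
two-stage union, grid shrinkage with tuning-sample selection, evaluation
in European and non-European test groups, and the cross-fitted PGS ->
severe-MMD mediation test.

The report bundle is a pure function of (config, seed); stages communicate
only via the returned objects and files written under ``outdir``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwasassoc, io, ldshrink, locoinfer, metacombine, mmdassoc, pgseval, synthdata
from .config import ShrinkGrid, SimConfig

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Desk-scale configuration of the full experiment."""

    # variant universe
    n_snps: int = 1100
    n_chromosomes: int = 22
    ld_block_size: int = 10
    ld_rho: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    # trait architecture
    h2: float = 0.3
    p_causal: float = 0.05
    # sample sizes (disjoint samples on the shared universe)
    n_gwas_avser: int = 4000   # avSER GWAS; also the MMD analysis sample
    n_gwas_aosw: int = 3000    # AOSW-inferred GWAS
    n_eq1_train: int = 2000    # inference-model training
    n_pgs_train: int = 2000    # LOCO weight training
    n_cream: int = 1500        # external cohort stand-in
    n_gera: int = 1500         # external cohort stand-in
    n_tuning: int = 1000
    n_test: int = 1500
    n_test_other: int = 1000   # non-European-analog test group
    ancestry_rg: float = 0.7   # cross-ancestry genetic correlation
    other_ancestry_label: str = "SAS"
    union_missing_frac: float = 0.07  # universe fraction absent from the externals
    # shrinkage
    grid: ShrinkGrid = field(default_factory=ShrinkGrid)
    ct_r2_max: float = 0.2
    loco_h2: float = 0.3
    loco_enabled: bool = True
    # evaluation
    n_boot: int = 500
    # MMD stage (prevalence raised above the population value for stable
    # case counts at desk scale; the faithful rate is used by the dedicated
    # mediation analyses)
    mmd_intercept: float = -5.5
    mmd_beta_direct: float = 0.0
    k_tranches: int = 5
    n_pcs: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = ShrinkGrid(**d["grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sim_config(cfg: PipelineConfig, n: int, seed: int, **kw) -> SimConfig:
    return SimConfig(
        n_samples=n,
        n_snps=cfg.n_snps,
        n_chromosomes=cfg.n_chromosomes,
        ld_block_size=cfg.ld_block_size,
        ld_rho=cfg.ld_rho,
        maf_low=cfg.maf_low,
        maf_high=cfg.maf_high,
        h2=cfg.h2,
        p_causal=cfg.p_causal,
        n_pcs=cfg.n_pcs,
        seed=seed,
        **kw,
    )


def _make_sample(cfg, n, seed, maf, causal, *, aosw=False, families=False, ancestry="EUR", **kw):
    sc = _sim_config(cfg, n, seed, **kw)
    panel = synthdata.simulate_panel(sc, maf=maf)
    cohort = synthdata.simulate_phenotypes(panel, sc, causal=causal)
    cohort["ancestry"] = ancestry
    if aosw:
        cohort = synthdata.simulate_aosw(cohort, sc)
    if families:
        cohort = synthdata.assign_families(cohort, sc)
    return sc, panel, cohort


def _gwas(panel, cohort, pheno_col="avSER", n_pcs=4):
    covars = gwasassoc.build_covariates(cohort, n_pcs=n_pcs)
    return gwasassoc.run_gwas(panel, cohort[pheno_col].to_numpy(float), covars)


def _loco_stage(cfg, samples) -> pd.DataFrame:
    """LOCO AOSW-inferred GWAS: 22 model fits, 22 GWAS runs, one assembly."""
    _, panel_pt, cohort_pt = samples["pgs_train"]
    _, panel_eq1, cohort_eq1 = samples["eq1_train"]
    _, panel_aosw, cohort_aosw = samples["aosw"]
    ss_pgs = _gwas(panel_pt, cohort_pt, n_pcs=cfg.n_pcs)
    chroms = range(1, cfg.n_chromosomes + 1)
    loco = locoinfer.LocoWeightSet.from_sumstats(ss_pgs, chromosomes=chroms, h2=cfg.loco_h2)
    runs = {}
    covars = gwasassoc.build_covariates(cohort_aosw, n_pcs=cfg.n_pcs)
    for k in chroms:
        w = loco.for_chromosome(k)
        pgs_eq1 = pgseval.standardize(ldshrink.score_samples(panel_eq1, w))
        model = locoinfer.AoswModel().fit(cohort_eq1, pgs_eq1)
        pgs_aosw = pgseval.standardize(ldshrink.score_samples(panel_aosw, w))
        inferred = locoinfer.infer_phenotype(model, cohort_aosw, pgs_aosw)
        runs[k] = gwasassoc.run_gwas(panel_aosw, inferred, covars)
    return locoinfer.assemble_loco_gwas(runs)


def _meta_stage(cfg, ss_avser, ss_aosw, ss_cream, ss_gera, missing_ids):
    """Two-stage meta: all cohorts on the common set, the UKB-analog pair on
    the rest, then the union assembly."""
    inputs_full = [
        ss[~ss["variant_id"].isin(missing_ids)].reset_index(drop=True)
        for ss in (ss_avser, ss_aosw, ss_cream, ss_gera)
    ]
    meta_full = metacombine.mtag_meta(
        metacombine.align_alleles(inputs_full, ["avser", "aosw", "cream", "gera"])
    )
    pair = metacombine.align_alleles([ss_avser, ss_aosw], ["avser", "aosw"])
    meta_pair = metacombine.mtag_meta(pair)
    meta_subset = meta_pair[meta_pair["variant_id"].isin(missing_ids)].reset_index(drop=True)
    union = metacombine.assemble_union(meta_full, meta_subset, list(meta_subset["variant_id"]))
    return union, meta_full, meta_subset


def _evaluate_group(cfg, panel, cohort, weights, seed) -> dict:
    score = ldshrink.score_samples(panel, weights)
    z = pgseval.standardize(score)
    covars = gwasassoc.build_covariates(cohort, n_pcs=cfg.n_pcs)
    inc = pgseval.incremental_r2(
        cohort["avSER"].to_numpy(float), z, covars, n_boot=cfg.n_boot, seed=seed
    )
    cats = pgseval.classify(cohort["avSER"].to_numpy(float))
    out = {
        "n": len(cohort),
        "incremental_r2": dataclasses.asdict(inc),
        "auroc": {},
        "tail_or_hm6": None,
    }
    for cat in cats.columns:
        y = cats[cat].to_numpy()
        if y.sum() >= 10 and (~y).sum() >= 10:
            direction = 1.0 if cat == "moderate_hyperopia" else -1.0
            est = pgseval.auroc(y, direction * z, n_boot=cfg.n_boot, seed=seed + 1)
            out["auroc"][cat] = dataclasses.asdict(est)
    y6 = cats["HM6"].to_numpy()
    if y6.sum() >= 5:
        out["tail_or_hm6"] = {
            k: v for k, v in pgseval.tail_or(z, y6, tail=0.10, side="low").items() if k != "table"
        }
        out["decile_hm6"] = pgseval.decile_risk(z, y6).to_dict(orient="list")
    return out


def _mmd_stage(cfg, samples, externals, tuned_attrs):
    """Cross-fitted PGS on the avSER-GWAS sample, then nested severe-MMD models."""
    sc, panel, cohort = samples["avser"]
    mmd_cfg = sc.replace(
        mmd_intercept=cfg.mmd_intercept, mmd_beta_direct=cfg.mmd_beta_direct
    )
    pgs_true = pgseval.standardize(-cohort["true_genetic_value"].to_numpy(float))
    cohort = synthdata.simulate_mmd(cohort, pgs_true, mmd_cfg)
    partition = mmdassoc.partition_tranches(cohort, k=cfg.k_tranches, seed=cfg.seed + 17)
    ld = ldshrink.build_ld_blocks(panel)
    grid1 = ShrinkGrid(
        h2_values=(tuned_attrs["h2"],),
        p_values=(tuned_attrs["p"],),
        sparse_values=(tuned_attrs["sparse"],),
        n_iter=cfg.grid.n_iter,
        burn_in=cfg.grid.burn_in,
        seed=cfg.grid.seed,
    )
    ss_cream, ss_gera = externals

    def derive(train_mask):
        sub_panel = panel.subset_samples(np.where(train_mask)[0])
        sub_cohort = cohort.loc[train_mask].reset_index(drop=True)
        ss = _gwas(sub_panel, sub_cohort, n_pcs=cfg.n_pcs)
        meta = metacombine.mtag_meta(
            metacombine.align_alleles([ss, ss_cream, ss_gera], ["train", "cream", "gera"])
        )
        return ldshrink.gibbs_grid(meta, ld, grid1)[0]

    score = mmdassoc.crossfit_pgs(panel, cohort, partition, derive)
    # myopia-risk orientation: more myopic genetic value -> higher score
    z = pgseval.standardize(-score)
    worse = [
        mmdassoc.worse_eye(r, l) for r, l in zip(cohort["eyeR_grade"], cohort["eyeL_grade"])
    ]
    severe = np.array([mmdassoc.severe_indicator(g) for g in worse], dtype=int)
    covars = gwasassoc.build_covariates(cohort, n_pcs=cfg.n_pcs)
    avser = cohort["avSER"].to_numpy(float)
    results = {}
    if severe.sum() >= 2:
        for firth in (False, True):
            for include_ser in (False, True):
                key = f"{'firth' if firth else 'ml'}_{'with' if include_ser else 'without'}_ser"
                try:
                    res = mmdassoc.logistic_assoc(
                        severe, z, avser, covars, include_ser=include_ser, firth=firth
                    )
                    results[key] = dataclasses.asdict(res)
                except RuntimeError as exc:
                    results[key] = {"error": str(exc)}
    results["n_severe"] = int(severe.sum())
    results["prevalence_severe_pct"] = mmdassoc.prevalence(int(severe.sum()), len(severe), 2)
    return results


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Execute simulate -> gwas -> loco -> meta -> shrink -> tune -> evaluate
    -> crossfit+mmd; returns (and optionally writes) the report bundle."""
    t0 = time.time()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(99,)))
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)

    # shared causal architecture on the universe
    template = _sim_config(cfg, 2, cfg.seed)
    tpl_panel = synthdata.simulate_panel(template, maf=maf)
    n_causal = max(1, int(round(cfg.p_causal * cfg.n_snps)))
    causal_idx = np.sort(rng.choice(cfg.n_snps, n_causal, replace=False))
    causal = pd.DataFrame(
        {
            "variant_id": tpl_panel.variants["variant_id"].to_numpy()[causal_idx],
            "raw_effect": rng.standard_normal(n_causal),
        }
    )

    names_sizes = {
        "avser": (cfg.n_gwas_avser, {"families": True}),
        "aosw": (cfg.n_gwas_aosw, {"aosw": True}),
        "eq1_train": (cfg.n_eq1_train, {"aosw": True}),
        "pgs_train": (cfg.n_pgs_train, {}),
        "cream": (cfg.n_cream, {}),
        "gera": (cfg.n_gera, {}),
        "tuning": (cfg.n_tuning, {}),
        "test": (cfg.n_test, {}),
    }
    samples = {}
    for i, (name, (n, kw)) in enumerate(names_sizes.items()):
        samples[name] = _make_sample(cfg, n, cfg.seed * 1009 + i, maf, causal, **kw)
    # non-European-analog test group: re-drawn frequencies, rg-correlated effects
    maf_other = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    causal_other = synthdata.resample_ancestry_effects(causal, cfg.ancestry_rg, template)
    samples["test_other"] = _make_sample(
        cfg,
        cfg.n_test_other,
        cfg.seed * 1009 + 50,
        maf_other,
        causal_other,
        ancestry=cfg.other_ancestry_label,
    )

    log.info("pipeline: samples simulated (%.1fs)", time.time() - t0)
    ss_avser = _gwas(*samples["avser"][1:], n_pcs=cfg.n_pcs)
    ss_cream = _gwas(*samples["cream"][1:], n_pcs=cfg.n_pcs)
    ss_gera = _gwas(*samples["gera"][1:], n_pcs=cfg.n_pcs)
    meta_inputs = [ss_avser]
    if cfg.loco_enabled:
        ss_aosw = _loco_stage(cfg, samples)
        meta_inputs.append(ss_aosw)
    log.info("pipeline: GWAS + LOCO done (%.1fs)", time.time() - t0)

    universe = tpl_panel.variants["variant_id"].to_numpy()
    n_missing = int(round(cfg.union_missing_frac * cfg.n_snps))
    missing_ids = set(rng.choice(universe, n_missing, replace=False))
    if cfg.loco_enabled:
        union, meta_full, meta_subset = _meta_stage(
            cfg, ss_avser, ss_aosw, ss_cream, ss_gera, missing_ids
        )
    else:
        inputs = [
            ss[~ss["variant_id"].isin(missing_ids)].reset_index(drop=True)
            for ss in (ss_avser, ss_cream, ss_gera)
        ]
        union = metacombine.mtag_meta(
            metacombine.align_alleles(inputs, ["avser", "cream", "gera"])
        )
        meta_full, meta_subset = union, union.iloc[:0]
    log.info("pipeline: meta-analysis done (%.1fs)", time.time() - t0)

    _, panel_tune, cohort_tune = samples["tuning"]
    ld = ldshrink.build_ld_blocks(panel_tune).restrict(union["variant_id"])
    aligned = union[union["variant_id"].isin(ld.variant_ids)].reset_index(drop=True)
    candidates = ldshrink.gibbs_grid(aligned, ld, cfg.grid)
    ct_candidates = []
    for p_max in cfg.grid.p_values:
        ct = ldshrink.clump_threshold(aligned, ld, r2_max=cfg.ct_r2_max, p_max=p_max)
        if len(ct):
            ct_candidates.append(ct)
    covars_tune = gwasassoc.build_covariates(cohort_tune, n_pcs=cfg.n_pcs)
    pheno_tune = cohort_tune["avSER"].to_numpy(float)
    tuned, grid_report = ldshrink.tune(candidates, panel_tune, pheno_tune, covars_tune)
    ct_best, ct_report = ldshrink.tune(ct_candidates, panel_tune, pheno_tune, covars_tune)
    log.info("pipeline: shrinkage + tuning done (%.1fs)", time.time() - t0)

    evaluation = {
        "EUR": _evaluate_group(cfg, *samples["test"][1:], tuned, cfg.seed + 101),
        cfg.other_ancestry_label: _evaluate_group(
            cfg, *samples["test_other"][1:], tuned, cfg.seed + 102
        ),
        "EUR_clump_threshold": _evaluate_group(cfg, *samples["test"][1:], ct_best, cfg.seed + 103),
    }
    mmd = _mmd_stage(cfg, samples, (ss_cream, ss_gera), tuned.attrs)
    log.info("pipeline: evaluation + MMD done (%.1fs)", time.time() - t0)

    bundle = {
        "config": cfg.to_dict(),
        "n_variants_union": int(len(union)),
        "n_variants_meta_full": int(len(meta_full)),
        "n_variants_subset_only": int(len(meta_subset)),
        "tuned_cell": {k: tuned.attrs[k] for k in ("h2", "p", "sparse")},
        "grid_report": grid_report.to_dict(orient="list"),
        "ct_report": ct_report.to_dict(orient="list"),
        "evaluation": evaluation,
        "mmd": mmd,
        "wall_time_s": round(time.time() - t0, 2),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_sumstats(union, outdir / "meta_union.tsv")
        io.write_weights(tuned, outdir / "pgs_weights.txt")
        grid_report.to_csv(outdir / "grid_report.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=_json_default)
    return bundle


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
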