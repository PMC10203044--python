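"""Shrinkage tests: LD block construction, the point-normal Gibbs sampler
against closed-form and quadrature oracles, clumping, scoring, tuning."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from refpgs.config import ShrinkGrid
from refpgs import ldshrink, synthdata
from refpgs.config import SimConfig
from tests.conftest import make_sumstats


def identity_ld(variant_ids):
    return ldshrink.LDBlockSet([(np.asarray(variant_ids), np.eye(len(variant_ids)))])


class TestLdBlocks:
    def test_unit_diagonal(self, small_panel):
        ld = ldshrink.build_ld_blocks(small_panel)
        for _, R in ld.blocks:
            assert np.allclose(np.diag(R), 1.0)
        ld.validate()

    def test_independent_variants_small_offdiag(self):
        cfg = SimConfig(n_samples=5000, n_snps=220, ld_rho=0.0, seed=31)
        panel = synthdata.simulate_panel(cfg)
        ld = ldshrink.build_ld_blocks(panel)
        offs = [R[~np.eye(len(R), dtype=bool)] for _, R in ld.blocks if len(R) > 1]
        assert np.abs(np.concatenate(offs)).max() < 0.08
        assert np.abs(np.concatenate(offs)).mean() < 0.02

    def test_three_variant_block_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        X[:, 2] = 0.7 * X[:, 0] + 0.3 * rng.normal(size=200)
        X = np.clip(X - X.min() + 0, 0, 2)  # keep in dosage range
        from refpgs.panel import GenotypePanel

        variants = pd.DataFrame(
            {
                "variant_id": ["a", "b", "c"],
                "chromosome": 1,
                "position": [1, 2, 3],
                "effect_allele": "A",
                "other_allele": "G",
                "allele_frequency": X.mean(axis=0) / 2,
            }
        )
        panel = GenotypePanel(np.array(["s%d" % i for i in range(200)]), variants,
                              X.astype(np.float32), blocks=[np.arange(3)])
        ld = ldshrink.build_ld_blocks(panel)
        hand = np.corrcoef(X, rowvar=False)
        assert np.allclose(ld.blocks[0][1], hand, atol=1e-6)


class TestGibbs:
    def test_infinitesimal_closed_form(self):
        """LD = identity, p = 1: posterior means equal the per-SNP
        closed form beta * (h2/m) / (h2/m + 1/n)."""
        rng = np.random.default_rng(1)
        m, n, h2 = 200, 50000, 0.4
        beta = rng.normal(0, np.sqrt(h2 / m), m) + rng.normal(0, 1 / np.sqrt(n), m)
        ss = make_sumstats(beta, ses=np.full(m, 1 / np.sqrt(n)), n=n)
        grid = ShrinkGrid(h2_values=(h2,), p_values=(1.0,), sparse_values=(False,),
                          n_iter=300, burn_in=50, seed=2)
        wv = ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid, n_gwas=n)[0]
        c = (h2 / m) / (h2 / m + 1 / n)
        rel = np.abs(wv["effect_weight"].to_numpy() - c * beta) / np.abs(c * beta)
        assert rel.max() < 1e-3

    def test_single_snp_matches_spike_slab_quadrature(self):
        """One SNP: the Gibbs posterior mean equals 1-D quadrature over the
        two-component (spike at 0, normal slab) posterior."""
        n, h2, p = 10000.0, 0.2, 0.3
        m = 1
        sigma2 = h2 / (m * p)
        betahat = 0.012

        def posterior_mean():
            sd_lik = np.sqrt(1 / n)
            lo, hi = betahat - 10 * sd_lik, betahat + 10 * sd_lik  # likelihood support
            lik = lambda b: stats.norm.pdf(betahat, loc=b, scale=sd_lik)
            slab = lambda b: stats.norm.pdf(b, scale=np.sqrt(sigma2))
            num = integrate.quad(lambda b: b * lik(b) * slab(b), lo, hi, epsabs=1e-16)[0] * p
            den = (
                integrate.quad(lambda b: lik(b) * slab(b), lo, hi, epsabs=1e-16)[0] * p
                + (1 - p) * lik(0.0)
            )
            return num / den

        ss = make_sumstats([betahat], ses=[1 / np.sqrt(n)], n=int(n))
        grid = ShrinkGrid(h2_values=(h2,), p_values=(p,), sparse_values=(False,),
                          n_iter=400, burn_in=100, seed=3)
        wv = ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid, n_gwas=n)[0]
        expect = posterior_mean()
        assert wv["effect_weight"].iloc[0] == pytest.approx(expect, rel=1e-3)

    def test_sparse_null_mostly_zero(self):
        rng = np.random.default_rng(4)
        m, n = 500, 5000
        beta = rng.normal(0, 1 / np.sqrt(n), m)  # pure noise
        ss = make_sumstats(beta, ses=np.full(m, 1 / np.sqrt(n)), n=n)
        grid = ShrinkGrid(h2_values=(0.3,), p_values=(1e-5,), sparse_values=(True,),
                          n_iter=200, burn_in=50, seed=5)
        wv = ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid, n_gwas=n)[0]
        assert (wv["effect_weight"] == 0).mean() >= 0.99

    def test_contraction_at_identity_ld(self):
        rng = np.random.default_rng(6)
        m, n = 100, 2000
        beta = rng.normal(0, 0.05, m)
        ss = make_sumstats(beta, ses=np.full(m, 1 / np.sqrt(n)), n=n)
        grid = ShrinkGrid(n_iter=150, burn_in=30, seed=7)
        for wv in ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid, n_gwas=n):
            assert (np.abs(wv["effect_weight"]) <= np.abs(beta) + 1e-12).all()

    def test_grid_determinism_and_size(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(0, 0.05, 30)
        ss = make_sumstats(beta, ses=np.full(30, 0.01), n=10000)
        grid = ShrinkGrid(n_iter=120, burn_in=20, seed=9)
        a = ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid)
        b = ldshrink.gibbs_grid(ss, identity_ld(ss["variant_id"]), grid)
        assert len(a) == 48
        for wa, wb in zip(a, b):
            assert np.array_equal(wa["effect_weight"].to_numpy(), wb["effect_weight"].to_numpy())


class TestClumpThreshold:
    def _toy(self, seed=0, m=20, rho=0.9):
        rng = np.random.default_rng(seed)
        blocks = []
        ids = np.array([f"v{i}" for i in range(m)])
        R_half = np.full((5, 5), rho)
        np.fill_diagonal(R_half, 1.0)
        for b in range(m // 5):
            blocks.append((ids[b * 5 : (b + 1) * 5], R_half.copy()))
        ss = make_sumstats(rng.normal(0, 0.05, m), ses=np.full(m, 0.01))
        return ss, ldshrink.LDBlockSet(blocks)

    def test_permissive_thresholds_keep_everything(self):
        ss, ld = self._toy()
        wv = ldshrink.clump_threshold(ss, ld, r2_max=1.0, p_max=1.0)
        assert len(wv) == len(ss)
        merged = wv.merge(ss, on="variant_id")
        assert np.allclose(merged["effect_weight"], merged["beta"])

    def test_perfectly_correlated_pair_keeps_one(self):
        ss = make_sumstats([0.05, 0.03])
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = ldshrink.LDBlockSet([(np.array(["v0", "v1"]), R)])
        wv = ldshrink.clump_threshold(ss, ld, r2_max=0.5, p_max=1.0)
        assert list(wv["variant_id"]) == ["v0"]  # smaller p wins

    def test_tie_breaks_to_genome_order(self):
        ss = make_sumstats([0.05, 0.05])
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = ldshrink.LDBlockSet([(np.array(["v0", "v1"]), R)])
        wv = ldshrink.clump_threshold(ss, ld, r2_max=0.5, p_max=1.0)
        assert list(wv["variant_id"]) == ["v0"]

    def test_matches_brute_force_greedy(self):
        ss, ld = self._toy(seed=3)
        wv = ldshrink.clump_threshold(ss, ld, r2_max=0.5, p_max=0.8)
        # brute-force replay of the greedy rule
        sub = ss.set_index("variant_id")
        order = ss.sort_values(["p_value", "position"], kind="stable")["variant_id"].tolist()
        kept: list[str] = []
        r2 = {}
        for ids, R in ld.blocks:
            for i, vi in enumerate(ids):
                for j, vj in enumerate(ids):
                    r2[(vi, vj)] = R[i, j] ** 2
        for v in order:
            if all(r2.get((v, k), 0.0) <= 0.5 for k in kept):
                kept.append(v)
        expect = [v for v in kept if sub.loc[v, "p_value"] <= 0.8]
        assert sorted(wv["variant_id"]) == sorted(expect)


class TestScore:
    def _panel(self):
        from refpgs.panel import GenotypePanel

        dos = np.array([[0, 1, 2], [2, 0, 1], [1, 1, 0], [0, 2, 2]], dtype=np.float32)
        variants = pd.DataFrame(
            {
                "variant_id": ["a", "b", "c"],
                "chromosome": 1,
                "position": [1, 2, 3],
                "effect_allele": ["A", "C", "A"],
                "other_allele": ["G", "T", "G"],
                "allele_frequency": dos.mean(axis=0) / 2,
            }
        )
        return GenotypePanel(np.array(["s1", "s2", "s3", "s4"]), variants, dos)

    def _weights(self, w, flip_c=False):
        return pd.DataFrame(
            {
                "variant_id": ["a", "b", "c"],
                "chromosome": 1,
                "effect_allele": ["A", "C", "G" if flip_c else "A"],
                "other_allele": ["G", "T", "A" if flip_c else "G"],
                "effect_weight": w,
            }
        )

    def test_hand_computed_dot_products(self):
        panel = self._panel()
        s = ldshrink.score_samples(panel, self._weights([0.5, -1.0, 2.0]))
        expect = panel.dosages @ np.array([0.5, -1.0, 2.0])
        assert np.allclose(s, expect)

    def test_zero_weights_zero_scores(self):
        assert np.allclose(ldshrink.score_samples(self._panel(), self._weights([0, 0, 0])), 0)

    def test_linearity(self):
        s1 = ldshrink.score_samples(self._panel(), self._weights([0.5, -1.0, 2.0]))
        s2 = ldshrink.score_samples(self._panel(), self._weights([1.0, -2.0, 4.0]))
        assert np.allclose(s2, 2 * s1)

    def test_allele_flip_uses_complement_dose(self):
        panel = self._panel()
        s_flip = ldshrink.score_samples(panel, self._weights([0.0, 0.0, 1.0], flip_c=True))
        assert np.allclose(s_flip, 2.0 - panel.dosages[:, 2])

    def test_zero_overlap_rejected(self):
        w = self._weights([1.0, 1.0, 1.0])
        w["variant_id"] = ["x", "y", "z"]
        with pytest.raises(ValueError, match="overlap"):
            ldshrink.score_samples(self._panel(), w)


class TestTune:
    def test_true_genetic_value_wins(self, small_panel, small_cohort):
        truth = small_cohort["true_genetic_value"].to_numpy()
        # candidate 0: weights recovering the causal architecture; candidate 1: noise
        causal = small_cohort.attrs["causal"]
        var = small_panel.variants
        w_true = var[["variant_id", "chromosome", "effect_allele", "other_allele"]].copy()
        w_true["effect_weight"] = 0.0
        pos = w_true.set_index("variant_id").index.get_indexer(causal["variant_id"])
        w_true.loc[w_true.index[pos], "effect_weight"] = causal["raw_effect"].to_numpy()
        rng = np.random.default_rng(10)
        w_noise = w_true.copy()
        w_noise["effect_weight"] = rng.normal(0, 0.01, len(w_noise))
        best, report = ldshrink.tune(
            [w_true, w_noise], small_panel, small_cohort["avSER"].to_numpy(), None
        )
        assert report["incremental_r2"].idxmax() == 0
        assert best is not w_noise

    def test_report_one_row_per_candidate_and_argmax(self, small_panel, small_cohort):
        rng = np.random.default_rng(11)
        var = small_panel.variants
        cands = []
        for i in range(4):
            w = var[["variant_id", "chromosome", "effect_allele", "other_allele"]].copy()
            w["effect_weight"] = rng.normal(0, 0.01, len(w))
            cands.append(w)
        pheno = small_cohort["avSER"].to_numpy()
        best, report = ldshrink.tune(cands, small_panel, pheno, None)
        assert len(report) == 4
        recomputed = [
            ldshrink.incremental_adj_r2(pheno, ldshrink.score_samples(small_panel, w), None)
            for w in cands
        ]
        assert report["incremental_r2"].idxmax() == int(np.argmax(recomputed))

    def test_empty_candidates_rejected(self, small_panel, small_cohort):
        with pytest.raises(ValueError):
            ldshrink.tune([], small_panel, small_cohort["avSER"].to_numpy(), None)
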