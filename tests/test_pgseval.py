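"""Evaluation-metric tests against independent oracles: exhaustive pair
counting for AUROC, the direct 2x2 formula for tail ORs, hand arithmetic
for standardization and relative changes, liability simulation for deciles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refpgs import pgseval


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-6.00, {"HM6", "HM5", "moderate_myopia", "myopia"}),
            (-5.00, {"HM5", "moderate_myopia", "myopia"}),
            (-3.00, {"moderate_myopia", "myopia"}),
            (-0.50, {"myopia"}),
            (-0.49, set()),
            (3.00, {"moderate_hyperopia"}),
            (0.0, set()),
        ],
    )
    def test_boundaries_inclusive(self, value, expected):
        flags = pgseval.classify([value]).iloc[0]
        assert {k for k, v in flags.items() if v} == expected

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-15, 15, allow_nan=False))
    def test_category_nesting(self, x):
        f = pgseval.classify([x]).iloc[0]
        assert (not f["HM6"]) or f["HM5"]
        assert (not f["HM5"]) or f["moderate_myopia"]
        assert (not f["moderate_myopia"]) or f["myopia"]
        assert not (f["moderate_hyperopia"] and f["myopia"])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pgseval.classify([np.nan])


class TestStandardize:
    def test_group_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, 100)
        g = np.repeat(["a", "b"], 50)
        z = pgseval.standardize(x, g)
        for lab in ("a", "b"):
            assert abs(z[g == lab].mean()) < 1e-12
            assert z[g == lab].std() == pytest.approx(1.0)

    def test_single_group_equals_global_zscore(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        assert np.allclose(pgseval.standardize(x), (x - x.mean()) / x.std())

    def test_two_group_toy_hand_standardized(self):
        x = np.array([1.0, 3.0, 10.0, 14.0])
        g = np.array([0, 0, 1, 1])
        z = pgseval.standardize(x, g)
        assert np.allclose(z, [-1, 1, -1, 1])

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            pgseval.standardize([1.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])


class TestIncrementalR2:
    def test_perfect_predictor_explains_everything(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 2, 300)
        est = pgseval.incremental_r2(y, y, None, n_boot=200, seed=0)
        assert est.value == pytest.approx(1.0, abs=1e-10)

    def test_noise_score_ci_covers_zero(self):
        """An uninformative score yields a CI containing zero in nearly all
        replicates (coverage tally oracle)."""
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(20):
            y = rng.normal(0, 1, 2000)
            s = rng.normal(0, 1, 2000)
            est = pgseval.incremental_r2(y, s, None, n_boot=300, seed=rep)
            hits += est.contains(0.0)
        assert hits >= 18

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 500)
        s = 0.5 * y + rng.normal(0, 1, 500)
        a = pgseval.incremental_r2(y, s, None, n_boot=200, seed=4)
        b = pgseval.incremental_r2(y, 3.0 * s - 7.0, None, n_boot=200, seed=4)
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y, s = rng.normal(size=300), rng.normal(size=300)
        a = pgseval.incremental_r2(y, s, None, n_boot=100, seed=9)
        b = pgseval.incremental_r2(y, s, None, n_boot=100, seed=9)
        assert (a.value, a.ci_low, a.ci_high) == (b.value, b.ci_low, b.ci_high)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (500, 5000):
            y = rng.normal(0, 1, n)
            s = 0.4 * y + rng.normal(0, 1, n)
            est = pgseval.incremental_r2(y, s, None, n_boot=300, seed=1)
            widths.append(est.ci_high - est.ci_low)
        assert widths[1] < widths[0]


def auroc_pair_count(labels, scores):
    """Exhaustive concordant-pair oracle with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        est = pgseval.auroc(y, np.array([0.1, 0.2, 0.8, 0.9]), n_boot=50, seed=0)
        assert est.value == 1.0

    def test_chance_level(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 5000)
        est = pgseval.auroc(y, rng.normal(size=5000), n_boot=100, seed=1)
        assert est.value == pytest.approx(0.5, abs=0.02)

    def test_six_observation_toy_with_ties(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([3.0, 2.0, 1.0, 2.0, 1.0, 0.0])
        est = pgseval.auroc(y, s, n_boot=50, seed=2)
        assert est.value == pytest.approx(auroc_pair_count(y, s))

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = rng.integers(4, 31)
            y = np.zeros(n, int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.0, 0.5, 1.0, 2.0, 3.0], n)  # heavy ties
            est = pgseval.auroc(y, s, n_boot=10, seed=3)
            assert est.value == pytest.approx(auroc_pair_count(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pgseval.auroc(np.ones(5), np.arange(5), n_boot=10)

    def test_compare_identical_scores_nonsignificant(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500)
        res = pgseval.compare_auroc(y, s, s.copy(), n_boot=100, seed=4)
        assert res["diff"] == 0.0
        assert res["p"] == 1.0

    def test_compare_detects_better_score(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 2000)
        good = y + rng.normal(0, 0.5, 2000)
        bad = rng.normal(size=2000)
        res = pgseval.compare_auroc(y, good, bad, n_boot=200, seed=5)
        assert res["p"] < 0.01 and res["diff"] > 0


class TestTailOr:
    def test_direct_2x2_formula(self):
        # a=10 tail cases, b=90 non-tail cases, c=10 tail controls, d=890
        z = np.concatenate([np.full(20, -3.0), np.zeros(980)])
        y = np.concatenate([np.ones(10), np.zeros(10), np.ones(90), np.zeros(890)])
        res = pgseval.tail_or(z, y, tail=0.02, side="low")
        assert res["or"] == pytest.approx((10 * 890) / (90 * 10), rel=1e-12)

    def test_side_symmetry(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=2000)
        y = (z + rng.normal(0, 1, 2000) < -1.5).astype(int)
        low = pgseval.tail_or(z, y, tail=0.1, side="low")
        high = pgseval.tail_or(-z, y, tail=0.1, side="high")
        assert low["or"] == pytest.approx(high["or"])

    def test_null_ci_contains_one(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            z = rng.normal(size=2000)
            y = rng.integers(0, 2, 2000)
            res = pgseval.tail_or(z, y, tail=0.25)
            hits += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert hits >= 18

    def test_zero_cell_haldane_correction(self):
        z = np.concatenate([np.full(10, -3.0), np.zeros(90)])
        y = np.concatenate([np.zeros(10), np.ones(10), np.zeros(80)])
        res = pgseval.tail_or(z, y, tail=0.1, side="low")
        assert np.isfinite(res["or"]) and res["or"] > 0


class TestDecileRisk:
    def test_uniform_risk_flat_deciles(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=20000)
        y = rng.random(20000) < 0.10
        out = pgseval.decile_risk(z, y)
        assert np.allclose(out["prevalence"], 0.10, atol=0.03)

    def test_counts_conserved(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=1000)
        y = rng.integers(0, 2, 1000)
        out = pgseval.decile_risk(z, y)
        assert out["cases"].sum() == y.sum()
        assert out["n"].sum() == 1000

    def test_monotone_liability_gives_decreasing_risk(self):
        """Liability-model oracle: case status from low liability, score
        positively correlated with liability -> prevalence falls with decile."""
        from scipy import stats as sps

        rng = np.random.default_rng(15)
        n = 10000
        liab = rng.normal(size=n)
        z = 0.7 * liab + np.sqrt(1 - 0.49) * rng.normal(size=n)
        y = liab < np.quantile(liab, 0.05)
        out = pgseval.decile_risk(z, y)
        rho, p = sps.spearmanr(out["decile"], out["prevalence"])
        assert rho < 0 and p < 0.01


class TestRelativeChange:
    def test_published_improvement_arithmetic(self):
        assert round(pgseval.relative_improvement(0.190, 0.112)) == 70

    def test_published_decrease_arithmetic(self):
        assert round(pgseval.relative_decrease(0.020, 0.190)) == 89

    def test_no_change(self):
        assert pgseval.relative_improvement(0.1, 0.1) == 0.0
        assert pgseval.relative_decrease(0.1, 0.1) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pgseval.relative_improvement(0.1, 0.0)


class TestTrajectories:
    def _long(self, slopes, ages=(7, 10, 11, 12, 15)):
        rows = []
        for i, b in enumerate(slopes):
            for a in ages:
                rows.append({"sample_id": f"s{i}", "age": a, "avSER": -b * (a - 7)})
        return pd.DataFrame(rows)

    def test_identical_scores_identical_bands(self):
        long = self._long(np.full(200, 0.1))
        z = pd.Series(np.linspace(-2, 2, 200), index=[f"s{i}" for i in range(200)])
        out = pgseval.trajectory_bands(long, z)
        piv = out.pivot(index="age", columns="percentile", values="mean_avSER")
        assert np.allclose(piv.to_numpy(), piv.to_numpy()[:, [0]] * np.ones((1, 5)))

    def test_score_dependent_slopes_order_bands(self):
        rng = np.random.default_rng(16)
        n = 500
        z_vals = rng.normal(size=n)
        slopes = 0.2 - 0.05 * z_vals  # low PGS -> steeper myopic progression
        long = self._long(slopes)
        z = pd.Series(z_vals, index=[f"s{i}" for i in range(n)])
        out = pgseval.trajectory_bands(long, z)
        final = out[out["age"] == 15].sort_values("percentile")["mean_avSER"].to_numpy()
        assert (np.diff(final) > 0).all()

    def test_short_series_excluded(self):
        long = self._long(np.full(30, 0.1))
        short = pd.DataFrame(
            {"sample_id": "few", "age": [7, 10], "avSER": [0.0, -0.1]}
        )
        z = pd.Series(
            np.linspace(-1, 1, 31), index=[f"s{i}" for i in range(30)] + ["few"]
        )
        out = pgseval.trajectory_bands(pd.concat([long, short]), z)
        used = set(out["percentile"])
        # "few" cannot appear: bands built only over eligible participants
        long_all = pd.concat([long, short])
        counts = long_all.groupby("sample_id")["age"].nunique()
        assert counts.loc["few"] == 2
        assert used == {5, 25, 50, 75, 95}
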