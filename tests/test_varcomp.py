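import math

import numpy as np
import pandas as pd
import pytest

import maizedti as m

# ---------------------------------------------------------------------------
# Brute-force oracles: sums of squares straight from the textbook definition,
# accumulated with explicit loops over every observation.
# ---------------------------------------------------------------------------


def oneway_ss_bruteforce(y: np.ndarray) -> dict:
    g, r = y.shape
    grand = y.sum() / y.size
    ss_g = ss_e = ss_tot = 0.0
    for i in range(g):
        gi = y[i].sum() / r
        for k in range(r):
            ss_g += (gi - grand) ** 2
            ss_e += (y[i, k] - gi) ** 2
            ss_tot += (y[i, k] - grand) ** 2
    return {"genotype": ss_g, "error": ss_e, "total": ss_tot}


def twoway_ss_bruteforce(y: np.ndarray) -> dict:
    g, t, r = y.shape
    grand = y.sum() / y.size
    mg = y.mean(axis=(1, 2))
    mt = y.mean(axis=(0, 2))
    mgt = y.mean(axis=2)
    ss = {"genotype": 0.0, "treatment": 0.0, "interaction": 0.0,
          "error": 0.0, "total": 0.0}
    for i in range(g):
        for j in range(t):
            for k in range(r):
                ss["genotype"] += (mg[i] - grand) ** 2
                ss["treatment"] += (mt[j] - grand) ** 2
                ss["interaction"] += (mgt[i, j] - mg[i] - mt[j] + grand) ** 2
                ss["error"] += (y[i, j, k] - mgt[i, j]) ** 2
                ss["total"] += (y[i, j, k] - grand) ** 2
    return ss


class TestAnovaOneway:
    def test_all_equal_degenerate(self):
        table = m.anova_oneway(np.full((3, 2), 5.0))
        assert table["genotype"]["ss"] == 0.0
        assert table["error"]["ss"] == 0.0
        assert math.isnan(table["genotype"]["f"])
        assert math.isnan(table["genotype"]["p"])

    def test_hand_computed_sums_of_squares(self):
        table = m.anova_oneway([[1.0, 1.0], [3.0, 3.0]])
        assert table["genotype"]["ss"] == pytest.approx(4.0)
        assert table["error"]["ss"] == pytest.approx(0.0, abs=1e-12)
        assert table["genotype"]["df"] == 1 and table["error"]["df"] == 2

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            g, r = rng.integers(2, 7), rng.integers(2, 5)
            y = rng.normal(10, 3, (g, r))
            table = m.anova_oneway(y)
            oracle = oneway_ss_bruteforce(y)
            for src in ("genotype", "error", "total"):
                assert table[src]["ss"] == pytest.approx(
                    oracle[src], rel=1e-10, abs=1e-10
                )

    def test_unbalanced_rejected(self):
        with pytest.raises(m.ValidationError):
            m.anova_oneway([[1.0, 2.0], [3.0]])

    def test_too_small_designs_rejected(self):
        with pytest.raises(m.ValidationError):
            m.anova_oneway([[1.0], [2.0]])


class TestAnovaTwoway:
    def test_additive_no_noise_data(self):
        g_eff = np.array([0.0, 2.0, 5.0])
        t_eff = np.array([0.0, -1.0])
        y = (10 + g_eff[:, None, None] + t_eff[None, :, None]) * np.ones((3, 2, 2))
        table = m.anova_twoway(y)
        assert table["interaction"]["ss"] == pytest.approx(0.0, abs=1e-10)
        assert table["error"]["ss"] == pytest.approx(0.0, abs=1e-10)
        assert table["genotype"]["ss"] > 0 and table["treatment"]["ss"] > 0

    def test_single_replicate_rejected(self):
        with pytest.raises(m.ValidationError, match="replicate"):
            m.anova_twoway(np.zeros((3, 2, 1)))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            g = rng.integers(2, 7)
            t = rng.integers(2, 5)
            r = rng.integers(2, 4)
            y = rng.normal(10, 3, (g, t, r))
            table = m.anova_twoway(y)
            oracle = twoway_ss_bruteforce(y)
            for src in oracle:
                assert table[src]["ss"] == pytest.approx(
                    oracle[src], rel=1e-10, abs=1e-10
                )

    def test_df_bookkeeping_and_ss_additivity(self):
        y = np.random.default_rng(2).normal(size=(5, 3, 3))
        table = m.anova_twoway(y)
        src = table.sources
        assert src.loc["total", "df"] == y.size - 1
        assert src.drop(index="total")["df"].sum() == src.loc["total", "df"]
        assert src.drop(index="total")["ss"].sum() == pytest.approx(
            src.loc["total", "ss"], rel=1e-12
        )

    def test_agrees_with_statsmodels(self):
        """Independent cross-check against an OLS two-factor ANOVA."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, (5, 3, 3))
        table = m.anova_twoway(y)
        g, t, r = y.shape
        df = pd.DataFrame(
            {
                "y": y.ravel(),
                "geno": np.repeat(np.arange(g), t * r).astype(str),
                "treat": np.tile(np.repeat(np.arange(t), r), g).astype(str),
            }
        )
        fit = smf.ols("y ~ C(geno) * C(treat)", data=df).fit()
        ref = anova_lm(fit, typ=1)
        assert table["genotype"]["ss"] == pytest.approx(
            ref.loc["C(geno)", "sum_sq"], rel=1e-8
        )
        assert table["treatment"]["ss"] == pytest.approx(
            ref.loc["C(treat)", "sum_sq"], rel=1e-8
        )
        assert table["interaction"]["ss"] == pytest.approx(
            ref.loc["C(geno):C(treat)", "sum_sq"], rel=1e-8
        )
        assert table["error"]["ss"] == pytest.approx(
            ref.loc["Residual", "sum_sq"], rel=1e-8
        )
        assert table["genotype"]["p"] == pytest.approx(
            ref.loc["C(geno)", "PR(>F)"], abs=1e-10
        )


class TestVarianceComponents:
    def test_no_genotype_signal(self):
        table = m.AnovaTable(
            pd.DataFrame(
                {"df": [4, 10], "ss": [4.0, 10.0], "ms": [1.0, 1.0],
                 "f": [1.0, np.nan], "p": [0.5, np.nan]},
                index=pd.Index(["genotype", "error"], name="source"),
            )
        )
        vc = m.variance_components(table, r=3)
        assert vc.sigma2_g == 0.0 and vc.sigma2_e == 1.0

    def test_oneway_ems_algebra(self):
        table = m.AnovaTable(
            pd.DataFrame(
                {"df": [4, 10], "ss": [28.0, 10.0], "ms": [7.0, 1.0],
                 "f": [7.0, np.nan], "p": [0.01, np.nan]},
                index=pd.Index(["genotype", "error"], name="source"),
            )
        )
        vc = m.variance_components(table, r=3)
        assert vc.sigma2_g == pytest.approx(2.0)
        assert vc.sigma2_e == pytest.approx(1.0)
        assert vc.truncated == ()

    def test_twoway_ems_algebra_and_truncation(self):
        table = m.AnovaTable(
            pd.DataFrame(
                {"df": [4, 2, 8, 30],
                 "ss": [0.0, 0.0, 0.0, 0.0],
                 "ms": [26.0, 5.0, 2.0, 4.0],
                 "f": [np.nan] * 4, "p": [np.nan] * 4},
                index=pd.Index(
                    ["genotype", "treatment", "interaction", "error"],
                    name="source"),
            )
        )
        vc = m.variance_components(table, r=2, t=4)
        # sigma2_gt = (2 - 4)/2 < 0 -> truncated; sigma2_g = (26 - 2)/8 = 3
        assert vc.sigma2_gt == 0.0
        assert "sigma2_gt" in vc.truncated
        assert vc.sigma2_g == pytest.approx(3.0)

    def test_parameter_recovery_simulation(self):
        """Mean EMS estimates over 500 small simulated grids recover the true
        components (4, 1, 1) within sampling error."""
        rng = np.random.default_rng(4)
        true = {"sigma2_g": 4.0, "sigma2_gt": 1.0, "sigma2_e": 1.0}
        g, t, r = 12, 4, 3
        est = {k: [] for k in true}
        for _ in range(500):
            ge = rng.normal(0, 2.0, g)
            gt_e = rng.normal(0, 1.0, (g, t))
            eps = rng.normal(0, 1.0, (g, t, r))
            y = ge[:, None, None] + gt_e[:, :, None] + eps
            vc = m.variance_components(m.anova_twoway(y), r=r, t=t)
            est["sigma2_g"].append(vc.sigma2_g)
            est["sigma2_gt"].append(vc.sigma2_gt)
            est["sigma2_e"].append(vc.sigma2_e)
        for k, v in true.items():
            assert np.mean(est[k]) == pytest.approx(v, rel=0.10)


class TestHeritability:
    def test_zero_genotype_variance(self):
        vc = m.VarianceComponents(0.0, 1.0, None, r=3, t=None)
        assert m.heritability(vc).h2 == 0.0

    def test_noiseless_limit(self):
        vc = m.VarianceComponents(2.0, 0.0, 0.0, r=3, t=4)
        assert m.heritability(vc, "within-treatment").h2 == 1.0
        assert m.heritability(vc, "across-treatments").h2 == 1.0

    def test_closed_form_within(self):
        vc = m.VarianceComponents(2.0, 1.0, None, r=3, t=None)
        assert m.heritability(vc).h2 == pytest.approx(2 / (2 + 1 / 3))

    def test_closed_form_across(self):
        vc = m.VarianceComponents(2.0, 1.0, 0.5, r=3, t=4)
        expected = 2.0 / (2.0 + 0.5 / 4 + 1.0 / 12)
        assert m.heritability(vc, "across-treatments").h2 == pytest.approx(expected)

    def test_undefined_marker_on_zero_denominator(self):
        vc = m.VarianceComponents(0.0, 0.0, None, r=3, t=None)
        assert math.isnan(m.heritability(vc).h2)

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_invariant_to_measurement_scale(self, scale):
        """Multiplying all observations by c scales every variance component
        by c^2 and leaves H2 unchanged."""
        y = np.random.default_rng(5).normal(10, 2, (8, 4))
        vc1 = m.variance_components(m.anova_oneway(y), r=4)
        vc2 = m.variance_components(m.anova_oneway(y * scale), r=4)
        assert m.heritability(vc2).h2 == pytest.approx(
            m.heritability(vc1).h2, rel=1e-9
        )


class TestFisherLsd:
    def test_zero_mse(self):
        assert m.fisher_lsd(0.0, 10, 5).lsd == 0.0

    def test_closed_form_with_t_quantile(self):
        res = m.fisher_lsd(2.0, 14, 8, alpha=0.05)
        assert res.lsd == pytest.approx(2.1448 * math.sqrt(0.5), abs=2e-4)
        assert res.lsd == pytest.approx(1.517, abs=1e-3)

    def test_sqrt2_scaling_in_mse(self):
        a = m.fisher_lsd(1.0, 20, 6).lsd
        b = m.fisher_lsd(2.0, 20, 6).lsd
        assert b == pytest.approx(a * math.sqrt(2), rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(m.ValidationError):
            m.fisher_lsd(1.0, 10, 5, alpha=alpha)
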