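import numpy as np
import pytest
from scipy import stats

from nitroroot import (
    AnalysisError,
    ConfigurationError,
    DesignError,
    adjust_bonferroni,
    anova_components,
    contrast_tests,
    estimate_global_variance,
    fit_gene_anova,
)
from nitroroot.anova import trimmed_mean_consistency_factor
from tests.conftest import make_matrix


def ss_by_projection(cells: np.ndarray) -> tuple[float, float, float, float]:
    """Independent oracle: sequential least-squares projections onto the
    effect-coded 2x2 design space give the same SS decomposition."""
    r = cells.shape[-1]
    y = cells.reshape(-1)  # order (g, n, rep)
    g = np.repeat([-1.0, 1.0], 2 * r)
    n = np.tile(np.repeat([-1.0, 1.0], r), 2)
    inter = g * n
    X_full = np.column_stack([np.ones_like(y), g, n, inter])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_mean = rss(X_full[:, :1])
    # columns are orthogonal in the balanced design, so each term's SS is the
    # RSS drop when its column is added
    ss_g = rss_mean - rss(X_full[:, :2])
    ss_n = rss(X_full[:, :2]) - rss(X_full[:, :3])
    ss_gxn = rss(X_full[:, :3]) - rss(X_full)
    ss_e = rss(X_full)
    return ss_g, ss_n, ss_gxn, ss_e


class TestFitGeneAnova:
    def test_worked_example(self, worked_example_matrix):
        (fit,) = fit_gene_anova(worked_example_matrix)
        assert fit.ss_g == pytest.approx(32.0)
        assert fit.ss_n == pytest.approx(2.0)
        assert fit.ss_gxn == pytest.approx(0.0, abs=1e-12)
        assert fit.ss_e == pytest.approx(8.0)
        assert fit.df_e == 4
        assert fit.residual_variance == pytest.approx(2.0)
        assert fit.grand_mean == pytest.approx(12.5)

    def test_constant_gene_has_zero_ss(self):
        fits = fit_gene_anova(make_matrix(np.full((1, 12), 7.0)))
        f = fits[0]
        assert f.ss_g == f.ss_n == f.ss_gxn == f.ss_e == 0.0

    @pytest.mark.parametrize("r", [2, 3, 4, 5])
    def test_matches_projection_oracle(self, r):
        rng = np.random.default_rng(100 + r)
        for _ in range(50):
            cells = rng.normal(5, 2, size=(1, 2, 2, r))
            comp = anova_components(cells)
            ss = ss_by_projection(cells[0])
            got = (comp["ss_g"][0], comp["ss_n"][0], comp["ss_gxn"][0], comp["ss_e"][0])
            for a, b in zip(got, ss):
                assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_ss_conservation(self):
        rng = np.random.default_rng(11)
        cells = rng.normal(8, 3, size=(300, 2, 2, 3))
        comp = anova_components(cells)
        total = ((cells - cells.mean(axis=(1, 2, 3), keepdims=True)) ** 2).sum(axis=(1, 2, 3))
        decomposed = comp["ss_g"] + comp["ss_n"] + comp["ss_gxn"] + comp["ss_e"]
        assert np.allclose(decomposed, total, rtol=1e-9)

    def test_single_replicate_rejected(self):
        with pytest.raises(DesignError):
            anova_components(np.zeros((1, 2, 2, 1)))

    def test_unbalanced_design_rejected(self):
        m = make_matrix(np.zeros((1, 12)))
        unbalanced = m.values.drop(columns=["MUT_LN_3"])
        from nitroroot import ExpressionMatrix

        with pytest.raises(DesignError):
            fit_gene_anova(ExpressionMatrix(values=unbalanced, design=m.design))


class TestGlobalVariance:
    def test_constant_s2_any_trim(self):
        gv = estimate_global_variance(
            np.array([1.0, 1.0, 1.0, 1.0]), df_per_gene=8, bias_correction=False
        )
        assert gv.sigma2 == pytest.approx(1.0)
        assert gv.n_retained == 4

    def test_hand_enumerated_trim(self):
        # quantile(0.8) of {1,2,3,4,100} under linear interpolation is 23.2,
        # so only 100 is strictly above it
        gv = estimate_global_variance(
            np.array([1.0, 2.0, 3.0, 4.0, 100.0]),
            trim_low_q=0.0,
            trim_high_q=0.8,
            df_per_gene=8,
            bias_correction=False,
        )
        assert gv.n_retained == 4
        assert gv.sigma2 == pytest.approx(2.5)

    def test_no_trim_is_plain_mean(self):
        s2 = np.array([0.5, 1.5, 4.0])
        gv = estimate_global_variance(
            s2, trim_low_q=0.0, trim_high_q=1.0, df_per_gene=8, bias_correction=False
        )
        assert gv.sigma2 == pytest.approx(s2.mean())

    def test_bias_correction_restores_expectation(self):
        # chi2(8)/8 draws: the corrected trimmed mean should recover 1
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(8, size=200_000) / 8
        gv = estimate_global_variance(s2, df_per_gene=8)
        raw = estimate_global_variance(s2, df_per_gene=8, bias_correction=False)
        assert raw.sigma2 < gv.sigma2  # the raw trimmed mean under-estimates
        assert gv.sigma2 == pytest.approx(1.0, rel=5e-3)
        factor = trimmed_mean_consistency_factor(8, 0.025, 0.975)
        assert 0.97 < factor < 0.99

    def test_invalid_quantiles_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_global_variance(np.ones(3), trim_low_q=0.9, trim_high_q=0.1, df_per_gene=8)


class TestContrastTests:
    def test_worked_statistic_and_chi2_p(self, worked_example_matrix):
        fits = fit_gene_anova(worked_example_matrix)
        gv = estimate_global_variance(
            np.array([2.0]), trim_low_q=0, trim_high_q=1, df_per_gene=4, bias_correction=False
        )
        table = contrast_tests(fits, gv)
        assert table.data["T_G"].iloc[0] == pytest.approx(16.0)
        # chi-square(1) survival at 16 via an independent numerical route:
        # P(Z^2 > t) = 2 * (1 - Phi(sqrt(t)))
        expected_p = 2 * stats.norm.sf(np.sqrt(16.0))
        assert expected_p == pytest.approx(6.33e-5, rel=1e-3)
        assert table.data["p_G"].iloc[0] == pytest.approx(expected_p, rel=1e-12)

    def test_zero_ss_gives_p_one(self):
        fits = fit_gene_anova(make_matrix(np.full((1, 12), 3.0)))
        gv = estimate_global_variance(
            np.array([1.0]), trim_low_q=0, trim_high_q=1, df_per_gene=8, bias_correction=False
        )
        table = contrast_tests(fits, gv)
        assert (table.data[["p_G", "p_N", "p_GxN"]].iloc[0] == 1.0).all()

    def test_doubling_sigma2_halves_t_and_raises_p(self, worked_example_matrix):
        fits = fit_gene_anova(worked_example_matrix)
        kw = dict(trim_low_q=0, trim_high_q=1, df_per_gene=4, bias_correction=False)
        t1 = contrast_tests(fits, estimate_global_variance(np.array([2.0]), **kw)).data
        t2 = contrast_tests(fits, estimate_global_variance(np.array([4.0]), **kw)).data
        for c in ("G", "N", "GxN"):
            assert t2[f"T_{c}"].iloc[0] == pytest.approx(t1[f"T_{c}"].iloc[0] / 2)
            assert t2[f"p_{c}"].iloc[0] >= t1[f"p_{c}"].iloc[0]

    def test_f_reference_close_to_chi2_at_large_df(self, worked_example_matrix):
        fits = fit_gene_anova(worked_example_matrix)
        from nitroroot import GlobalVariance

        gv = GlobalVariance(sigma2=2.0, n_retained=2000, trim_low_q=0, trim_high_q=1,
                            df_per_gene=8)
        p_chi2 = contrast_tests(fits, gv, reference="chi2").data["p_G"].iloc[0]
        p_f = contrast_tests(fits, gv, reference="f").data["p_G"].iloc[0]
        assert p_f == pytest.approx(p_chi2, rel=0.02)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p_raw,m,expected", [(0.001, 100, 0.1), (0.5, 3, 1.0), (0.2, 1, 0.2)]
    )
    def test_adjustment(self, p_raw, m, expected, worked_example_matrix):
        fits = fit_gene_anova(worked_example_matrix)
        gv = estimate_global_variance(
            np.array([2.0]), trim_low_q=0, trim_high_q=1, df_per_gene=4, bias_correction=False
        )
        table = contrast_tests(fits, gv)
        table.data.loc[:, ["p_G", "p_N", "p_GxN"]] = p_raw
        adjusted = adjust_bonferroni(table, m=m)
        assert adjusted.data["padj_G"].iloc[0] == pytest.approx(expected)
        assert adjusted.m == m

    def test_invalid_m_rejected(self, worked_example_matrix):
        fits = fit_gene_anova(worked_example_matrix)
        gv = estimate_global_variance(np.array([2.0]), df_per_gene=4, bias_correction=False)
        with pytest.raises(ConfigurationError):
            adjust_bonferroni(contrast_tests(fits, gv), m=0)


class TestNullCalibration:
    def test_null_p_values_uniform(self):
        """Raw p-values on a pure-noise run are approximately Uniform(0,1)."""
        from nitroroot import ExpressionSimConfig, simulate_expression

        matrix, _ = simulate_expression(
            ExpressionSimConfig(n_genes=2000, n_replicates=3, noise_sd=0.5, seed=0)
        )
        fits = fit_gene_anova(matrix)
        gv = estimate_global_variance(fits)
        table = contrast_tests(fits, gv)
        for c in ("G", "N", "GxN"):
            p = table.data[f"p_{c}"].to_numpy()
            assert abs(p.mean() - 0.5) < 0.02
        # the three contrast families are independent (orthogonal SS), so the
        # pooled sample estimates the same KS distance with less MC noise
        pooled = np.concatenate([table.data[f"p_{c}"] for c in ("G", "N", "GxN")])
        assert stats.kstest(pooled, "uniform").statistic < 0.03

    def test_power_monotone_in_effect_size(self):
        """Declared-positive rate grows with the planted genotype effect."""
        from nitroroot import ExpressionSimConfig, classify_de, simulate_expression

        rates = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            cfg = ExpressionSimConfig(
                n_genes=400, n_replicates=3, prop_G=1.0 if effect else 0.0,
                effect_size_G=effect or 1.0, noise_sd=0.5, seed=21,
            )
            matrix, _ = simulate_expression(cfg)
            fits = fit_gene_anova(matrix)
            gv = estimate_global_variance(fits)
            table = adjust_bonferroni(contrast_tests(fits, gv), m=2000)
            rates.append(classify_de(table).totals["G"] / 400)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.01 and rates[-1] > 0.9
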