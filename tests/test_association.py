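import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cocoex as cx


def normmat(values, **kw):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return cx.NormalizedMatrix([f"g{i}" for i in range(g)],
                               [f"s{j}" for j in range(n)], values, np.ones(n), **kw)


class TestFitGeneModels:
    def test_noise_free_exact_recovery(self):
        astro = np.array([0.0, 1.0, 2.0, 3.0, 0.5, 1.5])
        y = (2.0 * astro + 1.0)[None, :].repeat(3, axis=0)
        design = cx.make_design(pd.DataFrame({"AstroE": astro}))
        tab = cx.fit_gene_models(normmat(y), design, "AstroE")
        assert np.allclose(tab.frame["beta"], 2.0, atol=1e-12)
        assert np.allclose(tab.sigma2, 0.0, atol=1e-20)

    def test_matches_normal_equation_oracle(self, rng):
        """Coefficients and SEs equal a hand-rolled normal-equation solution."""
        y = rng.normal(size=(3, 4))
        x = np.column_stack([np.ones(4), rng.normal(size=4), rng.normal(size=4)])
        design = pd.DataFrame(x, columns=["Intercept", "a", "b"])
        tab = cx.fit_gene_models(normmat(y), design, "a")
        xtx_inv = np.linalg.inv(x.T @ x)
        for g in range(3):
            beta = xtx_inv @ x.T @ y[g]
            resid = y[g] - x @ beta
            s2 = resid @ resid / (4 - 3)
            se = np.sqrt(s2 * xtx_inv[1, 1])
            assert tab.frame["beta"].iloc[g] == pytest.approx(beta[1], abs=1e-10)
            assert tab.frame["se"].iloc[g] == pytest.approx(se, abs=1e-10)

    def test_weighted_fit_matches_statsmodels(self, rng):
        y = rng.normal(size=(4, 8))
        x = np.column_stack([np.ones(8), rng.normal(size=8)])
        w = rng.uniform(0.5, 2.0, size=(4, 8))
        design = pd.DataFrame(x, columns=["Intercept", "a"])
        wm = cx.WeightMatrix(weights=w)
        tab = cx.fit_gene_models(normmat(y), design, "a", wm)
        import statsmodels.api as sm
        for g in range(4):
            fit = sm.WLS(y[g], x, weights=w[g]).fit()
            assert tab.frame["beta"].iloc[g] == pytest.approx(fit.params[1], abs=1e-10)
            assert tab.frame["se"].iloc[g] == pytest.approx(fit.bse[1], abs=1e-10)
            assert tab.frame["p"].iloc[g] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_beta_recovery_from_simulation(self):
        """Estimated slopes on the true latent factor are unbiased at n=32."""
        cfg = cx.SimConfig(seed=21)
        human, _, table, truth = cx.simulate_coculture(cfg)
        hf, _ = cx.filter_low_expression(human)
        nm = cx.log_cpm(hf, cx.tmm_norm_factors(hf))
        design = cx.make_design(pd.DataFrame({
            "a": truth.factor_values.loc[nm.sample_ids],
            "ngn2": truth.ngn2_values.loc[nm.sample_ids]}))
        tab = cx.fit_gene_models(nm, design, "a")
        resp = [g for g in truth.responsive_gene_ids if g in set(nm.gene_ids)]
        bias = (tab.frame.loc[resp, "beta"] - truth.true_betas.loc[resp]).mean()
        assert abs(bias) <= 0.05

    def test_rank_deficiency_names_columns(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            cx.fit_gene_models(normmat(np.zeros((2, 4))), cx.make_design(x), "a")

    def test_rmse_decreases_with_sample_size(self):
        rmses = []
        for n in (16, 32, 64):
            cfg = cx.SimConfig(n_coculture=n, n_monoculture=0, n_human_genes=600,
                               n_mouse_genes=100, n_responsive_genes=60,
                               n_mouse_responsive_genes=0, seed=33)
            human, _, table, truth = cx.simulate_coculture(cfg)
            hf, _ = cx.filter_low_expression(human)
            nm = cx.log_cpm(hf, cx.tmm_norm_factors(hf))
            design = cx.make_design(pd.DataFrame(
                {"a": truth.factor_values.loc[nm.sample_ids],
                 "ngn2": truth.ngn2_values.loc[nm.sample_ids]}))
            tab = cx.fit_gene_models(nm, design, "a")
            resp = [g for g in truth.responsive_gene_ids if g in set(nm.gene_ids)]
            err = tab.frame.loc[resp, "beta"] - truth.true_betas.loc[resp]
            rmses.append(np.sqrt((err ** 2).mean()))
        assert rmses[0] > rmses[1] > rmses[2]


class TestModeration:
    def test_identical_variances_no_shrinkage(self, rng):
        x = rng.normal(size=12)
        design = cx.make_design(pd.DataFrame({"x": x}))
        # craft 15 genes with exactly equal residual variance via permuted residuals
        base_resid = rng.normal(size=12)
        base_resid -= np.polyval(np.polyfit(x, base_resid, 1), x)  # orthogonalize
        y = np.array([2.0 * x + np.roll(base_resid, 0) for _ in range(15)])
        tab = cx.fit_gene_models(normmat(y), design, "x")
        mod = cx.moderate_variances(tab)
        assert np.allclose(mod.frame["t_mod"], mod.frame["t"], rtol=1e-6)
        assert mod.d0 >= 1e5  # large-cap in the degenerate case

    def test_matches_reference_implementation_fixture(self, rng):
        """Frozen d0/s0^2/t computed with the standard moderated-t implementation
        in limma on a 30-gene, 6-sample instance."""
        r = np.random.default_rng(0)  # fixture regenerated deterministically
        y = _limma_fixture_y()
        design = cx.make_design(pd.DataFrame({"x": [0, 0, 0, 1, 1, 1]}))
        mod = cx.moderate_variances(cx.fit_gene_models(normmat(y), design, "x"))
        assert mod.d0 == pytest.approx(15.1101935175, rel=1e-4)
        assert mod.s0_2 == pytest.approx(0.8253368934, rel=1e-4)
        expected_t = [-0.6588659829, 1.0091819810, 0.2038574652,
                      -0.1778218441, 1.6265639584]
        assert np.allclose(mod.frame["t_mod"].to_numpy()[:5], expected_t, atol=1e-5)

    def test_moment_estimator_matches_stepwise_oracle(self, rng):
        """d0/s0^2 equal an independent step-by-step computation of the
        log-variance moment equations."""
        from scipy import special
        s2 = rng.lognormal(0.0, 1.5, 40)  # spread wide enough for a finite prior df
        df = 4.0
        d0, s0_2 = cx.estimate_variance_prior(s2, df)
        e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
        evar = e.var(ddof=1) - special.polygamma(1, df / 2)
        assert evar > 0
        # d0 solves trigamma(d0/2) = evar
        assert special.polygamma(1, d0 / 2) == pytest.approx(evar, rel=1e-8)
        assert s0_2 == pytest.approx(
            np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)), rel=1e-10)

    def test_shrinkage_is_convex(self, rng):
        """Moderated |t| lies between |t| computed with s_g and with s0."""
        y = rng.normal(size=(50, 8))
        design = cx.make_design(pd.DataFrame({"x": rng.normal(size=8)}))
        tab = cx.fit_gene_models(normmat(y), design, "x")
        mod = cx.moderate_variances(tab)
        beta = mod.frame["beta"].to_numpy()
        c = tab.stdev_unscaled.to_numpy()
        t_gene = np.abs(tab.frame["t"].to_numpy())
        t_prior = np.abs(beta / (np.sqrt(mod.s0_2) * c))
        t_mod = np.abs(mod.frame["t_mod"].to_numpy())
        lo = np.minimum(t_gene, t_prior) - 1e-9
        hi = np.maximum(t_gene, t_prior) + 1e-9
        assert ((t_mod >= lo) & (t_mod <= hi)).all()
        # and moderation never flips the sign
        assert (np.sign(mod.frame["t_mod"]) == np.sign(mod.frame["t"])).all()


def _limma_fixture_y():
    """30 x 6 normal draws frozen from the oracle session (R set.seed(7))."""
    return np.array(_LIMMA_Y).reshape(30, 6)


_LIMMA_Y = [
    2.28725, -0.870851, 0.076371, 1.63579, -1.55472, -0.355694,
    -1.19677, 0.718711, 0.159155, -0.645423, 1.56989, 1.0973,
    -0.694293, 0.110653, 0.543674, 0.618992, 0.68845, -0.906692,
    -0.412293, -0.078467, 0.704807, 0.236394, -0.177604, -0.207457,
    -0.970673, -0.42049, 0.318969, 0.846501, 0.729201, 0.678861,
    -0.94728, -0.562126, 1.10925, -0.573646, 1.53325, -0.797788,
    0.748139, 0.997513, 0.769154, 1.11799, 0.506578, -1.59154,
    -0.116955, -1.10513, 1.15347, -1.54, 0.033328, 1.18035,
    0.152658, -0.142288, 1.26068, -0.438124, -1.46755, 1.22257,
    2.18998, 0.314995, 0.700624, -0.150673, 1.01916, -0.010909,
    0.356986, 1.21855, 0.432627, 0.519058, -0.593339, 0.345522,
    2.71675, -0.699317, -0.922602, 0.58754, 0.81241, 0.094189,
    2.28145, -0.285433, -0.615584, -0.079333, 0.866168, 0.006793,
    0.324021, -1.31155, -0.86666, -1.17436, 0.368308, 0.742623,
    1.89607, -0.391012, -1.63952, 0.308722, 1.13482, 1.04219,
    0.467681, -0.401527, -1.32584, -1.60388, -0.757099, -0.319337,
    -0.893801, 1.35052, -0.889037, 0.99129, 0.445221, 0.322643,
    -0.307328, 0.59119, -0.557602, 1.02322, 0.915933, 0.685053,
    -0.004822, 0.100525, -0.062402, 0.840145, 0.269759, 0.320243,
    0.988164, 0.931072, 2.42269, 0.120079, 1.00754, -1.91494,
    0.83975, -0.262742, 0.342585, -0.426255, -1.46143, -2.33996,
    0.705342, -0.007668, 0.004248, 0.458926, -0.874786, 0.482864,
    1.30597, 0.367153, 0.02922, 0.645048, 0.165229, 1.17853,
    -1.388, 1.70716, -0.393423, 0.611531, 0.207207, -1.29278,
    1.27292, 0.72374, -0.792705, -0.889211, 0.482362, 0.615773,
    0.184193, 0.481036, -0.311702, 1.54389, -0.071658, 0.256042,
    0.75228, -1.56787, -0.346069, -1.24176, -0.888928, 0.727839,
    0.591745, 0.31825, -0.304608, 1.10345, 0.485944, 1.32411,
    -0.983053, 0.165991, -1.78589, 0.982772, 0.340497, 0.147158,
    -0.276064, -0.899908, 0.587275, 0.304327, -1.09792, -0.598539,
]


class TestAdjustPvalues:
    def test_bh_by_hand(self):
        q = cx.adjust_pvalues([0.01, 0.02, 0.03], "BH")
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert cx.adjust_pvalues([0.2], "BH")[0] == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bh_matches_brute_force_stepup(self, ps):
        p = np.array(ps)
        q = cx.adjust_pvalues(p, "BH")
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert np.allclose(q, brute, atol=1e-12)

    def test_bonferroni_flags_and_thresholds(self):
        flags = cx.adjust_pvalues([0.001, 0.02, 0.4], "bonferroni", alpha=0.05)
        assert flags.tolist() == [True, False, False]
        assert cx.bonferroni_threshold(16694) == pytest.approx(3.0e-6)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cx.adjust_pvalues([1.5], "BH")


class TestVarianceFractions:
    def test_exact_predictor_takes_all(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        cov = pd.DataFrame({"x": x})
        vf = cx.variance_fractions(normmat(x[None, :]), cov)
        assert vf["x"].iloc[0] == pytest.approx(100.0)
        assert vf["residual"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_hundred(self, rng):
        y = rng.normal(size=(20, 10))
        cov = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        vf = cx.variance_fractions(normmat(y), cov)
        assert np.allclose(vf.sum(axis=1), 100.0, atol=1e-9)

    def test_orthogonal_equal_effects_split_evenly(self, rng):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        y = (a + b + rng.normal(scale=0.5, size=n))[None, :]
        vf = cx.variance_fractions(normmat(y), pd.DataFrame({"a": a, "b": b}))
        assert vf["a"].iloc[0] == pytest.approx(vf["b"].iloc[0], rel=0.15)


class TestConditionContrast:
    def test_known_shift_recovered(self, rng):
        n = 40
        cond = np.array(["monoculture"] * 20 + ["coculture"] * 20)
        y = rng.normal(size=(100, n))
        y[:20, 20:] += 1.0
        tab = cx.condition_contrast(normmat(y), cond,
                                    levels=("monoculture", "coculture"))
        assert tab.frame["beta"].iloc[:20].mean() == pytest.approx(1.0, abs=0.25)
        assert tab.frame["beta"].iloc[20:].mean() == pytest.approx(0.0, abs=0.15)

    def test_identical_groups_zero_lfc(self):
        y = np.tile(np.arange(4.0), (3, 2)).reshape(3, 8)
        cond = ["a"] * 4 + ["b"] * 4
        y2 = np.concatenate([y[:, :4], y[:, :4]], axis=1)
        tab = cx.condition_contrast(normmat(y2), cond)
        assert np.allclose(tab.frame["beta"], 0.0, atol=1e-12)

    def test_label_permutation_null(self, rng):
        y = rng.normal(size=(300, 16))
        cond = rng.permutation(["a"] * 8 + ["b"] * 8)
        tab = cx.condition_contrast(normmat(y), list(cond))
        assert stats.kstest(tab.frame["p"], "uniform").pvalue > 0.01


class TestAggregateAndClassStats:
    def test_constructed_one_sd_shift(self, rng):
        n_a, n_b = 10, 10
        base = rng.normal(size=(50, n_a + n_b))
        # shift condition-B samples by one pooled SD for every set gene
        sd = base.std(axis=1, ddof=1, keepdims=True)
        base[:, n_a:] += sd
        nm = normmat(base)
        cond = ["mono"] * n_a + ["co"] * n_b
        res = cx.aggregate_shift(nm, nm.gene_ids, cond, levels=("mono", "co"))
        assert res.estimate == pytest.approx(1.0, abs=0.25)
        assert res.p < 1e-6

    def test_empty_intersection_rejected(self, rng):
        nm = normmat(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match="intersect"):
            cx.aggregate_shift(nm, ["nope"], ["a", "a", "a", "b", "b", "b"])

    def test_marker_class_shift_recovers_delta(self, rng):
        delta = 0.8
        y = rng.normal(size=(30, 40))
        group = np.array(["g1"] * 20 + ["g2"] * 20)
        sd = y.std(axis=1, ddof=1, keepdims=True)
        y[:, 20:] += delta * sd
        beta, se, p = cx.marker_class_shift(normmat(y), [f"g{i}" for i in range(30)], group)
        assert beta == pytest.approx(delta, abs=3 * se + 0.15)
        assert p < 0.01

    def test_marker_class_shift_null(self, rng):
        y = rng.normal(size=(20, 30))
        group = ["a"] * 15 + ["b"] * 15
        beta, se, p = cx.marker_class_shift(normmat(y), [f"g{i}" for i in range(20)], group)
        assert abs(beta) < 3 * se + 0.2

    def test_marker_class_contrast(self, rng):
        a = rng.normal(4.4, 0.5, size=(10, 28))
        b = rng.normal(1.5, 0.5, size=(8, 28))
        nm = normmat(np.vstack([a, b]))
        ga = [f"g{i}" for i in range(10)]
        gb = [f"g{i}" for i in range(10, 18)]
        delta, p = cx.marker_class_contrast(nm, ga, gb)
        assert delta == pytest.approx(2.9, abs=0.15)
        assert p < 1e-10
        # equal classes give zero difference
        d0, _ = cx.marker_class_contrast(nm, ga, ga)
        assert d0 == 0.0
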