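"""GLM fitting, AICc model selection, variance partitioning, contrasts,
the functional-redundancy ANCOVA and the NB Wald differential test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbiome import models as mod


@pytest.fixture(scope="module")
def lin_data():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"x": rng.normal(size=40), "g": list("ab") * 20,
         "z": rng.normal(size=40)}
    )
    y = 2.0 + 3.0 * df["x"] + (df["g"] == "b") * 1.5 + rng.normal(size=40)
    return y, df


class TestGaussianGLM:
    def test_exact_linear_data_recovered(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        y = 1.0 + 2.0 * df["x"]
        fit = mod.fit_glm(y, data=df, terms=["x"], family="gaussian")
        assert fit.coef["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coef["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.deviance == pytest.approx(0.0, abs=1e-18)

    def test_matches_ols_oracle(self, lin_data):
        sm = pytest.importorskip("statsmodels.api")
        y, df = lin_data
        fit = mod.fit_glm(y, data=df, terms=["x", "g"], family="gaussian")
        X, names, _ = mod.build_design(df, ["x", "g"])
        ols = sm.OLS(np.asarray(y), X).fit()
        assert np.abs(fit.coef.to_numpy() - ols.params).max() < 1e-10
        assert np.abs(fit.cov.to_numpy() - ols.cov_params()).max() < 1e-10
        assert fit.llf == pytest.approx(ols.llf, abs=1e-8)


class TestNegativeBinomialGLM:
    def test_large_dispersion_limit_reproduces_poisson(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"g": ["a"] * 30 + ["b"] * 30})
        y = rng.poisson(np.where(df["g"] == "a", 10, 30))
        fit = mod.fit_glm(y, data=df, terms=["g"],
                          family="negative_binomial", alpha=1e-8)
        X, _, _ = mod.build_design(df, ["g"])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(fit.coef.to_numpy() - pois.params).max() < 1e-6

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        beta = np.array([2.0, 0.7])
        mu = np.exp(beta[0] + beta[1] * x)
        alpha = 0.3
        y = rng.negative_binomial(n=1 / alpha, p=1 / (1 + alpha * mu))
        fit = mod.fit_glm(y, data=pd.DataFrame({"x": x}), terms=["x"],
                          family="negative_binomial")
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.coef["Intercept"] - beta[0]) < 3 * se[0]
        assert abs(fit.coef["x"] - beta[1]) < 3 * se[1]
        assert 0.1 < fit.alpha < 0.9

    def test_aicc_approaches_aic_for_large_n(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=10**6)})
        y = 1 + df["x"] + rng.normal(size=10**6)
        fit = mod.fit_glm(y, data=df, terms=["x"], family="gaussian")
        # the small-sample correction is exactly 2k(k+1)/(n-k-1), which at
        # n = 1e6 and k = 3 (two coefficients + scale) is 2.4e-5 and
        # vanishes relative to the criterion itself
        n, k = fit.n, fit.k
        # abs tolerance reflects float cancellation at AIC ~ 3e6 magnitude
        assert fit.aicc - fit.aic == pytest.approx(
            2 * k * (k + 1) / (n - k - 1), abs=1e-9
        )
        assert abs(fit.aicc - fit.aic) < 1e-4
        assert abs(fit.aicc - fit.aic) / abs(fit.aic) < 1e-9


class TestAllSubsets:
    def test_single_true_effect_selected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"x": rng.normal(size=100), "noise": rng.normal(size=100)}
        )
        y = 2 * df["x"] + rng.normal(size=100)
        best, table = mod.all_subsets_select(y, df, ["x", "noise"])
        assert best.terms == ("x",)
        assert (table["aicc"].diff().dropna() >= -1e-12).all()

    def test_pure_noise_mostly_selects_intercept(self):
        rng = np.random.default_rng(5)
        wins = 0
        for s in range(30):
            df = pd.DataFrame({"a": rng.normal(size=40),
                               "b": rng.normal(size=40)})
            y = pd.Series(rng.normal(size=40))
            best, _ = mod.all_subsets_select(y, df, ["a", "b"])
            wins += best.terms == ()
        assert wins > 15

    def test_interactions_require_main_effects(self):
        subsets = list(mod._subsets(["a", "b", "a:b"]))
        assert ["a:b"] not in subsets
        assert ["a", "a:b"] not in subsets
        assert ["a", "b", "a:b"] in subsets


class TestVariancePartition:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=60),
                           "g": list("abc") * 20})
        y = df["x"] + (df["g"] == "b") * 2 + rng.normal(size=60)
        out = mod.variance_partition(y, df, ["x", "g"])
        assert out.sum() == pytest.approx(1.0, abs=1e-10)
        assert (out >= -1e-12).all()

    def test_single_term_fraction_equals_r_squared(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        y = 2 * df["x"] + rng.normal(size=50)
        out = mod.variance_partition(y, df, ["x"])
        r2 = 1 - out["residual"]
        fit = mod.fit_glm(y, data=df, terms=["x"], family="gaussian")
        null = mod.fit_glm(y, data=df, terms=[], family="gaussian")
        assert r2 == pytest.approx(1 - fit.deviance / null.deviance,
                                   abs=1e-10)
        assert out["x"] == pytest.approx(r2, abs=1e-10)

    def test_orthogonal_balanced_design_is_order_invariant(self):
        # balanced 2x2: sequential SS identical in either order
        df = pd.DataFrame({"a": list("xxyy") * 10, "b": list("uvuv") * 10})
        rng = np.random.default_rng(8)
        y = (df["a"] == "y") * 1.0 + (df["b"] == "v") * 2.0 + rng.normal(
            size=40, scale=0.1
        )
        out = mod.variance_partition(y, df, ["a", "b"])
        seq_ab = mod.fit_glm(y, data=df, terms=["a"], family="gaussian")
        null = mod.fit_glm(y, data=df, terms=[], family="gaussian")
        first_a = (null.deviance - seq_ab.deviance) / null.deviance
        assert out["a"] == pytest.approx(first_a, abs=1e-10)


class TestContrasts:
    def test_self_contrast_is_null(self, lin_data):
        y, df = lin_data
        fit = mod.fit_glm(y, data=df, terms=["g"], family="gaussian")
        L = pd.DataFrame([[0.0, 0.0]], columns=fit.coef.index,
                         index=["b - b"])
        out = mod.pairwise_contrasts(fit, L)
        assert out.loc["b - b", "estimate"] == 0.0
        assert out.loc["b - b", "p"] == 1.0

    def test_bh_adjustment_hand_values(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.001, 0.04, 0.5], method="fdr_bh")[1]
        assert np.allclose(adj, [0.003, 0.06, 0.5])

    def test_null_contrast_calibration(self):
        rng = np.random.default_rng(9)
        rejections = 0
        trials = 500
        for s in range(trials):
            df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
            y = pd.Series(rng.normal(size=20))
            fit = mod.fit_glm(y, data=df, terms=["g"], family="gaussian")
            L = pd.DataFrame([[0.0, 1.0]], columns=fit.coef.index,
                             index=["b - a"])
            out = mod.pairwise_contrasts(fit, L)
            rejections += out["p"].iloc[0] <= 0.05
        assert rejections / trials <= 0.07


class TestRedundancyAncova:
    def test_identity_map_slope_one_not_redundant(self):
        rng = np.random.default_rng(10)
        t = rng.integers(10, 60, size=30).astype(float)
        out = mod.redundancy_ancova(t, t, ["g"] * 30)
        rec = out["slopes"][0]
        assert rec.slope == pytest.approx(1.0, abs=1e-10)
        assert not rec.redundant  # boundary: slope < 1 strictly

    def test_saturated_map_slope_zero_redundant(self):
        rng = np.random.default_rng(11)
        t = rng.integers(10, 60, size=30).astype(float)
        f = np.ones(30)
        rec = mod.redundancy_ancova(f, t, ["g"] * 30)["slopes"][0]
        assert rec.slope == pytest.approx(0.0, abs=1e-10)
        assert rec.redundant

    @pytest.mark.parametrize("slope,verdict", [(0.37, True), (3.30, False)])
    def test_slope_rule_on_known_slopes(self, slope, verdict):
        rng = np.random.default_rng(12)
        t = np.linspace(10, 50, 20)
        f = slope * t + rng.normal(size=20, scale=1e-6)
        rec = mod.redundancy_ancova(f, t, ["g"] * 20)["slopes"][0]
        assert rec.slope == pytest.approx(slope, abs=1e-3)
        assert rec.redundant is verdict

    def test_heterogeneity_detected_between_groups(self):
        rng = np.random.default_rng(13)
        t = np.concatenate([np.linspace(10, 50, 25)] * 2)
        f = np.concatenate(
            [0.3 * t[:25] + rng.normal(size=25, scale=0.5),
             2.5 * t[25:] + rng.normal(size=25, scale=0.5)]
        )
        groups = ["low"] * 25 + ["high"] * 25
        out = mod.redundancy_ancova(f, t, groups)
        assert out["heterogeneity"]["p"] < 1e-6
        assert len(out["pairwise"]) == 1
        assert out["pairwise"]["p_adj"].iloc[0] < 1e-6

    def test_degenerate_groups_flagged(self):
        out = mod.redundancy_ancova([1, 2, 3], [5, 5, 5], ["g"] * 3)
        assert out["slopes"] == []
        assert out["flagged"][0]["reason"] == "zero covariate variance"


class TestNBWaldDA:
    def test_size_factors_recover_exact_scalars(self):
        rng = np.random.default_rng(14)
        base = rng.integers(5, 50, size=8).astype(float)
        tab = pd.DataFrame([base, 2 * base, 4 * base], index=list("xyz"))
        sf = mod.size_factors(tab)
        # median-of-ratios normalizes the scalars by their geometric mean
        expected = np.array([1.0, 2.0, 4.0]) / 2.0
        assert np.allclose(sf.to_numpy(), expected, atol=1e-10)

    def test_known_fold_change_detected(self):
        rng = np.random.default_rng(15)
        mu = np.full((40, 12), 50.0)
        mu[20:, 0] *= 8.0
        counts = pd.DataFrame(
            rng.negative_binomial(n=1 / 0.3, p=1 / (1 + 0.3 * mu)),
            index=[f"s{i}" for i in range(40)],
            columns=[f"f{i}" for i in range(12)],
        )
        out = mod.nb_wald_da(counts, ["a"] * 20 + ["b"] * 20)
        hit = out[(out["feature"] == "f0") & (out["p_adj"] <= 0.05)]
        assert len(hit) == 1
        assert hit["log2_fold_change"].iloc[0] == pytest.approx(3.0, abs=0.8)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(16)
        rej = tot = 0
        for s in range(60):
            counts = pd.DataFrame(
                rng.negative_binomial(n=1 / 0.4, p=1 / (1 + 0.4 * 50),
                                      size=(20, 10)),
                index=[f"s{i}" for i in range(20)],
                columns=[f"f{i}" for i in range(10)],
            )
            out = mod.nb_wald_da(counts, ["a"] * 10 + ["b"] * 10)
            rej += int((out["p"] <= 0.05).sum())
            tot += len(out)
        assert 0.02 <= rej / tot <= 0.08

    def test_single_sample_group_excluded(self):
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(5, 4)).astype(float),
            index=[f"s{i}" for i in range(5)],
            columns=list("abcd"),
        )
        out = mod.nb_wald_da(counts, ["x", "x", "y", "y", "lone"])
        assert not out["coef"].str.contains("lone").any()
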