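import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from gazewm.stats import (LmmSpec, boxcox_select, fit_feature_ladder,
                          fit_lmm, fit_poisson_glmm, lr_ladder,
                          make_predictors, paired_tests,
                          simplify_random_structure)

RNG = np.random.default_rng(2024)


class TestBoxCox:
    def test_lognormal_data_recommends_log(self):
        y = np.exp(RNG.normal(size=5000))
        res = boxcox_select(y)
        assert res.transform == "log"
        assert res.ci95[0] <= 0.0 <= res.ci95[1]

    def test_normal_data_gives_lambda_near_one(self):
        y = RNG.normal(100, 5, 5000)
        res = boxcox_select(y)
        assert abs(res.lmbda - 1.0) < 0.2
        assert res.transform == "identity"

    def test_nonpositive_values_rejected_with_rows(self):
        with pytest.raises(ValueError, match="offending rows: \\[2\\]"):
            boxcox_select(np.array([1.0, 2.0, -1.0]))


class TestMakePredictors:
    def setup_method(self):
        self.cond = np.repeat([0, 45, 90, 135], 25)
        self.pred = make_predictors(self.cond)

    def test_polynomials_orthogonal_over_design(self):
        P = self.pred[["linear", "quadratic", "cubic"]].to_numpy()
        G = P.T @ P
        off = G - np.diag(np.diag(G))
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_columns_are_z_scaled(self):
        for col in self.pred.columns:
            assert self.pred[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert self.pred[col].std(ddof=0) == pytest.approx(1.0)

    def test_linear_column_monotone_in_angle(self):
        means = pd.DataFrame({"c": self.cond,
                              "lin": self.pred["linear"]}).groupby("c").mean()
        assert np.all(np.diff(means["lin"].to_numpy()) > 0)

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError, match="unknown condition"):
            make_predictors(np.array([0, 30]))


class TestPoissonGlmm:
    def test_intercept_only_constant_response(self):
        y = np.full(600, 2)
        groups = np.repeat(np.arange(6), 100)
        fit = fit_poisson_glmm(y, np.ones((600, 1)), groups,
                               fe_names=["intercept"])
        assert fit.fixed_effects.loc["intercept", "estimate"] == \
            pytest.approx(np.log(2), abs=1e-6)
        assert float(np.trace(fit.cov_re)) < 1e-4

    def test_matches_glm_oracle_when_no_group_variance(self):
        rng = np.random.default_rng(7)
        n = 3000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = rng.poisson(np.exp(0.4 + 0.3 * x))
        groups = rng.integers(0, 10, n)
        fit = fit_poisson_glmm(y, X, groups, fe_names=["intercept", "x"])
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(
            fit.fixed_effects["estimate"].to_numpy() - glm.params)) < 1e-4

    def test_slope_recovered_within_two_se(self):
        """True fixed slope lands inside +-2 SE in at least 90% of
        replicates."""
        beta_true = 0.25
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            G, npg = 12, 100
            g = np.repeat(np.arange(G), npg)
            x = rng.normal(size=G * npg)
            b0 = rng.normal(0, 0.2, G)
            y = rng.poisson(np.exp(0.3 + beta_true * x + b0[g]))
            fit = fit_poisson_glmm(y, np.column_stack([np.ones(G * npg), x]),
                                   g, fe_names=["intercept", "x"],
                                   n_restarts=1)
            est = fit.fixed_effects.loc["x", "estimate"]
            se = fit.fixed_effects.loc["x", "se"]
            hits += abs(est - beta_true) <= 2 * se
        assert hits / reps >= 0.90

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_poisson_glmm(np.array([0.5, 1.0]), np.ones((2, 1)),
                             np.array([0, 1]))


class TestLrLadder:
    def _fits(self, seed=0):
        rng = np.random.default_rng(seed)
        G, npg = 12, 60
        g = np.repeat(np.arange(G), npg)
        cond = np.tile(np.repeat([0, 45, 90, 135], npg // 4), G)
        lin = make_predictors(cond)["linear"].to_numpy()
        b0 = rng.normal(0, 0.1, G)
        y = rng.poisson(np.exp(0.4 + 0.25 * lin + b0[g]))
        return fit_feature_ladder(y, cond, g, seed=0, n_restarts=1)

    def test_chi2_is_twice_loglik_gain(self):
        fits = self._fits()
        out = lr_ladder(fits).set_index("model")
        gain = 2 * (fits["quadratic"].loglik - fits["linear"].loglik)
        assert out.loc["quadratic", "chisq"] == pytest.approx(
            max(gain, 0.0), abs=1e-9)

    def test_model_compared_to_itself_is_null(self):
        fits = self._fits()
        dup = {"a": fits["linear"], "b": fits["linear"]}
        out = lr_ladder(dup, order=("a", "b"), compat_nonnested_p=True)
        assert out.iloc[1]["chisq"] == 0.0
        assert out.iloc[1]["p"] == 1.0

    def test_nonnested_rows_flagged(self):
        out = lr_ladder(self._fits())
        log_row = out.set_index("model").loc["logarithmic"]
        assert not log_row["nested"]
        assert "AIC" in log_row["note"]
        assert np.isnan(log_row["p"])

    def test_differing_n_obs_rejected(self):
        fits = self._fits()
        other = self._fits()
        other["exponential"].n_obs = 999
        with pytest.raises(ValueError, match="share observations"):
            lr_ladder({"exponential": other["exponential"],
                       "logarithmic": fits["logarithmic"]})

    def test_aic_bic_identities(self):
        for fit in self._fits().values():
            k, ll, n = fit.n_params, fit.loglik, fit.n_obs
            assert fit.aic == pytest.approx(2 * k - 2 * ll)
            assert fit.bic == pytest.approx(k * np.log(n) - 2 * ll)


class TestPairedTests:
    def _summary(self, values):
        """participant x condition table with pct_k columns."""
        rows = []
        for p in range(len(values[0])):
            for c, cond in enumerate((0, 45, 90, 135)):
                rows.append({"participant": p + 1, "condition_deg": cond,
                             **{f"pct_{k}": values[c][p] + k for k in
                                (1, 2, 3, 4)}})
        return pd.DataFrame(rows)

    def test_identical_vectors_give_null_result(self):
        vals = [[10.0, 20.0, 30.0]] * 4
        res = paired_tests(self._summary(vals), k_levels=(1,),
                           neighbor_pairs=((0, 45),))[0]
        assert res.t == 0.0 and res.cohens_d == 0.0
        assert res.ci95[0] <= 0.0 <= res.ci95[1]

    def test_hand_computed_fixture(self):
        # differences 1, 2, 3 -> mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.464
        a = [11.0, 22.0, 33.0]
        b = [10.0, 20.0, 30.0]
        res = paired_tests(self._summary([a, b, b, b]), k_levels=(1,),
                           neighbor_pairs=((0, 45),))[0]
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)
        assert res.cohens_d == pytest.approx(2.0)

    def test_twelve_comparisons_for_four_levels(self, small_sim):
        import gazewm as gw
        summary = gw.feature_probabilities(small_sim["scored"])
        res = paired_tests(summary)
        assert len(res) == 12
        assert all(r.df == r.n_pairs - 1 for r in res)


def _lmm_frame(rng, G=8, npg=40, slope_sd=0.0, noise=0.05):
    g = np.repeat(np.arange(G), npg)
    x = rng.normal(size=G * npg)
    b0 = rng.normal(0, 0.3, G)
    b1 = rng.normal(0, slope_sd, G)
    y = 1.0 + 0.5 * x + b0[g] + b1[g] * x + rng.normal(0, noise, G * npg)
    return pd.DataFrame({"y": y, "x": x, "x2": x ** 2, "g": g})


class TestLmm:
    def test_exact_linear_response_has_zero_quadratic_term(self):
        rng = np.random.default_rng(3)
        df = _lmm_frame(rng, slope_sd=0.0, noise=1e-6)
        df["y"] = 1.0 + 0.5 * df["x"]          # no noise, no grouping
        fit = fit_lmm(LmmSpec(df, "y", ["x", "x2"], "g"))
        assert abs(fit.fixed_effects.loc["x2", "estimate"]) < 1e-4
        assert fit.fixed_effects.loc["x", "estimate"] == \
            pytest.approx(0.5, abs=1e-4)

    def test_quadratic_sign_recovered(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            df = _lmm_frame(rng, noise=0.3)
            df["y"] = df["y"] + 0.4 * df["x2"]
            fit = fit_lmm(LmmSpec(df, "y", ["x", "x2"], "g"))
            hits += fit.fixed_effects.loc["x2", "estimate"] > 0
        assert hits / reps >= 0.95

    def test_stat_label_declares_df_method(self):
        rng = np.random.default_rng(4)
        fit = fit_lmm(LmmSpec(_lmm_frame(rng), "y", ["x"], "g"))
        assert "Satterthwaite" in fit.stat_label


class TestSimplifyRandomStructure:
    def test_zero_variance_slope_removed_with_audited_criteria(self):
        rng = np.random.default_rng(5)
        df = _lmm_frame(rng, G=12, npg=60, slope_sd=0.0, noise=0.2)
        spec = LmmSpec(df, "y", ["x"], "g", random_slopes=["x"])
        fit, final, audit = simplify_random_structure(spec)
        assert final.random_slopes == []
        removal = [a for a in audit if a["action"] == "remove"][0]
        assert removal["slope"] == "x"
        assert removal["criteria"]["lrt_p"] > 0.05
        assert removal["criteria"]["pca_component_share"] < 1e-3

    def test_supported_slope_retained(self):
        rng = np.random.default_rng(6)
        df = _lmm_frame(rng, G=12, npg=80, slope_sd=0.6, noise=0.2)
        spec = LmmSpec(df, "y", ["x"], "g", random_slopes=["x"])
        _, final, _ = simplify_random_structure(spec)
        assert final.random_slopes == ["x"]

    def test_intercept_never_removed(self):
        rng = np.random.default_rng(7)
        df = _lmm_frame(rng, G=10, npg=40, slope_sd=0.0, noise=0.2)
        spec = LmmSpec(df, "y", ["x"], "g", random_slopes=[])
        fit, final, audit = simplify_random_structure(spec)
        assert fit.random_structure.startswith("intercept")
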