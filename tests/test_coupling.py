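"""Wave-morphometry coupling regressions, Gamma GLMs and AICc dredging."""

import numpy as np
import pandas as pd
import pytest

from conftest import grid_gamma_mle_loglik
from wavemorph.coupling import (
    adjust_unit_interval,
    aicc,
    dredge,
    fit_glm,
    gamma_glm_fit,
    gaussian_lm_fit,
    mcfadden_r2,
    r2_topography_models,
    site_coupling,
    winter_mean_u,
)
from wavemorph.errors import DomainError, InsufficientDataError


class TestWinterMeanU:
    days = pd.DataFrame(
        {
            "date": ["2015-01-10", "2015-02-10", "2015-03-10", "2015-07-01"],
            "u_i_max": [5.0, 6.0, 7.0, 4.0],
        }
    )

    def test_mean_over_window(self):
        assert winter_mean_u(self.days, 2015) == pytest.approx(6.0)

    def test_missing_window_is_nan(self):
        assert np.isnan(winter_mean_u(self.days, 2016))


class TestSiteCoupling:
    def test_perfectly_linear_r2_one(self):
        df = pd.DataFrame(
            {"winter_u": [5, 6, 7, 8], "mean_S": [3.0, 2.8, 2.6, 2.4], "HQF": [0.5] * 4}
        )
        res = site_coupling("X", df)
        assert res.r2_S == pytest.approx(1.0)
        assert res.slope_S == pytest.approx(-0.2)
        assert res.r2_HQF == 0.0  # constant response

    def test_matches_closed_form_ols(self):
        u = np.array([5.0, 5.5, 6.0, 7.0, 8.0])
        s = np.array([2.9, 2.5, 2.8, 2.2, 2.0])
        df = pd.DataFrame({"winter_u": u, "mean_S": s, "HQF": s / 4})
        res = site_coupling("X", df)
        beta = np.cov(u, s, bias=True)[0, 1] / np.var(u)
        r2 = np.corrcoef(u, s)[0, 1] ** 2
        assert res.slope_S == pytest.approx(beta)
        assert res.r2_S == pytest.approx(r2)
        assert res.u_bar_site == pytest.approx(u.mean())

    def test_too_few_pairs(self):
        df = pd.DataFrame({"winter_u": [5, 6], "mean_S": [2, 3], "HQF": [0.5, 0.6]})
        with pytest.raises(InsufficientDataError):
            site_coupling("X", df)


class TestGammaGlm:
    def test_intercept_only_equals_log_mean(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(5.0, 2.0, 100)
        fit = gamma_glm_fit(y, np.ones((100, 1)))
        assert fit.params.iloc[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        mu = np.exp(0.5 + 0.3 * x)
        y = rng.gamma(5.0, mu / 5.0)
        fit = gamma_glm_fit(y, pd.DataFrame({"const": 1.0, "x": x}))
        assert fit.params["const"] == pytest.approx(0.5, abs=0.1)
        assert fit.params["x"] == pytest.approx(0.3, abs=0.1)
        assert fit.shape == pytest.approx(5.0, rel=0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 12)
        y = rng.gamma(3.0, np.exp(0.4 + 0.5 * x) / 3.0)
        X = np.column_stack([np.ones(12), x])
        fit = gamma_glm_fit(y, X)
        oracle = grid_gamma_mle_loglik(y, X)
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)
        assert fit.loglik >= oracle - 1e-6  # true ML cannot be beaten

    def test_rejects_nonpositive_response(self):
        with pytest.raises(DomainError):
            gamma_glm_fit([1.0, -2.0, 3.0], np.ones((3, 1)))

    def test_rejects_rank_deficiency(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(DomainError):
            gamma_glm_fit(np.linspace(1, 2, 10), X)


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-100.0, 3, 20) == pytest.approx(207.5)
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 4, 10**9) == pytest.approx(208.0, abs=1e-6)

    def test_undefined_for_small_n(self):
        with pytest.raises(DomainError):
            aicc(-10.0, 5, 6)


class TestDredge:
    def test_enumerates_admissible_models(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"A": rng.normal(size=30), "B": rng.normal(size=30)})
        d["y"] = rng.normal(size=30)
        tab = dredge(d, "y", ["A", "B", "A:B"])
        assert set(tab["terms"]) == {"1", "A", "B", "A + B", "A + B + A:B"}

    def test_recovers_generating_term(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, 200)
        B = rng.normal(0, 1, 200)
        d = pd.DataFrame({"A": A, "B": B, "y": 1.0 + 2.0 * A + rng.normal(0, 0.5, 200)})
        tab = dredge(d, "y", ["A", "B", "A:B"])
        assert "A" in tab["terms"].iloc[0]
        assert tab["weight"].iloc[0] > 0.5
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_null_competitive_on_pure_noise(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d = pd.DataFrame(
                {"A": rng.normal(size=40), "B": rng.normal(size=40), "y": rng.normal(size=40)}
            )
            tab = dredge(d, "y", ["A", "B"])
            null_delta = float(tab.loc[tab["terms"] == "1", "delta"].iloc[0])
            hits += null_delta <= 2.0
        assert hits >= 40  # >= 80% of seeds

    def test_ranking_depends_only_on_delta(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame({"A": rng.normal(size=50)})
        d["y"] = 2 + d["A"] + rng.normal(0, 1, 50)
        tab = dredge(d, "y", ["A"])
        assert (tab["delta"] >= 0).all()
        w = np.exp(-tab["delta"] / 2)
        assert np.allclose(tab["weight"], w / w.sum())


class TestMcFadden:
    def test_null_vs_null_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(4, 1, 50)
        null = gamma_glm_fit(y, np.ones((50, 1)))
        assert mcfadden_r2(null, null) == 0.0

    def test_strong_signal_in_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        y = rng.gamma(5.0, np.exp(0.5 + 0.3 * x) / 5.0)
        X = np.column_stack([np.ones(500), x])
        fit = gamma_glm_fit(y, X)
        null = gamma_glm_fit(y, np.ones((500, 1)))
        val = mcfadden_r2(fit, null)
        assert 0.0 < val < 1.0

    def test_gaussian_value_rises_toward_one_as_noise_shrinks(self):
        # meaningful (0,1) range requires both log-likelihoods negative,
        # i.e. residual sd above ~1/sqrt(2*pi*e)
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 200)
        X = np.column_stack([np.ones(200), x])
        vals = []
        for noise in (3.0, 1.0, 0.45):
            y = 100.0 * x + rng.normal(0, noise, 200)
            fit = gaussian_lm_fit(y, X)
            null = gaussian_lm_fit(y, np.ones((200, 1)))
            vals.append(mcfadden_r2(fit, null))
        assert all(0.0 < v < 1.0 for v in vals)
        assert vals[0] < vals[1] < vals[2]


class TestTopographyModels:
    def _table(self, rng, n=26, signal="interaction", noise=0.05):
        alpha = rng.uniform(0, 90, n)
        slope = -rng.uniform(0.009, 0.1, n)
        u_bar = rng.uniform(5, 8, n)
        if signal == "interaction":
            y = 0.3 + 2.0 * slope * u_bar + rng.normal(0, noise, n)
        elif signal == "alpha":
            y = 0.8 - 0.006 * alpha + rng.normal(0, noise, n)
        else:
            y = np.full(n, 0.5)
        return pd.DataFrame({"alpha": alpha, "slope": slope, "u_bar": u_bar, "r2_S": y})

    def test_interaction_signal_recovered(self):
        hits = 0
        for seed in range(20):
            tab = r2_topography_models(self._table(np.random.default_rng(seed)))
            hits += "slope:u_bar" in tab["terms"].iloc[0]
        assert hits >= 15

    def test_alpha_signal_recovered(self):
        tab = r2_topography_models(self._table(np.random.default_rng(5), signal="alpha"))
        assert "alpha" in tab["terms"].iloc[0]

    def test_constant_response_prefers_null(self):
        tab = r2_topography_models(self._table(np.random.default_rng(0), signal="none"))
        assert tab["terms"].iloc[0] == "1"

    def test_too_few_sites(self):
        with pytest.raises(InsufficientDataError):
            r2_topography_models(self._table(np.random.default_rng(0), n=5))


class TestFitGlmFormula:
    def test_categorical_factor_expansion(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 20), "y": rng.gamma(4, 1, 60) + 0.5}
        )
        fit = fit_glm("y ~ C(g)", d, family="gamma_log")
        assert fit.n_params == 4  # 3 coefficients + shape


def test_adjust_unit_interval():
    assert adjust_unit_interval(0.0, 10) == pytest.approx(0.05)
    assert adjust_unit_interval(1.0, 10) == pytest.approx(0.95)
    assert adjust_unit_interval(0.5, 100) == pytest.approx(0.5, abs=1e-12)
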