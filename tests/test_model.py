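"""Two-part model: fitters, comparators, diagnostics, recombination, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import afcost
from afcost.design import DesignSpec, build_design, design_columns, encode_covariates
from afcost.diagnostics import diagnose_family_link
from afcost.twopart import (
    GammaGLMFit,
    ProbitFit,
    SeparationError,
    TwoPartFit,
    fit_comparators,
    fit_glm_gamma_log,
    fit_probit,
    fit_two_part,
    predict_mean_cost,
)

from conftest import grid_maximise


def _ones(n):
    return pd.DataFrame({"intercept": np.ones(n)})


class TestFitProbit:
    def test_intercept_only_half_positives(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        fit = fit_probit(_ones(40), y)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_75pct(self):
        y = np.r_[np.ones(30), np.zeros(10)]
        fit = fit_probit(_ones(40), y)
        assert fit.params["intercept"] == pytest.approx(stats.norm.ppf(0.75), abs=1e-6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_probit(_ones(10), np.ones(10))

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(15), np.ones(15)]
        X = pd.DataFrame({"intercept": np.ones(30), "x": x})
        with pytest.raises((SeparationError, ValueError)):
            fit_probit(X, x.copy())

    def test_score_equations_vanish_and_probabilities_calibrate(self, model_panel):
        # at the MLE the probit score is zero: sum over rows of
        # (y - Phi) * phi / (Phi (1 - Phi)) * x = 0 for every column; the
        # average fitted probability then tracks the sample frequency closely
        # (exact equality is a logit property, not a probit one)
        params, panel = model_panel
        X, any_use, _ = build_design(panel, params.design)
        fit = fit_probit(X, any_use)
        eta = X.to_numpy() @ fit.params.to_numpy()
        p = stats.norm.cdf(eta)
        w = stats.norm.pdf(eta) / (p * (1 - p))
        score = ((any_use.to_numpy() - p) * w) @ X.to_numpy()
        assert np.abs(score).max() < 1e-6 * len(panel)
        assert p.mean() == pytest.approx(any_use.mean(), abs=0.005)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=30)
        X = pd.DataFrame({"intercept": np.ones(30), "x": x})
        y = (rng.random(30) < stats.norm.cdf(0.4 + 0.8 * x)).astype(float)

        def loglik(theta):
            eta = X.to_numpy() @ theta
            p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        oracle = grid_maximise(loglik)
        fit = fit_probit(X, y)
        assert np.abs(fit.params.to_numpy() - oracle).max() < 1e-4


class TestFitGammaGLM:
    def test_intercept_only_equals_log_mean(self):
        rng = np.random.default_rng(5)
        y = rng.gamma(2.0, 50.0, size=200)
        fit = fit_glm_gamma_log(_ones(200), y)
        assert fit.params["intercept"] == pytest.approx(np.log(y.mean()), abs=1e-10)

    def test_nonpositive_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_glm_gamma_log(_ones(5), np.array([1.0, 2.0, 0.0, 4.0, 5.0]))

    def test_parameter_recovery(self):
        # gamma = (log 500, 0.3), shape 2; estimates within 3 reported SEs
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.integers(0, 2, size=n).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        mu = np.exp(np.log(500.0) + 0.3 * x)
        y = rng.gamma(2.0, mu / 2.0)
        fit = fit_glm_gamma_log(X, y)
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.params["intercept"] - np.log(500.0)) < 3 * se[0]
        assert abs(fit.params["x"] - 0.3) < 3 * se[1]
        assert 1.5 < fit.shape < 2.5

    def test_doubling_covariate_coefficient_log2(self):
        rng = np.random.default_rng(9)
        n = 20_000
        x = rng.integers(0, 2, size=n).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = rng.gamma(2.0, (100.0 * 2.0**x) / 2.0)
        fit = fit_glm_gamma_log(X, y)
        se = np.sqrt(fit.cov.loc["x", "x"])
        assert abs(fit.params["x"] - np.log(2.0)) < 3 * se

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(27)
        x = rng.normal(size=30)
        X = pd.DataFrame({"intercept": np.ones(30), "x": x})
        y = rng.gamma(2.0, np.exp(1.0 + 0.5 * x) / 2.0)

        def loglik(theta):
            # coefficient estimates do not depend on the fixed shape
            mu = np.exp(X.to_numpy() @ theta)
            return float(np.sum(stats.gamma.logpdf(y, a=1.0, scale=mu)))

        oracle = grid_maximise(loglik)
        fit = fit_glm_gamma_log(X, y)
        assert np.abs(fit.params.to_numpy() - oracle).max() < 1e-4


class TestComparators:
    def test_gaussian_data_prefers_ols(self):
        rng = np.random.default_rng(13)
        n = 5000
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = 100.0 + 5.0 * x + rng.normal(0, 2.0, size=n)
        g = fit_glm_gamma_log(X, y)
        aics = fit_comparators(X, y, gamma_aic=g.aic)
        assert aics.best() == "ols"

    def test_gamma_data_prefers_gamma_glm(self):
        rng = np.random.default_rng(14)
        n = 5000
        x = rng.integers(0, 2, size=n).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = rng.gamma(1.2, np.exp(6.0 + 0.5 * x) / 1.2)
        g = fit_glm_gamma_log(X, y)
        aics = fit_comparators(X, y, gamma_aic=g.aic)
        assert aics.best() == "gamma_glm"

    def test_selection_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(15)
        n = 2000
        x = rng.normal(size=n)
        X1 = pd.DataFrame({"intercept": np.ones(n), "x": x})
        X2 = pd.DataFrame({"intercept": np.ones(n), "x": 10.0 * x})
        y = rng.gamma(2.0, np.exp(4.0 + 0.3 * x) / 2.0)
        a1 = fit_comparators(X1, y, fit_glm_gamma_log(X1, y).aic)
        a2 = fit_comparators(X2, y, fit_glm_gamma_log(X2, y).aic)
        assert a1.best() == a2.best()
        assert a1.ols == pytest.approx(a2.ols, abs=1e-6)
        assert a1.gamma_glm == pytest.approx(a2.gamma_glm, abs=1e-6)


class TestDiagnostics:
    @staticmethod
    def _fit(X, y):
        return fit_glm_gamma_log(X, y)

    def test_gamma_data_recommends_gamma(self):
        rng = np.random.default_rng(19)
        n = 20_000
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = rng.gamma(2.0, np.exp(5.0 + 0.4 * x) / 2.0)
        rep = diagnose_family_link(X, y, self._fit(X, y))
        assert 1.5 < rep.park_lambda < 2.5
        assert rep.recommended_family == "gamma"

    def test_constant_variance_recommends_gaussian(self):
        rng = np.random.default_rng(20)
        n = 20_000
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = np.exp(3.0 + 0.4 * x) + rng.normal(0, 1.0, size=n)
        y = np.maximum(y, 0.1)
        rep = diagnose_family_link(X, y, self._fit(X, y))
        assert rep.park_lambda < 0.5
        assert rep.recommended_family == "gaussian"

    def test_hosmer_lemeshow_type_i_error(self):
        # a correctly specified model should reject at roughly the 5% level
        rng = np.random.default_rng(21)
        n, reps = 400, 100
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            X = pd.DataFrame({"intercept": np.ones(n), "x": x})
            y = rng.gamma(2.0, np.exp(4.0 + 0.3 * x) / 2.0)
            rep = diagnose_family_link(X, y, self._fit(X, y))
            rejections += rep.hl_p < 0.05
        assert rejections / reps <= 0.12

    def test_too_few_fitted_values_rejected(self):
        y = np.full(30, 7.0)
        y[::2] = 9.0
        X = _ones(30)
        fit = fit_glm_gamma_log(_ones(30), np.random.default_rng(1).gamma(2, 5, 30))
        from afcost.diagnostics import modified_hosmer_lemeshow

        with pytest.raises(ValueError, match="distinct fitted"):
            modified_hosmer_lemeshow(y, np.full(30, 8.0))


def _manual_fit(columns, beta, gamma, spec):
    probit = ProbitFit(
        params=pd.Series(beta, index=columns),
        cov=pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns),
        llf=0.0,
        converged=True,
        n=1,
    )
    gam = GammaGLMFit(
        params=pd.Series(gamma, index=columns),
        cov=pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns),
        shape=1.0,
        llf=0.0,
        aic=0.0,
        n=1,
    )
    return TwoPartFit(
        probit=probit, gamma=gam, comparators=None, diagnostics=None,
        spec=spec, columns=list(columns), n_part1=1, n_part2=1,
    )


class TestPredictMeanCost:
    def test_half_times_exp(self):
        # x.beta = 0, x.gamma = log 7570 -> 0.5 * 7570
        spec = DesignSpec(blocks=("sex",))
        cols = design_columns(spec)
        fit = _manual_fit(cols, [0.0, 0.0], [np.log(7570.0), 0.0], spec)
        X = pd.DataFrame({"intercept": [1.0], "female": [0.0]})
        per_row, grand = predict_mean_cost(fit, X)
        assert grand == pytest.approx(3785.0)

    def test_degenerate_part_one_gives_exp_mean(self):
        spec = DesignSpec(blocks=("sex",))
        cols = design_columns(spec)
        fit = _manual_fit(cols, [0.0, 0.0], [np.log(100.0), np.log(2.0)], spec)
        fit.probit = None  # probability part identically one
        X = pd.DataFrame({"intercept": [1.0, 1.0], "female": [0.0, 1.0]})
        per_row, grand = predict_mean_cost(fit, X)
        assert per_row == pytest.approx([100.0, 200.0])
        assert grand == pytest.approx(150.0)

    def test_column_mismatch_rejected(self):
        spec = DesignSpec(blocks=("sex",))
        cols = design_columns(spec)
        fit = _manual_fit(cols, [0.0, 0.0], [0.0, 0.0], spec)
        with pytest.raises(ValueError, match="columns"):
            predict_mean_cost(fit, pd.DataFrame({"intercept": [1.0]}))


class TestRecombination:
    def test_grand_mean_near_oracle_and_shrinking_error(self, model_panel):
        params, _ = model_panel
        errors = {}
        for n, seed in ((1000, 101), (10_000, 102)):
            import dataclasses

            p = dataclasses.replace(params, seed=seed)
            pop = afcost.generate_population(n, p)
            panel = afcost.generate_panel(pop, p)
            fit = fit_two_part(panel, p.design, compare=False)
            m = afcost.mean_annual_cost(panel, fit)
            X = encode_covariates(panel, p.design)
            oracle = float(afcost.dgp_expected_mean(X.to_numpy(), p).mean())
            errors[n] = abs(m - oracle) / oracle
        assert errors[10_000] < 0.05
        assert errors[10_000] < errors[1000]


class TestBuildDesign:
    def test_reference_row_all_zero(self):
        row = pd.DataFrame(
            {
                "age_group": ["0-49"],
                "sex": ["male"],
                "admission_year": [2005],
                "simd": [1],
                "geography": ["large_urban"],
                "health_board": ["greater_glasgow_and_clyde"],
                "comorbidity": [1],
                "died_within_5y": [False],
            }
        )
        X = encode_covariates(row, DesignSpec(year_center=2005))
        assert X["intercept"].iloc[0] == 1.0
        assert X.drop(columns="intercept").iloc[0].abs().sum() == 0.0

    def test_k_minus_one_age_columns(self):
        spec = DesignSpec(year_center=2005)
        age_cols = [c for c in design_columns(spec) if c.startswith("age_") and ":" not in c]
        assert len(age_cols) == 9

    def test_excluding_mortality_drops_interaction_too(self):
        spec = DesignSpec(include_mortality=False, year_center=2005)
        cols = design_columns(spec)
        assert "died" not in cols
        assert not any(c.startswith("died:") for c in cols)

    def test_unseen_category_rejected(self):
        row = pd.DataFrame(
            {
                "age_group": ["0-49"],
                "sex": ["other"],
                "admission_year": [2005],
                "simd": [1],
                "geography": ["large_urban"],
                "health_board": ["greater_glasgow_and_clyde"],
                "comorbidity": [1],
                "died_within_5y": [False],
            }
        )
        from afcost.design import UnseenCategoryError

        with pytest.raises(UnseenCategoryError):
            encode_covariates(row, DesignSpec(year_center=2005))


class TestBootstrap:
    def test_b_too_small_rejected(self, model_panel):
        params, panel = model_panel
        with pytest.raises(ValueError):
            afcost.bootstrap_ci(panel, params.design, B=50, seed=1)

    def test_point_estimate_independent_of_B(self, model_panel):
        params, panel = model_panel
        small = panel[panel["patient_id"].isin(panel["patient_id"].unique()[:300])]
        a = afcost.bootstrap_ci(small, params.design, B=100, seed=3)
        b = afcost.bootstrap_ci(small, params.design, B=200, seed=3)
        assert a["mean_annual_cost"]["point"] == b["mean_annual_cost"]["point"]

    def test_degenerate_constant_cost(self):
        rows = []
        for i in range(100):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "year_index": 1,
                    "age_group": "0-49",
                    "sex": "male" if i % 2 else "female",
                    "admission_year": 2005,
                    "simd": 1,
                    "geography": "large_urban",
                    "health_board": "greater_glasgow_and_clyde",
                    "comorbidity": 1 + (i % 3),
                    "died_within_5y": False,
                    "any_use": True,
                    "total": 250.0,
                }
            )
        panel = pd.DataFrame(rows)
        spec = DesignSpec(blocks=("sex", "comorbidity"), year_center=2005)
        ci = afcost.bootstrap_ci(panel, spec, B=100, seed=4)
        assert ci["mean_annual_cost"]["lower"] == pytest.approx(250.0)
        assert ci["mean_annual_cost"]["upper"] == pytest.approx(250.0)


class TestClusterRobust:
    def test_sandwich_close_to_model_based_under_independence(self, model_panel):
        # the generator draws follow-up years independently given covariates,
        # so clustered and model-based standard errors should roughly agree
        params, panel = model_panel
        plain = fit_two_part(panel, params.design, compare=False)
        clustered = fit_two_part(panel, params.design, compare=False, cluster_robust=True)
        pd.testing.assert_series_equal(plain.gamma.params, clustered.gamma.params)
        se_plain = np.sqrt(np.diag(plain.probit.cov))
        se_clust = np.sqrt(np.diag(clustered.probit.cov))
        ratio = se_clust / se_plain
        assert (ratio > 0.7).all() and (ratio < 1.4).all()


class TestSensitivity:
    def test_all_alive_equals_mortality_free_fit(self, model_panel):
        params, panel = model_panel
        alive = panel[~panel["died_within_5y"]]
        spec_nm = DesignSpec(blocks=params.design.blocks, include_mortality=False)
        direct = fit_two_part(alive, spec_nm, compare=False)
        fit, _ = afcost.fit_sensitivity(alive, "alive", params.design)
        pd.testing.assert_series_equal(direct.probit.params, fit.probit.params)
        pd.testing.assert_series_equal(direct.gamma.params, fit.gamma.params)

    def test_empty_stratum_rejected(self, model_panel):
        params, panel = model_panel
        alive = panel[~panel["died_within_5y"]]
        with pytest.raises(ValueError, match="empty stratum"):
            afcost.fit_sensitivity(alive, "dead", params.design)

    def test_dead_stratum_costlier_by_construction(self, model_panel):
        # the generating gamma coefficient for decedents is strongly positive
        params, panel = model_panel
        _, m_alive = afcost.fit_sensitivity(panel, "alive", params.design)
        _, m_dead = afcost.fit_sensitivity(panel, "dead", params.design)
        assert m_dead > m_alive

    def test_invalid_status_rejected(self, model_panel):
        _, panel = model_panel
        with pytest.raises(ValueError, match="status"):
            afcost.fit_sensitivity(panel, "zombie")
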