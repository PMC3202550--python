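"""Hierarchical mortality model: standardization, likelihood, MCMC, DIC."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import expit

import beechmort as bm
from beechmort.hier_model import MCMCSettings, _pointwise_loglik


class TestStandardize:
    def test_three_point_example(self):
        var = bm.standardize([1.0, 2.0, 3.0])
        assert np.allclose(var.values, [-0.5, 0.0, 0.5])

    def test_standardized_sample_has_mean_zero_sd_half(self):
        rng = np.random.default_rng(0)
        var = bm.standardize(rng.gamma(2.0, 3.0, size=500))
        assert var.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert var.values.std(ddof=1) == pytest.approx(0.5, rel=1e-12)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        first = bm.standardize(rng.normal(size=100))
        second = bm.standardize(first.values)
        assert np.allclose(first.values, second.values)

    def test_back_transform_inverts(self):
        raw = np.array([3.0, 7.0, 11.0, 20.0])
        var = bm.standardize(raw)
        assert np.allclose(var.back_transform(var.values), raw)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            bm.standardize([2.0, 2.0, 2.0])


class TestLinearPredictorAndSurvival:
    def test_zero_coefficients_give_even_odds(self):
        x = np.zeros((4, 2))
        k = bm.linear_predictor([0.0, 0.0, 0.0], x)
        assert np.allclose(expit(k), 0.5)

    def test_intercept_only_inverse_logit(self):
        k = bm.linear_predictor([-4.6, 0.0], np.zeros((1, 1)))
        assert expit(k[0]) == pytest.approx(0.0099518, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bm.linear_predictor([0.0, 1.0], np.zeros((3, 2)))

    def test_interaction_column_is_product_of_main_effects(self, fitted_small_model):
        data, _ = fitted_small_model
        x = data.design.matrix
        assert np.allclose(x[:, 2], x[:, 0] * x[:, 1])

    @pytest.mark.parametrize(
        "m, t, expected", [(0.0, 9, 1.0), (0.5, 1, 0.5), (0.022, 9, 0.978**9)]
    )
    def test_survival_closed_forms(self, m, t, expected):
        assert bm.survival_probability(m, t) == pytest.approx(expected, rel=1e-12)

    def test_survival_monotone_in_rate_and_time(self):
        m = np.linspace(0.01, 0.5, 20)
        s = bm.survival_probability(m, 10)
        assert np.all(np.diff(s) < 0)
        assert bm.survival_probability(0.1, 5) > bm.survival_probability(0.1, 6)


class TestLogLikelihood:
    def test_single_survivor_contribution(self):
        # S = 0.8 over the period, tree survived -> log 0.8
        k = np.array([math.log((1 - 0.8 ** (1 / 9)) / (0.8 ** (1 / 9)))])
        ll = _pointwise_loglik(k, np.array([False]), 9.0)
        assert ll[0] == pytest.approx(math.log(0.8), rel=1e-10)

    def test_matches_naive_product_oracle(self, fitted_small_model):
        data, _ = fitted_small_model
        rng = np.random.default_rng(4)
        idx = rng.choice(data.n_trees, size=50, replace=False)
        beta = np.array([-3.5, -0.5, 1.0, 0.2])
        alpha = rng.normal(0, 0.5, data.n_plots)
        # oracle: per-tree survival probability product, then log
        log_prob = 0.0
        for i in idx:
            k = beta[0] + data.design.matrix[i] @ beta[1:] + alpha[data.plot_index[i]]
            m = 1.0 / (1.0 + math.exp(-k))
            s = (1.0 - m) ** data.t_years
            log_prob += math.log(s if data.y[i] == 0 else 1.0 - s)
        k_all = bm.linear_predictor(beta, data.design.matrix, alpha[data.plot_index])
        mine = _pointwise_loglik(k_all, data.y.astype(bool), data.t_years)[idx].sum()
        assert mine == pytest.approx(log_prob, rel=1e-10)

    def test_finite_at_extreme_predictors(self):
        k = np.array([-800.0, 800.0])
        ll = _pointwise_loglik(k, np.array([True, False]), 9.0)
        assert np.isfinite(ll).all()


class TestBuildDesign:
    def test_sample_restricted_to_focal_small_trees(self, census_history, desk_scenario):
        spec = bm.MortalityModelSpec("small", desk_scenario.periods[0], "BAL")
        data = bm.build_design(census_history, spec)
        by_id = {r.tree_id: r for r in census_history}
        for tid in data.tree_ids[:200]:
            rec = by_id[tid]
            assert bm.is_focal_eligible(rec.subplot_row, rec.subplot_col)
            assert rec.is_alive("c0") and rec.diameter_at("c0") < 200.0

    def test_ba_and_bal_never_share_a_design(self, desk_scenario):
        spec = bm.MortalityModelSpec("small", desk_scenario.periods[0], "BAL", True)
        assert spec.covariate_names == ("D", "BAL", "D:BAL")

    def test_invalid_size_class_rejected(self, desk_scenario):
        with pytest.raises(ValueError):
            bm.MortalityModelSpec("medium", desk_scenario.periods[0], "BAL")


class TestMCMC:
    def test_posterior_summaries_are_ordered(self, fitted_small_model):
        _, result = fitted_small_model
        table = result.summary()
        assert (table["q2.5"] <= table["mean"]).all()
        assert (table["mean"] <= table["q97.5"]).all()
        assert (result.pooled_sigma >= 0).all()

    def test_chains_converge_on_desk_problem(self, fitted_small_model):
        _, result = fitted_small_model
        assert result.converged
        assert all(v < 1.05 for v in result.rhat.values())

    def test_zero_death_dataset_pushes_intercept_down_without_crashing(self):
        sc = bm.SyntheticScenario(
            n_plots=12, stems_per_subplot_mean=2.0, seed=6,
            coefficients=(-30.0, 0.0, 0.0, 0.0), plot_effect_sd=0.1,
            landslide=bm.LandslideRegime(enabled=False),
        )
        records = bm.simulate_history(sc)
        spec = bm.MortalityModelSpec("small", sc.periods[0], "BAL")
        data = bm.build_design(records, spec)
        assert data.y.sum() == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = bm.fit_mcmc(
                data, MCMCSettings(n_chains=2, burn_in=500, draws=500, seed=0)
            )
        assert result.posterior_mean_beta()[0] < -4.0

    def test_limit_case_matches_ml_logistic_regression(self):
        # one-year interval and no plot effect: the model reduces to plain
        # logistic regression of the death indicator on the covariates
        import statsmodels.api as sm

        period = bm.CensusPeriod("P", "c0", "c1", 1)
        sc = bm.SyntheticScenario(
            n_plots=120, stems_per_subplot_mean=2.5, seed=13,
            coefficients=(-1.2, 0.8, 0.6, 0.0), plot_effect_sd=0.0,
            periods=(period,), landslide=bm.LandslideRegime(enabled=False),
        )
        records = bm.simulate_history(sc)
        spec = bm.MortalityModelSpec("small", period, "BAL")
        data = bm.build_design(records, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = bm.fit_mcmc(
                data,
                MCMCSettings(n_chains=3, burn_in=1500, draws=3000, seed=2,
                             random_effects=False),
            )
        mle = sm.Logit(data.y, sm.add_constant(data.design.matrix)).fit(disp=0)
        assert np.allclose(result.posterior_mean_beta(), mle.params, atol=0.1)

    def test_empty_data_rejected(self, fitted_small_model):
        data, _ = fitted_small_model
        import dataclasses

        empty = dataclasses.replace(
            data,
            y=np.zeros(0, dtype=np.int8),
            plot_index=np.zeros(0, dtype=int),
            tree_ids=(),
        )
        with pytest.raises(ValueError):
            bm.fit_mcmc(empty)


class TestDIC:
    def test_degenerate_posterior_has_zero_effective_parameters(self, fitted_small_model):
        data, result = fitted_small_model
        import copy

        frozen = copy.copy(result)
        beta_hat = result.posterior_mean_beta()
        alpha_hat = result.posterior_mean_alpha()
        shape = result.beta_draws.shape
        frozen.beta_draws = np.broadcast_to(beta_hat, shape).copy()
        frozen.alpha_draws = np.broadcast_to(alpha_hat, result.alpha_draws.shape).copy()
        dev = -2.0 * bm.log_likelihood(beta_hat, alpha_hat, data)
        frozen.deviance_draws = np.full(result.deviance_draws.shape, dev)
        dic = bm.compute_dic(frozen, data)
        assert dic.p_d == pytest.approx(0.0, abs=1e-8)
        assert dic.dic == pytest.approx(dic.dbar, abs=1e-8)

    def test_dic_identity_holds(self, fitted_small_model):
        _, result = fitted_small_model
        assert result.dic.p_d == pytest.approx(result.dic.dbar - result.dic.dhat)
        assert result.dic.dic == pytest.approx(result.dic.dbar + result.dic.p_d)
        assert result.dic.p_d > 0
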