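import numpy as np
import pytest
from scipy import stats

from scidcea import (
    ParameterDistribution,
    ParameterSet,
    fit_distribution,
    one_way,
    run_psa,
    tornado,
)
from scidcea.sensitivity import PSA_DEFAULT_VARIED, UniformSampler


class TestFitDistribution:
    def test_gamma_matches_mean_within_one_percent(self):
        d = ParameterDistribution(
            name="hsct_cost_early", family="gamma",
            expected=119_282.0, low=119_282.0 * 0.9, high=119_282.0 * 1.1,
        )
        s = fit_distribution(d)
        rng = np.random.default_rng(0)
        draws = s.sample(rng, size=10_000)
        assert np.mean(draws) == pytest.approx(119_282.0, rel=0.01)
        # +/-10% read as a central 95% interval -> SD ~ 5.1% of the mean
        assert np.std(draws) == pytest.approx(0.051 * 119_282.0, rel=0.1)

    def test_beta_support_and_moments(self):
        d = ParameterDistribution(
            name="incidence", family="beta", expected=2e-5, low=1.2e-5, high=2.5e-5
        )
        s = fit_distribution(d)
        rng = np.random.default_rng(1)
        draws = s.sample(rng, size=20_000)
        assert np.all((draws > 0) & (draws < 1))
        assert np.mean(draws) == pytest.approx(2e-5, rel=0.02)
        # matched central interval should sit near the published bounds
        q = stats.beta.ppf([0.025, 0.975], s.a, s.b)
        assert q[0] == pytest.approx(1.2e-5, rel=0.35)
        assert q[1] == pytest.approx(2.5e-5, rel=0.35)

    def test_fixed_is_constant(self):
        s = fit_distribution(
            ParameterDistribution(name="x", family="fixed", expected=3.0)
        )
        rng = np.random.default_rng(2)
        assert s.sample(rng) == 3.0
        assert np.all(s.sample(rng, size=5) == 3.0)

    def test_infeasible_beta_falls_back_to_uniform(self, caplog):
        d = ParameterDistribution(
            name="degenerate", family="beta", expected=0.0, low=0.0, high=0.01
        )
        with caplog.at_level("WARNING"):
            s = fit_distribution(d)
        assert isinstance(s, UniformSampler)
        assert "uniform" in caplog.text

    def test_missing_bounds_rejected(self):
        d = ParameterDistribution(name="x", family="gamma", expected=1.0)
        with pytest.raises(ValueError, match="bounds"):
            fit_distribution(d)


class TestOneWay:
    def test_degenerate_bounds_give_zero_span(self, params, life_table):
        e = one_way(params, life_table, "incidence", 2e-5, 2e-5,
                    horizon_years=5)
        assert e.span == 0.0

    def test_incidence_bounds_published(self, params, life_table):
        e = one_way(params, life_table, "incidence", horizon_years=5)
        assert (e.low, e.high) == (1.2e-5, 2.5e-5)
        assert e.icer_low > e.icer_high  # rarer disease -> higher ICER
        assert e.span > 0

    def test_discount_rate_direction_at_long_horizon(self, params, life_table):
        # health gains accrue later than costs, so heavier discounting
        # worsens the ICER over 60 years
        e = one_way(params, life_table, "discount_rate", 0.0, 0.05,
                    horizon_years=60)
        assert e.icer_low < e.icer_high

    def test_unknown_parameter_and_bad_bounds(self, params, life_table):
        with pytest.raises(ValueError, match="bounds"):
            one_way(params, life_table, "utility_poor")
        with pytest.raises(ValueError, match="low"):
            one_way(params, life_table, "incidence", 3e-5, 1e-5)

    def test_tornado_sorted_by_span(self, params, life_table):
        df = tornado(params, life_table, horizon_years=5,
                     names=["incidence", "screen_cost", "false_positive_rate"])
        assert list(df["span"]) == sorted(df["span"], reverse=True)
        assert set(df["parameter"]) == {
            "incidence", "screen_cost", "false_positive_rate"
        }


class TestPSA:
    def test_seed_reproducibility_bitwise(self, params, life_table):
        a = run_psa(params, life_table, n_iter=25, seed=11, horizon_years=5)
        b = run_psa(params, life_table, n_iter=25, seed=11, horizon_years=5)
        c = run_psa(params, life_table, n_iter=25, seed=12, horizon_years=5)
        assert a.iterations.equals(b.iterations)
        assert not a.iterations.equals(c.iterations)

    def test_ceac_monotone_in_wtp(self, params, life_table):
        res = run_psa(params, life_table, n_iter=60, seed=3, horizon_years=5)
        assert (res.ceac["p_cost_effective"].diff().dropna() >= 0).all()
        assert res.ceac["p_cost_effective"].between(0, 1).all()

    def test_degenerate_distributions_reproduce_base_case(self, params,
                                                          life_table,
                                                          cohorts_5y):
        from scidcea import expected_outcome_no_screen, expected_outcome_screen

        res = run_psa(params, life_table, n_iter=5, seed=0, horizon_years=5,
                      varied=[])
        screen = expected_outcome_screen(params, cohorts_5y["early"],
                                         cohorts_5y["late"])
        no_screen = expected_outcome_no_screen(params, cohorts_5y["early"],
                                               cohorts_5y["late"])
        base = screen.cost - no_screen.cost
        assert np.allclose(res.iterations["delta_cost"], base)
        assert res.iterations["delta_cost"].nunique() == 1

    def test_mean_near_base_case_for_mean_preserving_draws(self, params,
                                                           life_table,
                                                           cohorts_5y):
        # cost gammas are fitted with mean == expected value, so the PSA
        # mean increment should sit within Monte-Carlo error of the base
        from scidcea import expected_outcome_no_screen, expected_outcome_screen

        res = run_psa(params, life_table, n_iter=120, seed=5, horizon_years=5,
                      varied=["screen_cost", "hsct_cost_early",
                              "hsct_cost_late"])
        screen = expected_outcome_screen(params, cohorts_5y["early"],
                                         cohorts_5y["late"])
        no_screen = expected_outcome_no_screen(params, cohorts_5y["early"],
                                               cohorts_5y["late"])
        base = screen.cost - no_screen.cost
        dc = res.iterations["delta_cost"]
        se = dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(dc.mean() - base) < 3 * se

    def test_default_varied_set_is_screening_costs_and_probabilities(self):
        assert "incidence" in PSA_DEFAULT_VARIED
        assert "surv5_late" not in PSA_DEFAULT_VARIED
        assert "hsct_cost_late" not in PSA_DEFAULT_VARIED

    def test_varied_all_samples_survival_too(self, params, life_table):
        res = run_psa(params, life_table, n_iter=8, seed=0, horizon_years=5,
                      varied="all")
        assert "par_surv5_late" in res.iterations.columns
        assert res.iterations["par_surv5_late"].nunique() == 8
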