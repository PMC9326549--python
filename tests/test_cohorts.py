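import numpy as np
import pytest

from scidcea import (
    HealthState,
    ParameterSet,
    build_early_model,
    build_late_model,
    run_cohort,
    run_strategy,
    treatment_cea,
)

DEAD = int(HealthState.DEAD)


def _survivor_share(trace, cycle, state):
    occ = trace.occupancy[cycle]
    alive = occ[: DEAD].sum()
    return occ[int(state)] / alive


class TestModelStructure:
    @pytest.mark.parametrize("builder", [build_early_model, build_late_model])
    def test_transition_rows_stochastic_over_60_years(self, builder, params, life_table):
        model = builder(params, life_table)
        model.validate(horizon_cycles=240)  # raises on any defect

    def test_early_pre_treatment_mortality(self, cohorts_5y, params):
        trace = cohorts_5y["early"].trace
        assert trace.occupancy[1, DEAD] == pytest.approx(
            1 - params.p_survive_to_tx_early, abs=1e-12
        )

    def test_early_post_hsct_split(self, cohorts_5y):
        trace = cohorts_5y["early"].trace
        assert _survivor_share(trace, 2, HealthState.WELL) == pytest.approx(0.80)
        assert _survivor_share(trace, 2, HealthState.MODERATE) == pytest.approx(0.15)

    def test_late_path_through_infection(self, cohorts_5y, params):
        trace = cohorts_5y["late"].trace
        # everyone spends the second cycle in SCID Poor before transplant
        assert trace.occupancy[1, int(HealthState.POOR)] == pytest.approx(1.0)
        assert trace.occupancy[2, DEAD] >= 1 - params.p_survive_to_tx_late - 1e-12

    def test_late_post_hsct_split(self, cohorts_5y):
        trace = cohorts_5y["late"].trace
        assert _survivor_share(trace, 3, HealthState.WELL) == pytest.approx(0.50)
        assert _survivor_share(trace, 3, HealthState.POOR) == pytest.approx(0.20)

    def test_no_deaths_in_degenerate_limit(self, zero_mortality):
        p = ParameterSet(p_survive_to_tx_late=1.0, surv5_late=1.0)
        res = run_strategy(p, zero_mortality, "late", 5)
        assert res.trace.occupancy[:, DEAD].max() == 0.0

    def test_horizon_too_short(self, params, life_table):
        with pytest.raises(ValueError, match="2 cycles"):
            run_strategy(params, life_table, "early", 0.25)


class TestSurvivalValidation:
    """The treated cohorts' survival must reproduce the published inputs."""

    @pytest.mark.parametrize(
        "arm,expected",
        [("early", 0.9423 * 0.94), ("late", 0.78 * 0.82)],
    )
    def test_five_year_window_reading_is_exact(self, arm, expected, params,
                                               life_table):
        res = run_strategy(params, life_table, arm, 5,
                           survival_basis="five-year-window",
                           limit_excess_to_5_years=True)
        surv = 1 - res.trace.occupancy[20, DEAD]
        assert surv == pytest.approx(expected, rel=5e-3)

    @pytest.mark.parametrize("arm,p_tx,s", [("early", 0.9423, 0.94),
                                            ("late", 0.78, 0.82)])
    def test_annual_rate_reading_consistency(self, arm, p_tx, s, params,
                                             life_table):
        # under the annual reading, survivors decay by s per year after
        # transplantation (life-table floor negligible at these ages)
        res = run_strategy(params, life_table, arm, 5)
        tx_cycle = 1 if arm == "early" else 2
        surv = 1 - res.trace.occupancy[20, DEAD]
        assert surv == pytest.approx(p_tx * s ** ((20 - tx_cycle) / 4), rel=1e-6)


class TestRewardBookkeeping:
    def test_equalised_morbidity_leaves_survival_driven_qaly_gap(self, life_table):
        # with Moderate/Poor collapsed onto Well (same utility, same cost),
        # each arm's QALYs equal utility x discounted life-years, so the
        # QALY gap is purely a survival difference
        p = ParameterSet(
            utility_moderate=0.95, utility_poor=0.95, utility_hsct=0.95,
            utility_pre_symptomatic=0.95,
            annual_cost_moderate=34.0, annual_cost_poor=34.0,
        )
        for arm in ("early", "late"):
            res = run_strategy(p, life_table, arm, 5)
            occ = res.trace.occupancy
            alive = occ[:, :DEAD].sum(axis=1)
            d = (1.03) ** (-0.25 * np.arange(20))
            ly = float((0.5 * (alive[:-1] + alive[1:]) * 0.25 * d).sum())
            assert res.total_qaly == pytest.approx(0.95 * ly, rel=1e-12)

    def test_early_gains_qalys_at_all_horizons(self, params, life_table):
        for horizon in (2, 5, 20, 60):
            e = run_strategy(params, life_table, "early", horizon)
            l = run_strategy(params, life_table, "late", horizon)
            assert e.total_qaly > l.total_qaly

    def test_end_of_life_cost_charged_only_on_morbid_deaths(self, zero_mortality):
        # send every transplant survivor to Well: no Moderate/Poor deaths,
        # so removing the end-of-life cost must not change the total
        p = ParameterSet(post_hsct_split_early=(1.0, 0.0, 0.0))
        base = run_strategy(p, zero_mortality, "early", 5)
        no_eol = run_strategy(
            ParameterSet(post_hsct_split_early=(1.0, 0.0, 0.0), end_of_life_cost=0.0),
            zero_mortality, "early", 5,
        )
        assert base.total_cost == pytest.approx(no_eol.total_cost, rel=1e-12)

    def test_pre_treatment_death_cost(self, params, zero_mortality):
        # the only cost difference between death_pre_hsct_cost on and off is
        # the discounted flow of pre-treatment deaths
        p0 = ParameterSet(death_pre_hsct_cost=0.0)
        on = run_strategy(params, zero_mortality, "early", 5)
        off = run_strategy(p0, zero_mortality, "early", 5)
        expected = (1 - params.p_survive_to_tx_early) * params.death_pre_hsct_cost
        expected *= 1.03 ** -0.25
        assert on.total_cost - off.total_cost == pytest.approx(expected, rel=1e-12)


class TestTreatmentCEA:
    def test_early_dominates_at_both_horizons(self, params, life_table):
        for horizon in (5, 60):
            early, late, cea = treatment_cea(params, life_table, horizon)
            assert cea.dominance == "dominant"
            assert cea.delta_cost < 0 and cea.delta_qaly > 0

    def test_late_arm_five_year_qaly_near_published(self, cohorts_5y):
        # "only ... 1.97 QALYs" for the late-treated patient over 5 years
        assert cohorts_5y["late"].total_qaly == pytest.approx(1.97, rel=0.05)

    def test_identical_arms_have_zero_increment(self, cohorts_5y):
        from scidcea import StrategyOutcome, icer

        e = cohorts_5y["early"]
        same = icer(
            StrategyOutcome("a", e.total_cost, e.total_qaly),
            StrategyOutcome("b", e.total_cost, e.total_qaly),
        )
        assert same.delta_cost == 0.0 and same.delta_qaly == 0.0
        assert same.icer is None
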