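"""Cohort engine: annualization, savings, arm accounting, and oracles."""

import logging
from dataclasses import replace

import numpy as np
import pytest

from anemia_cea import (ValidationError, annual_quality_decrement, annual_savings,
                        annualize_monthly_rate, default_bundle, run_arm,
                        run_base_case, toy_scenario)
from anemia_cea.engine import ArmSpec, build_arm_specs
from anemia_cea.survival import SurvivalCurve


def constant_hazard_curve(p, T):
    q = np.full(T, 1.0 - p)
    return SurvivalCurve(survival=np.concatenate([[1.0], np.cumprod(1 - q)]),
                         annual_mortality=q)


class TestAnnualization:
    def test_monthly_rate_times_rr_times_twelve(self):
        assert annualize_monthly_rate(0.0490, 0.41) == pytest.approx(0.24108)

    def test_zero_rate(self):
        assert annualize_monthly_rate(0.0, 0.9) == 0.0

    def test_cap_at_one_patient_year_logs_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="anemia_cea.engine"):
            assert annualize_monthly_rate(0.1079, 1.0) == 1.0
        assert any("capped" in r.message for r in caplog.records)

    def test_quality_decrement_values(self):
        assert annual_quality_decrement(0.0490, 1.0, 0.03) == pytest.approx(0.01764)
        assert annual_quality_decrement(0.0490, 0.41, 0.03) == pytest.approx(0.0072324)
        assert annual_quality_decrement(0.0490, 0.41, 0.03, enabled=False) == 0.0


class TestAnnualSavings:
    def test_hospitalization_component(self, bundle):
        total, parts = annual_savings(bundle.tiers[1], bundle.hospitalization,
                                      bundle.hypertension, bundle.economics)
        assert parts["hospitalization"] == pytest.approx(0.126 * 4210.59)

    def test_esa_free_only_mode(self, bundle):
        total, parts = annual_savings(bundle.tiers[1], bundle.hospitalization,
                                      bundle.hypertension, bundle.economics,
                                      mode="esa_free_only")
        assert parts["esa"] == pytest.approx(0.186 * 5200.0)

    def test_full_mode_adds_avoided_inappropriate_use(self, bundle):
        total, parts = annual_savings(bundle.tiers[1], bundle.hospitalization,
                                      bundle.hypertension, bundle.economics)
        expected = 0.1079 * (1 - 0.37) * 12 * 5200.0 + 0.186 * 5200.0
        assert parts["esa"] == pytest.approx(expected)

    def test_null_effects_give_zero(self, bundle):
        tier = replace(bundle.tiers[1], rr_inappropriate_esa=1.0,
                       rr_severe_anemia=1.0, diff_esa_free_months=0.0)
        hosp = replace(bundle.hospitalization, arr=0.0)
        total, _ = annual_savings(tier, hosp, bundle.hypertension, bundle.economics)
        assert total == 0.0

    def test_breakdown_sums_to_total(self, bundle):
        total, parts = annual_savings(bundle.tiers[2], bundle.hospitalization,
                                      bundle.hypertension, bundle.economics)
        assert total == pytest.approx(sum(parts.values()), abs=1e-9)


class TestRunArm:
    def test_life_years_identical_across_arms(self, base_result):
        assert base_result.acm.life_years == pytest.approx(
            base_result.no_acm.life_years, abs=1e-12)

    def test_totals_equal_trace_sums(self, base_result):
        for arm in (base_result.acm, base_result.no_acm):
            assert arm.lifetime_cost == pytest.approx(
                sum(r.cost_discounted for r in arm.trace), abs=1e-6)
            assert arm.qalys == pytest.approx(
                sum(r.qaly_discounted for r in arm.trace), abs=1e-9)

    def test_cycle_breakdown_sums_to_cycle_cost(self, base_result):
        for rec in base_result.acm.trace:
            assert rec.cost == pytest.approx(sum(rec.cost_breakdown.values()), abs=1e-9)

    def test_null_effects_make_arms_identical(self, life_table):
        b = default_bundle()
        tier = replace(b.tiers[1], rr_inappropriate_esa=1.0, rr_severe_anemia=1.0,
                       diff_esa_free_months=0.0)
        b = replace(b, tiers={**b.tiers, 1: tier},
                    hospitalization=replace(b.hospitalization, arr=0.0))
        res = run_base_case(b, life_table)
        assert res.acm.lifetime_cost == pytest.approx(res.no_acm.lifetime_cost, abs=1e-9)
        assert res.acm.qalys == pytest.approx(res.no_acm.qalys, abs=1e-9)

    def test_cost_linear_in_annual_hd_cost(self, life_table):
        b = default_bundle()
        b2 = b.replace_param("annual_hd_cost_2017", 2 * 54604.0)
        r1 = run_base_case(b, life_table)
        r2 = run_base_case(b2, life_table)
        hd1 = sum(rec.cost_breakdown["hd_base"] for rec in r1.no_acm.trace)
        hd2 = sum(rec.cost_breakdown["hd_base"] for rec in r2.no_acm.trace)
        assert hd2 == pytest.approx(2 * hd1, rel=1e-12)

    def test_qalys_linear_in_utility_when_qol_effect_off(self, life_table):
        b = default_bundle()
        b = replace(b, scenario=replace(b.scenario, qol_effect_enabled=False))
        r1 = run_base_case(b, life_table)
        r2 = run_base_case(b.replace_param("utility_hd", 0.345), life_table)
        assert r2.no_acm.qalys == pytest.approx(r1.no_acm.qalys / 2, rel=1e-12)

    def test_one_year_scenario_differs_only_in_first_cycle(self, life_table):
        b = default_bundle()
        b = replace(b, scenario=replace(b.scenario, acm_effect_duration="first_year_only"))
        res = run_base_case(b, life_table)
        for rec_a, rec_n in zip(res.acm.trace[1:], res.no_acm.trace[1:]):
            assert rec_a.cost == pytest.approx(rec_n.cost, abs=1e-12)
            assert rec_a.qaly == pytest.approx(rec_n.qaly, abs=1e-12)
        assert res.acm.trace[0].cost < res.no_acm.trace[0].cost

    def test_horizon_mismatch_rejected(self, bundle, life_table):
        curve = constant_hazard_curve(0.9, 10)
        spec = ArmSpec("acm", bundle.tiers[1], np.ones(5, dtype=bool))
        with pytest.raises(ValidationError):
            run_arm(spec, curve, bundle)


class TestToyOracle:
    """Engine totals equal the constant-hazard closed forms to 1e-9."""

    @pytest.mark.parametrize("p", [1.0, 0.9, 0.5, 0.2])
    @pytest.mark.parametrize("r", [0.0, 0.03, 0.1])
    @pytest.mark.parametrize("T", [1, 7, 40])
    def test_life_years_match_closed_form(self, p, r, T):
        from anemia_cea.survival import discounted_life_years
        toy = toy_scenario(p, r=r, T=T)
        curve = constant_hazard_curve(p, T)
        assert discounted_life_years(curve, r) == pytest.approx(
            toy.expected_life_years, abs=1e-9)

    @pytest.mark.parametrize("timing", ["midcycle", "endcycle"])
    def test_arm_cost_and_qalys_match_closed_form(self, timing):
        p, r, T, u, c = 0.8, 0.05, 25, 0.7, 1000.0
        b = default_bundle()
        b = replace(b,
                    economics=replace(b.economics, utility_hd=u,
                                      annual_hd_cost_2017=c,
                                      cpi_factor_2017_to_2024=1.0,
                                      discount_rate=r),
                    scenario=replace(b.scenario, qol_effect_enabled=False),
                    settings=replace(b.settings, discount_timing=timing))
        curve = constant_hazard_curve(p, T)
        spec = ArmSpec("no_acm", b.tiers[1], np.zeros(T, dtype=bool))
        res = run_arm(spec, curve, b)
        toy = toy_scenario(p, u=u, c=c, r=r, T=T, discount_timing=timing)
        assert res.life_years == pytest.approx(toy.expected_life_years, abs=1e-9)
        assert res.qalys == pytest.approx(toy.expected_qalys, abs=1e-9)
        assert res.lifetime_cost == pytest.approx(toy.expected_cost, abs=1e-9)

    def test_immortal_cohort(self):
        toy = toy_scenario(1.0, u=1.0, c=0.0, r=0.0, T=10)
        assert toy.expected_life_years == pytest.approx(10.0)

    def test_geometric_limit(self):
        toy = toy_scenario(0.5, r=0.0, T=200)
        assert toy.expected_life_years == pytest.approx(1.5, abs=1e-12)


class TestMicrosimulationOracle:
    def test_individual_simulation_matches_cohort(self, bundle, base_result):
        """Seeded patient-level simulation reproduces cohort LY and QALYs.

        N = 100,000 patients face the same annual death probabilities;
        decedents accrue half a cycle.  Cohort expectations must lie within
        3 Monte-Carlo standard errors of the simulated means.
        """
        curve = base_result.curve
        q = curve.annual_mortality
        T = len(q)
        rng = np.random.default_rng(20240901)
        N = 100_000
        alive = np.ones(N, dtype=bool)
        d = (1.0 + 0.03) ** -(np.arange(1, T + 1) - 0.5)
        ly = np.zeros(N)
        qaly = np.zeros(N)
        u_eff = 0.69 - 0.01764  # comparator arm effective utility
        for t in range(T):
            dies = alive & (rng.random(N) < q[t])
            credit = np.where(dies, 0.5, 1.0) * alive * d[t]
            ly += credit
            qaly += credit * u_eff
            alive &= ~dies
        for sim, cohort in ((ly, base_result.no_acm.life_years),
                            (qaly, base_result.no_acm.qalys)):
            se = sim.std(ddof=1) / np.sqrt(N)
            assert abs(sim.mean() - cohort) < 3 * se


class TestArmSpecs:
    def test_lifetime_scenario_all_active(self, bundle):
        acm, no_acm = build_arm_specs(bundle, 33)
        assert acm.effects_active_per_cycle.all()
        assert not no_acm.effects_active_per_cycle.any()

    def test_first_year_only(self, bundle):
        b = replace(bundle, scenario=replace(bundle.scenario,
                                             acm_effect_duration="first_year_only"))
        acm, _ = build_arm_specs(b, 33)
        assert acm.effects_active_per_cycle[0]
        assert not acm.effects_active_per_cycle[1:].any()
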