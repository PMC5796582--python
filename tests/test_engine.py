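"""Transition matrices, state costs, and the cohort simulation."""

import numpy as np
import pytest

import t2dcea as t
from t2dcea import HealthState
from t2dcea.errors import ContractError, InfeasibleParametersError


class TestTransitionMatrix:
    def test_su_dual_row_band_60_70(self, base_params):
        """DUAL-state death = band probability x hazard ratio for SU."""
        M = t.build_transition_matrix(t.SU, base_params, 0)
        assert M[1, 3] == pytest.approx(0.021 * 1.85)       # 0.03885
        assert M[1, 1] == pytest.approx(1 - 0.053 - 0.03885)  # 0.90815
        assert M[1, 2] == 0.053

    def test_dpp4i_mono_row_band_60_70(self, base_params):
        M = t.build_transition_matrix(t.DPP4I, base_params, 0)
        assert M[0].tolist() == pytest.approx([0.933, 0.046, 0.0, 0.021])

    @pytest.mark.parametrize("pathway", [t.SU, t.DPP4I])
    @pytest.mark.parametrize("band", [0, 1, 2])
    def test_rows_stochastic_and_structure(self, base_params, pathway, band):
        M = t.build_transition_matrix(pathway, base_params, band)
        assert M.sum(axis=1) == pytest.approx([1, 1, 1, 1], abs=1e-12)
        assert (M >= 0).all() and (M <= 1).all()
        assert M[3].tolist() == [0, 0, 0, 1]          # death absorbing
        assert M[1, 0] == 0 and M[2, 0] == 0 and M[2, 1] == 0  # no backward moves

    def test_infeasible_row_raises(self, base_params):
        p = t.set_parameter(base_params, "pathways.su.dual_state_death_hazard_ratio", 15.0)
        with pytest.raises(InfeasibleParametersError):
            t.build_transition_matrix(t.SU, p, 2)  # 0.107 * 15 + 0.053 > 1


class TestStateCosts:
    def test_mono(self, base_params):
        c = t.state_annual_cost(HealthState.MONO, t.DPP4I, base_params)
        assert c == pytest.approx(24 + 0.004 * 18627 + 0.003 * 14118 + 0.003 * 7939)
        assert round(c) == 165

    def test_dual_dpp4i(self, base_params):
        c = t.state_annual_cost(HealthState.DUAL, t.DPP4I, base_params)
        assert round(c) == 3854

    def test_dual_su_components(self, base_params):
        c = t.state_annual_cost(HealthState.DUAL, t.SU, base_params)
        cv = 0.020 * 14118 + 0.020 * 7939
        hypo = 0.016 * 146 + 0.009 * 199
        assert c == pytest.approx(40 + hypo + cv)
        assert round(cv) == 441

    def test_triple_same_events_both_arms(self, base_params):
        c_d = t.state_annual_cost(HealthState.TRIPLE, t.DPP4I, base_params)
        c_s = t.state_annual_cost(HealthState.TRIPLE, t.SU, base_params)
        # regimens differ only by the second-line agent price
        assert c_d - c_s == pytest.approx(3500 - 16)
        assert round(c_s) == 4054

    def test_zero_event_rates_leave_drug_cost(self, base_params):
        p = base_params.copy()
        for state in p.event_rates_by_state.values():
            for f in ("severe_hypoglycemia", "hypoglycemia_medical_assistance",
                      "myocardial_infarction", "heart_failure", "stroke"):
                setattr(state, f, 0.0)
        assert t.state_annual_cost(HealthState.MONO, t.DPP4I, p) == 24
        assert t.state_annual_cost(HealthState.DUAL, t.DPP4I, p) == 3524

    def test_death_rejected(self, base_params):
        with pytest.raises(ContractError):
            t.state_annual_cost(HealthState.DEATH, t.SU, base_params)


class TestTransitionCost:
    def test_only_mono_to_dual_under_su(self, base_params):
        c = t.transition_cost(HealthState.MONO, HealthState.DUAL, t.SU, base_params)
        assert c == pytest.approx(0.51 * 289)
        assert t.transition_cost(HealthState.MONO, HealthState.DUAL, t.DPP4I, base_params) == 0
        assert t.transition_cost(HealthState.DUAL, HealthState.TRIPLE, t.SU, base_params) == 0


class TestDiscountFactor:
    def test_values(self):
        assert t.discount_factor(1, 0.03) == pytest.approx(1 / 1.03)
        assert all(t.discount_factor(k, 0.0) == 1.0 for k in range(1, 30))
        with pytest.raises(ContractError):
            t.discount_factor(0, 0.03)


class TestRunCohort:
    def test_probability_conservation(self, base_results):
        for res in base_results.values():
            sums = res.trace.membership.sum(axis=1)
            assert sums == pytest.approx(np.ones(len(sums)), abs=1e-9)

    def test_death_monotone_alive_declines(self, base_results):
        for res in base_results.values():
            death = res.trace.membership[:, HealthState.DEATH]
            assert (np.diff(death) >= -1e-12).all()
            alive = 1 - death
            assert (np.diff(alive) <= 1e-12).all()

    def test_su_pathway_loses_life_years(self, base_results):
        """Hazard ratio 1.85 > 1 costs the SU cohort survival."""
        assert (base_results[t.SU].total_ly_discounted
                < base_results[t.DPP4I].total_ly_discounted)
        assert (base_results[t.SU].total_ly_undiscounted
                < base_results[t.DPP4I].total_ly_undiscounted)

    def test_discounted_below_undiscounted(self, base_results):
        for res in base_results.values():
            assert res.total_ly_discounted < res.total_ly_undiscounted
            assert res.total_cost_discounted < res.total_cost_undiscounted

    def test_zero_discount_matches_undiscounted_exactly(self, base_params):
        p = t.set_parameter(base_params, "discount_rate", 0.0)
        for key in (t.SU, t.DPP4I):
            res = t.run_cohort(key, p)
            assert res.total_ly_discounted == res.total_ly_undiscounted
            assert res.total_cost_discounted == res.total_cost_undiscounted

    def test_totals_decrease_with_discount_rate(self, base_params, base_results):
        p = t.set_parameter(base_params, "discount_rate", 0.06)
        res = t.run_cohort(t.DPP4I, p)
        assert res.total_ly_discounted < base_results[t.DPP4I].total_ly_discounted
        assert res.total_cost_discounted < base_results[t.DPP4I].total_cost_discounted

    def test_certain_death_gives_zero_life_years(self, base_params):
        spec = t.ScenarioSpec(seed=0, certain_death=True)
        p = t.random_scenario(spec)
        res = t.run_cohort(t.SU, p)
        assert res.total_ly_undiscounted == 0.0
        assert res.trace.membership[1, HealthState.DEATH] == 1.0

    def test_geometric_closed_form_oracle(self):
        """Single band, no treatment failure: undiscounted life-years equal
        the geometric sum over survival, sum_{t=1..H} (1-d)^t."""
        d, H = 0.04, 25
        p = t.load_parameters({
            "mortality": {"bands": [
                {"age_low": 60, "age_high": 120, "annual_death_probability": d}]},
            "pathways": {
                "dpp4i": {"failure_rate_mono": 0.0, "failure_rate_dual": 0.0},
                "su": {"failure_rate_mono": 0.0, "failure_rate_dual": 0.0,
                       "dual_state_death_hazard_ratio": 1.0},
            },
            "horizon": H,
        })
        q = 1 - d
        expected = q * (1 - q**H) / (1 - q)
        for key in (t.SU, t.DPP4I):
            res = t.run_cohort(key, p)
            assert res.total_ly_undiscounted == pytest.approx(expected, rel=1e-12)
        # discounted variant: geometric sum in q/(1+r)
        r = p.discount_rate
        qd = q / (1 + r)
        expected_d = qd * (1 - qd**H) / (1 - qd)
        assert t.run_cohort(t.DPP4I, p).total_ly_discounted == pytest.approx(
            expected_d, rel=1e-12)

    def test_banded_survival_geometric_blocks(self, base_params, base_results):
        """Because the DPP-4i arm has equal death probabilities in all alive
        states, its life-years reduce to banded geometric survival sums —
        an independent closed-form check of the engine."""
        r = base_params.discount_rate
        total_u = total_d = 0.0
        surv = 1.0
        for (n, d) in ((10, 0.021), (10, 0.051), (5, 0.107)):
            q = 1 - d
            block_u = surv * q * (1 - q**n) / (1 - q)
            surv_new = surv * q**n
            total_u += block_u
            surv = surv_new
        assert base_results[t.DPP4I].total_ly_undiscounted == pytest.approx(total_u, rel=1e-12)
        # discounted: accumulate cycle by cycle (closed form per band)
        surv, disc, total_d = 1.0, 1.0, 0.0
        cycle = 0
        for (n, d) in ((10, 0.021), (10, 0.051), (5, 0.107)):
            for _ in range(n):
                cycle += 1
                surv *= 1 - d
                total_d += surv / (1 + r) ** cycle
        assert base_results[t.DPP4I].total_ly_discounted == pytest.approx(total_d, rel=1e-12)

    def test_equalized_arms_identical(self, base_params):
        """HR = 1 plus identical dual rates/costs collapses the two pathways."""
        p = base_params.copy()
        p.pathways[t.SU].dual_state_death_hazard_ratio = 1.0
        p.pathways[t.SU].failure_rate_dual = p.pathways[t.DPP4I].failure_rate_dual
        p.pathways[t.SU].weight_gain_transition_cost_applies = False
        p.event_rates_by_state["dual_su"] = p.event_rates_by_state["dual_dpp4i"]
        p.unit_costs.drug_su = p.unit_costs.drug_dpp4i
        a = t.run_cohort(t.SU, p)
        b = t.run_cohort(t.DPP4I, p)
        assert a.total_cost_discounted == pytest.approx(b.total_cost_discounted, rel=1e-12)
        assert a.total_ly_discounted == pytest.approx(b.total_ly_discounted, rel=1e-12)

    def test_pre_accrual_variant_differs_only_in_costs(self, base_params):
        p = t.load_parameters({"cost_accrual": "pre"})
        pre = t.run_cohort(t.DPP4I, p)
        post = t.run_cohort(t.DPP4I, base_params)
        assert pre.total_ly_discounted == post.total_ly_discounted
        assert pre.total_cost_discounted != post.total_cost_discounted

    def test_cv_convergence_with_own_rates_is_identity(self, base_params):
        """Feeding each arm its own CV rates through the duration-split
        machinery must reproduce the plain run."""
        for key, state in ((t.DPP4I, "dual_dpp4i"), (t.SU, "dual_su")):
            er = base_params.event_rates_by_state[state]
            conv = t.CVConvergence(
                myocardial_infarction=er.myocardial_infarction,
                heart_failure=er.heart_failure,
                stroke=er.stroke,
            )
            a = t.run_cohort(key, base_params, cv_convergence=conv)
            b = t.run_cohort(key, base_params)
            assert a.total_cost_discounted == pytest.approx(b.total_cost_discounted, rel=1e-10)
            assert a.total_ly_discounted == pytest.approx(b.total_ly_discounted, rel=1e-12)

    def test_trace_frame_layout(self, base_results):
        df = base_results[t.SU].trace.to_frame()
        assert list(df.columns[:6]) == ["cycle", "age", "mono", "dual", "triple", "death"]
        assert len(df) == 26
        assert df.loc[0, "mono"] == 1.0
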