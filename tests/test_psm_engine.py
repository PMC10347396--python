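"""Partitioned-survival engine: occupancy, accrual, dosing, ICER logic."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmcea import (AEProfile, CostInputs, EconResult, EconomicSettings,
                    ParametricCurve, UtilityInputs, accrue, ae_expected_cost,
                    compute_icer, cycle_drug_cost, discount_factor, run_arm,
                    state_occupancy)
from psmcea.psm_engine import DAYS_PER_MONTH, MissingCostError

LN2 = np.log(2.0)
OS = ParametricCurve("exponential", (LN2 / 16.8,))
PFS = ParametricCurve("exponential", (LN2 / 5.1,))


class TestStateOccupancy:
    def test_entry_state_and_conservation(self):
        tr = state_occupancy(OS, PFS, EconomicSettings())
        assert (tr.pfs[0], tr.pd[0], tr.dead[0]) == (1.0, 0.0, 0.0)
        assert np.allclose(tr.pfs + tr.pd + tr.dead, 1.0, atol=1e-9)
        assert np.all(np.diff(tr.dead) >= -1e-12)
        assert tr.discount[0] == 1.0

    def test_identical_curves_give_zero_pd(self):
        tr = state_occupancy(OS, OS, EconomicSettings())
        assert np.allclose(tr.pd, 0.0, atol=1e-12)
        assert tr.n_clamped == 0

    def test_closed_form_exponential_occupancy(self):
        # at 12 months: PFS = e^{-12*ln2/5.1}, PD = e^{-12*ln2/16.8} - PFS
        tr = state_occupancy(OS, PFS, EconomicSettings())
        s_os = np.exp(-12 * LN2 / 16.8)
        s_pfs = np.exp(-12 * LN2 / 5.1)
        assert tr.pfs[12] == pytest.approx(s_pfs, abs=1e-12)
        assert tr.pd[12] == pytest.approx(s_os - s_pfs, abs=1e-12)
        assert tr.dead[12] == pytest.approx(1 - s_os, abs=1e-12)

    def test_crossing_curves_are_clamped_and_counted(self):
        tr = state_occupancy(PFS, OS, EconomicSettings())  # PFS above OS
        assert np.all(tr.pd >= 0)
        assert tr.n_clamped > 0


class TestDiscountFactor:
    def test_identities(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(12, 0.05) == pytest.approx(1 / 1.05, abs=1e-12)
        assert all(discount_factor(c, 0.0) == 1.0 for c in range(0, 61, 7))
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)


class TestDrugCosts:
    def test_tdxd_whole_vial_administration(self):
        # 5.4 mg/kg x 55 kg = 297 mg -> 3 vials of 100 mg
        c = CostInputs()
        per_admin = 3 * 2431.37
        assert per_admin == pytest.approx(7294.11, abs=1e-9)
        monthly = cycle_drug_cost("tdxd", c)
        assert monthly == pytest.approx(per_admin * DAYS_PER_MONTH / 21.0, abs=1e-9)

    def test_tdxd_exact_mg_billing(self):
        c = replace(CostInputs(), tdxd_wastage="exact")
        monthly = cycle_drug_cost("tdxd", c)
        per_admin = 2.97 * 2431.37
        assert per_admin == pytest.approx(7221.17, abs=0.005)
        assert monthly == pytest.approx(per_admin * DAYS_PER_MONTH / 21.0, abs=1e-9)

    def test_zero_body_weight_zero_cost_exact_policy(self):
        c = replace(CostInputs(), tdxd_wastage="exact", body_weight_kg=0.0)
        assert cycle_drug_cost("tdxd", c) == 0.0

    def test_missing_agent_cost_named_error(self):
        with pytest.raises(MissingCostError, match="eribulin"):
            cycle_drug_cost("chemo", CostInputs())  # eribulin/gemcitabine unset

    def test_chemo_weighted_mix(self, demo_model):
        c = demo_model.costs
        monthly = cycle_drug_cost("chemo", c)
        # independent recomputation of the weighted monthly cost
        expected = 0.0
        for name, w in c.regimen_weights.items():
            a = c.agents[name]
            expected += w * a.per_admin_cost(c.bsa_m2) * a.admins_per_21d * DAYS_PER_MONTH / 21
        assert monthly == pytest.approx(expected, abs=1e-9)
        assert monthly < cycle_drug_cost("tdxd", c)


def test_ae_expected_cost_ten_term_sum():
    """Expected adverse-event cost equals the hand-computed incidence x
    unit-cost sum over the ten grade >=3 events."""
    ae = AEProfile()
    expected_tdxd = (0.137 * 547.50 + 0.081 * 607.06 + 0.051 * 193.50
                     + 0.065 * 104.95 + 0.046 * 39.60 + 0.013 * 39.60
                     + 0.011 * 44.30 + 0.032 * 68.30 + 0.075 * 131.78
                     + 0.024 * 115.40)
    expected_chemo = (0.407 * 547.50 + 0.047 * 607.06 + 0.006 * 193.50
                      + 0.192 * 104.95 + 0.017 * 44.30 + 0.081 * 68.30
                      + 0.047 * 131.78 + 0.012 * 115.40)
    assert ae_expected_cost("tdxd", ae) == pytest.approx(expected_tdxd, abs=1e-9)
    assert ae_expected_cost("chemo", ae) == pytest.approx(expected_chemo, abs=1e-9)


class TestAccrue:
    def _inputs(self):
        c = replace(CostInputs(), tdxd_wastage="whole")
        return EconomicSettings(), c, UtilityInputs(), AEProfile()

    def test_all_dead_after_entry(self):
        settings, costs, utils, ae = self._inputs()
        H = settings.horizon_cycles
        from psmcea.psm_engine import StateTrace
        pfs = np.zeros(H + 1); pfs[0] = 1.0
        dead = np.ones(H + 1); dead[0] = 0.0
        tr = StateTrace(cycles=np.arange(H + 1), pfs=pfs, pd=np.zeros(H + 1),
                        dead=dead, discount=np.ones(H + 1))
        res = accrue(tr, "tdxd", costs, utils, ae, settings)
        assert res.qaly_total == pytest.approx(utils.u_pfs / 12.0)
        assert res.cost_pd == 0.0

    def test_utility_linearity(self):
        settings, costs, _, ae = self._inputs()
        tr = state_occupancy(OS, PFS, settings)
        r1 = accrue(tr, "tdxd", costs, UtilityInputs(0.4, 0.3), ae, settings)
        r2 = accrue(tr, "tdxd", costs, UtilityInputs(0.8, 0.6), ae, settings)
        assert r2.qaly_total == pytest.approx(2 * r1.qaly_total, rel=1e-12)

    def test_cost_linearity(self):
        settings, costs, utils, ae = self._inputs()
        tr = state_occupancy(OS, PFS, settings)
        r1 = accrue(tr, "tdxd", costs, utils, ae, settings)
        doubled = replace(costs,
                          tdxd_per_100mg=2 * costs.tdxd_per_100mg,
                          hospitalization_per_cycle=2 * costs.hospitalization_per_cycle,
                          followup_per_cycle=2 * costs.followup_per_cycle,
                          pd_cost_per_cycle=2 * costs.pd_cost_per_cycle)
        ae2 = AEProfile(costs={k: 2 * v for k, v in ae.costs.items()},
                        incidence=ae.incidence)
        r2 = accrue(tr, "tdxd", doubled, utils, ae2, settings)
        assert r2.cost_total == pytest.approx(2 * r1.cost_total, rel=1e-12)

    def test_undiscounted_unit_utility_equals_restricted_mean_survival(self):
        """With discount 0 and utilities 1, total QALYs equal the area under
        the OS curve in years, to within one cycle's width of the trapezoid."""
        settings = EconomicSettings(annual_discount=0.0)
        _, costs, _, ae = self._inputs()
        utils = UtilityInputs(1.0, 1.0)
        tr = state_occupancy(OS, PFS, settings)
        res = accrue(tr, "tdxd", costs, utils, ae, settings)
        t = np.arange(settings.horizon_cycles + 1, dtype=float)
        rmst_years = np.trapezoid(np.exp(-t * LN2 / 16.8), t) / 12.0
        assert abs(res.qaly_total - rmst_years) <= 1.0 / 12.0

    def test_econresult_totals_are_component_sums(self):
        settings, costs, utils, ae = self._inputs()
        res = run_arm(OS, PFS, "tdxd", settings, costs, utils, ae)
        assert res.cost_total == pytest.approx(res.cost_pfs + res.cost_pd, abs=0.005)
        assert res.qaly_total == pytest.approx(res.qaly_pfs + res.qaly_pd, abs=0.005)


@given(st.floats(-1e6, 1e6), st.floats(-10, 10))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_icer_quadrant_logic_total(dc, dq):
    """compute_icer never raises and labels every quadrant consistently."""
    a = EconResult(cost_pfs=max(dc, 0.0), cost_pd=0.0,
                   qaly_pfs=max(dq, 0.0), qaly_pd=0.0)
    b = EconResult(cost_pfs=max(-dc, 0.0), cost_pd=0.0,
                   qaly_pfs=max(-dq, 0.0), qaly_pd=0.0)
    out = compute_icer(a, b)
    if out.label == "icer":
        assert out.icer == pytest.approx(out.delta_cost / out.delta_qaly)
        assert (out.delta_qaly > 0 and out.delta_cost > 0) or \
               (out.delta_qaly < 0 and out.delta_cost < 0)
    else:
        assert np.isnan(out.icer)


class TestComputeICER:
    def test_published_all_patients_arithmetic(self):
        a = EconResult(cost_pfs=104168.30, cost_pd=0.0, qaly_pfs=0.31, qaly_pd=0.0)
        b = EconResult(0.0, 0.0, 0.0, 0.0)
        out = compute_icer(a, b)
        assert round(out.icer, 2) == 336026.77

    def test_published_hr_positive_arithmetic(self):
        a = EconResult(cost_pfs=118209.46, cost_pd=0.0, qaly_pfs=0.43, qaly_pd=0.0)
        b = EconResult(0.0, 0.0, 0.0, 0.0)
        out = compute_icer(a, b)
        assert round(out.icer, 2) == 274905.72

    def test_dominance_quadrants(self):
        base = EconResult(100.0, 0.0, 1.0, 0.0)
        cheaper_better = EconResult(99.0, 0.0, 2.0, 0.0)
        out = compute_icer(cheaper_better, base)
        assert out.label == "dominant" and np.isnan(out.icer)
        out = compute_icer(base, cheaper_better)
        assert out.label == "dominated"

    def test_zero_delta_qaly_never_raises(self):
        a = EconResult(10.0, 0.0, 1.0, 0.0)
        b = EconResult(5.0, 0.0, 1.0, 0.0)
        assert compute_icer(a, b).label == "dominated"
        assert compute_icer(b, a).label == "dominant"
        assert compute_icer(a, a).label == "indeterminate"

    def test_zero_costs_yield_labels_not_garbage(self):
        a = EconResult(0.0, 0.0, 1.2, 0.0)
        b = EconResult(0.0, 0.0, 1.0, 0.0)
        out = compute_icer(a, b)
        assert out.label == "dominant"
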