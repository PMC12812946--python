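"""Cost composition, adverse-event burden, accrual and incremental statistics."""

import numpy as np
import pytest

from psmcea import (
    AdverseEvent,
    EconomicInputs,
    ModelSettings,
    accrue,
    ae_burden,
    build_trace,
    incremental,
    state_cost_per_cycle,
    weibull_fit_from_params,
)
from psmcea.economics import CONTROL, TREATMENT, ArmResult, default_inputs

PFS_FIT = weibull_fit_from_params(1.1719, 20.508)
OS_FIT = weibull_fit_from_params(1.7373, 41.986)
OTHER_TOTAL = 59.89 + 152.95 + 90.71 + 140.20 + 11.64


def test_state_cost_composition():
    """Regimen drugs + routine items in PFS; post-progression regimen in PD,
    identical across arms."""
    inputs = default_inputs()
    assert state_cost_per_cycle(CONTROL, "pfs", inputs) == pytest.approx(
        419.60 + 646.59 + OTHER_TOTAL
    )
    assert state_cost_per_cycle(TREATMENT, "pfs", inputs) == pytest.approx(
        4065.70 + 419.60 + 646.59 + OTHER_TOTAL
    )
    for arm in (TREATMENT, CONTROL):
        assert state_cost_per_cycle(arm, "pd", inputs) == pytest.approx(459.28 + OTHER_TOTAL)
    with pytest.raises(ValueError):
        state_cost_per_cycle(TREATMENT, "cured", inputs)
    with pytest.raises(ValueError):
        state_cost_per_cycle("armX", "pfs", inputs)


def test_zeroed_inputs_give_zero_costs():
    inputs = default_inputs()
    for d in inputs.drug_cost_per_cycle:
        inputs.drug_cost_per_cycle[d] = 0.0
    for o in inputs.other_cost_per_cycle:
        inputs.other_cost_per_cycle[o] = 0.0
    assert state_cost_per_cycle(TREATMENT, "pfs", inputs) == 0.0
    assert state_cost_per_cycle(TREATMENT, "pd", inputs) == 0.0


def test_ae_burden_zero_single_and_additive():
    inputs = default_inputs()
    for ae in inputs.ae_profile:
        ae.incidence = {TREATMENT: 0.0, CONTROL: 0.0}
    assert ae_burden(TREATMENT, inputs) == (0.0, 0.0)
    inputs.ae_profile = [AdverseEvent("neutropenia", 28.04, 0.13, {TREATMENT: 1.0})]
    cost, qaly = ae_burden(TREATMENT, inputs)
    assert cost == pytest.approx(28.04)
    assert qaly == pytest.approx(0.13 * 28.0 / 365.25)
    inputs.ae_profile.append(AdverseEvent("anemia", 21.03, 0.07, {TREATMENT: 0.5}))
    cost2, qaly2 = ae_burden(TREATMENT, inputs)
    assert cost2 == pytest.approx(28.04 + 0.5 * 21.03)
    assert qaly2 == pytest.approx(qaly + 0.5 * 0.07 * 28.0 / 365.25)


def test_ae_incidence_validation():
    with pytest.raises(ValueError):
        AdverseEvent("bad", 1.0, 0.1, {TREATMENT: 1.2})


def _no_ae_inputs(u_pfs=0.837, u_pd=0.443):
    inputs = default_inputs()
    inputs.ae_profile = []
    inputs.utilities = {"pfs": u_pfs, "pd": u_pd}
    return inputs


def test_accrue_reduces_to_life_years_with_unit_utilities():
    trace = build_trace(PFS_FIT, OS_FIT, ModelSettings(discount_annual=0.0))
    res = accrue(trace, TREATMENT, _no_ae_inputs(1.0, 1.0))
    assert res.total_qaly == pytest.approx(trace.life_years(), rel=1e-12)


def test_accrue_zero_utility_in_pfs_only_trace():
    alive = weibull_fit_from_params(1.0, 1e9)  # nobody progresses or dies
    trace = build_trace(alive, alive, ModelSettings(horizon_rule="fixed", horizon_years=2))
    inputs = _no_ae_inputs(0.0, 0.443)
    res = accrue(trace, TREATMENT, inputs)
    assert np.all(trace.pd_bar == 0)
    assert res.total_qaly == pytest.approx(0.0, abs=1e-12)


def test_accrue_single_cycle_sum():
    alive = weibull_fit_from_params(1.0, 1e9)
    settings = ModelSettings(
        discount_annual=0.0, horizon_rule="fixed", horizon_years=28.0 / 365.25
    )
    trace = build_trace(alive, alive, settings)
    assert trace.n_cycles == 1
    inputs = default_inputs()
    res = accrue(trace, TREATMENT, inputs)
    c_pfs = state_cost_per_cycle(TREATMENT, "pfs", inputs)
    ae_cost, _ = ae_burden(TREATMENT, inputs)
    assert res.total_cost == pytest.approx(c_pfs + ae_cost)


def test_cost_linearity_in_unit_costs():
    """Doubling one drug's per-cycle cost moves only the arm that uses it,
    by exactly the discounted PFS-occupancy-weighted drug term."""
    settings = ModelSettings()
    traces = {
        TREATMENT: build_trace(PFS_FIT, OS_FIT, settings),
        CONTROL: build_trace(weibull_fit_from_params(1.1719, 9.981), OS_FIT, settings),
    }
    base = default_inputs()
    doubled = base.copy()
    doubled.drug_cost_per_cycle["inavolisib"] *= 2
    trt_base = accrue(traces[TREATMENT], TREATMENT, base)
    trt_doubled = accrue(traces[TREATMENT], TREATMENT, doubled)
    ctl_base = accrue(traces[CONTROL], CONTROL, base)
    ctl_doubled = accrue(traces[CONTROL], CONTROL, doubled)
    drug_term = 4065.70 * float(np.sum(traces[TREATMENT].df * traces[TREATMENT].pfs_bar))
    assert trt_doubled.total_cost - trt_base.total_cost == pytest.approx(drug_term, rel=1e-10)
    assert ctl_doubled.total_cost == pytest.approx(ctl_base.total_cost, rel=1e-12)


def test_qaly_bounded_by_discounted_life_expectancy():
    trace = build_trace(PFS_FIT, OS_FIT, ModelSettings())
    res = accrue(trace, TREATMENT, default_inputs())
    assert res.total_qaly <= trace.life_years(discounted=True) + 1e-9


def test_incremental_arithmetic_and_published_qaly_gap():
    a = ArmResult(TREATMENT, 200.0, 3.0)
    b = ArmResult(CONTROL, 100.0, 1.0)
    ce = incremental(a, b, wtp=50.0)
    assert ce.icer == pytest.approx(50.0)
    # the published per-arm QALY totals imply the published increment
    ce2 = incremental(ArmResult(TREATMENT, 0, 2.999), ArmResult(CONTROL, 0, 1.744), 40271.0)
    assert ce2.delta_qaly == pytest.approx(1.255, abs=1e-9)


def test_incremental_dominance_and_nmb_sign():
    dominant = incremental(ArmResult("t", 50.0, 2.0), ArmResult("c", 100.0, 1.0), 10.0)
    assert dominant.dominance == "dominant" and dominant.nmb > 0
    dominated = incremental(ArmResult("t", 150.0, 1.0), ArmResult("c", 100.0, 2.0), 10.0)
    assert dominated.dominance == "dominated"
    tie = incremental(ArmResult("t", 150.0, 1.0), ArmResult("c", 100.0, 1.0), 10.0)
    assert tie.icer is None and tie.nmb == pytest.approx(-50.0)
    # ICER > WTP <=> NMB < 0 whenever delta QALYs > 0
    for wtp in (10.0, 49.0, 51.0, 500.0):
        ce = incremental(ArmResult("t", 200.0, 3.0), ArmResult("c", 100.0, 1.0), wtp)
        assert (ce.icer > wtp) == (ce.nmb < 0)
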