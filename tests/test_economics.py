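import numpy as np
import pytest

from protoncea.economics import (
    CEResult, compute_ce, compute_ce_all, discount_factor, discounted_costs,
    discounted_qalys, net_monetary_benefit, run_arm,
)
from protoncea.engine import StateTrace
from protoncea.params import UtilityPair, default_params
from protoncea.synthetic import generate_toy_fixture


def make_trace(n, p_no, p_hl, onset=None):
    """Constant-occupancy trace for closed-form reward checks."""
    t = np.arange(n + 1)
    return StateTrace(
        t=t, age=6 + t,
        p_no_hl=np.full(n + 1, p_no),
        p_hl=np.full(n + 1, p_hl),
        p_dead=np.full(n + 1, 1.0 - p_no - p_hl),
        onset_mass=np.zeros(n + 1) if onset is None else np.asarray(onset, float),
        hazard=np.zeros(n + 1),
    )


# ----------------------------------------------------------------------
# discounting

def test_discount_factor_identities():
    assert discount_factor(0, 0.03) == 1.0
    assert discount_factor(7, 0.0) == 1.0
    assert discount_factor(1, 0.03) == pytest.approx(1 / 1.03, abs=1e-15)


def test_discount_factor_rejects_negative_inputs():
    with pytest.raises(ValueError):
        discount_factor(-1, 0.03)
    with pytest.raises(ValueError):
        discount_factor(1, -0.03)


# ----------------------------------------------------------------------
# QALYs

def test_undiscounted_full_survival_life_years():
    tr = make_trace(94, 1.0, 0.0)
    u = UtilityPair(u_no_hl=1.0, u_hl=0.5)
    assert discounted_qalys(tr, u, 0.0) == pytest.approx(94.0, abs=1e-9)


def test_toy_trace_hand_sum():
    # 3 cycles at p=(0.9, 0.1, 0), u=(1, 0.5), r=0 -> 3 x (0.9 + 0.05)
    tr = make_trace(3, 0.9, 0.1)
    u = UtilityPair(u_no_hl=1.0, u_hl=0.5)
    assert discounted_qalys(tr, u, 0.0) == pytest.approx(2.85, abs=1e-12)


def test_flat_mortality_matches_geometric_series():
    # q = 0.02 at every age and r = 0.03: discounted life-years have the
    # closed form sum_{t=1..n} (0.98/1.03)^t
    params, lt = generate_toy_fixture("flat_mortality")
    for g in (params.avg_risk, params.high_risk):
        g.hl_risk_xrt = 0.0
        g.hl_risk_pt = 0.0
    out = run_arm(params, lt, "XRT")
    x = 0.98 / 1.03
    n = params.n_cycles
    expected = x * (1 - x ** n) / (1 - x)
    assert out.occ_no_hl == pytest.approx(expected, abs=1e-9)
    assert out.occ_hl == pytest.approx(0.0, abs=1e-15)


def test_qalys_strictly_decrease_with_discount_rate(params, life_table):
    tr = run_arm(params, life_table, "XRT").trace
    u = params.utilities["EQ-5D"]
    q = [discounted_qalys(tr, u, r) for r in (0.0, 0.01, 0.03, 0.07)]
    assert all(a > b for a, b in zip(q, q[1:]))


# ----------------------------------------------------------------------
# costs

def test_zero_risk_cost_is_course_cost_exactly(params):
    tr = make_trace(94, 1.0, 0.0)
    assert discounted_costs(tr, params.costs, "XRT", 0.03) == params.costs.c_xrt_course
    assert discounted_costs(tr, params.costs, "PT", 0.03) == params.costs.c_pt_course


def test_unknown_arm_rejected(params):
    tr = make_trace(10, 1.0, 0.0)
    with pytest.raises(ValueError, match="arm"):
        discounted_costs(tr, params.costs, "IMRT", 0.03)


def test_purchase_schedule_enumeration(params):
    # one full onset at t=1, nobody dies, r=0, horizon 11, aids last 5 years:
    # oracle = direct enumeration -> aid purchases in years 1, 6, 11;
    # hearing tests in years 1 (onset), 2, 3; fitting test once
    n = 11
    onset = np.zeros(n + 1)
    onset[1] = 1.0
    p_no = np.concatenate([[1.0], np.zeros(n)])
    p_hl = 1.0 - p_no
    tr = StateTrace(
        t=np.arange(n + 1), age=6 + np.arange(n + 1),
        p_no_hl=p_no, p_hl=p_hl, p_dead=np.zeros(n + 1),
        onset_mass=onset, hazard=np.zeros(n + 1),
    )
    c = params.costs
    expected = (
        c.c_xrt_course + 3 * c.c_hearing_test + c.c_fitting_test
        + 3 * c.c_hearing_aid
    )
    assert discounted_costs(tr, c, "XRT", 0.0) == pytest.approx(expected, abs=1e-9)


def test_hearing_costs_prorated_by_survival(params):
    # half of the onset cohort dead by the replacement year -> half an aid
    n = 6
    onset = np.zeros(n + 1)
    onset[1] = 1.0
    alive = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5])
    tr = StateTrace(
        t=np.arange(n + 1), age=6 + np.arange(n + 1),
        p_no_hl=np.zeros(n + 1), p_hl=alive, p_dead=1.0 - alive,
        onset_mass=onset, hazard=np.zeros(n + 1),
    )
    c = params.costs
    expected = (
        c.c_xrt_course + c.c_hearing_test + c.c_fitting_test + c.c_hearing_aid
        + 2 * c.c_hearing_test        # follow-up tests, years 2 and 3
        + 0.5 * c.c_hearing_aid       # replacement at year 6, half alive
    )
    assert discounted_costs(tr, c, "XRT", 0.0) == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------------
# incremental results

def test_equal_risk_arms_give_undefined_icer(life_table):
    p = default_params()
    for g in (p.avg_risk, p.high_risk):
        g.hl_risk_xrt = 0.0
        g.hl_risk_pt = 0.0
    res = compute_ce(p, life_table, "EQ-5D")
    assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
    assert res.delta_cost == pytest.approx(
        p.costs.c_pt_course - p.costs.c_xrt_course, abs=1e-9
    )
    assert not res.icer_defined
    assert res.icer is None


def test_icer_consistency_identity(params, life_table):
    for res in compute_ce_all(params, life_table).values():
        assert res.icer * res.delta_qaly == pytest.approx(res.delta_cost, abs=1e-9)


def test_proton_arm_dominates_quadrant(params, life_table):
    # proton therapy costs more and yields more QALYs under base inputs
    for res in compute_ce_all(params, life_table).values():
        assert res.qaly_pt > res.qaly_xrt
        assert res.cost_pt > res.cost_xrt


def test_net_monetary_benefit_identities(params, life_table):
    res = compute_ce(params, life_table, "EQ-5D")
    assert net_monetary_benefit(res, 0.0) == pytest.approx(-res.delta_cost)
    assert net_monetary_benefit(res, res.icer) == pytest.approx(0.0, abs=1e-6)
    assert net_monetary_benefit(res, params.econ.wtp) > 0


def test_half_cycle_correction_shifts_qalys_slightly(life_table):
    p = default_params()
    base = compute_ce(p, life_table, "EQ-5D")
    p.half_cycle_correction = True
    half = compute_ce(p, life_table, "EQ-5D")
    rel = abs(half.qaly_xrt - base.qaly_xrt) / base.qaly_xrt
    assert 0.0 < rel < 0.03
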