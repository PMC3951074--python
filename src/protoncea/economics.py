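"""Discounted costs, QALYs, and incremental cost-effectiveness.

Accounting conventions (each a deliberate, documented choice):

* Rewards accrue at cycle end: cycle 0 carries only the radiation-course
  cost, cycles 1..n contribute utilities and hearing-related costs, all
  discounted by (1+r)^-t.  An optional half-cycle correction averages
  adjacent state vectors and discounts at mid-cycle; it is off by default.
* Hearing-related costs follow each onset cohort: hearing test + fitting
  test + hearing aid at onset, an annual hearing test in each of the two
  years after onset, and a replacement hearing aid every ``aid_lifetime``
  years for life, all pro-rated by the cohort mass still alive at the
  purchase cycle.
* ICERs are computed from unrounded incremental costs and QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .engine import ArmSpec, StateTrace, mix_cohorts, run_cohort
from .mortality import LifeTable, MortalitySchedule
from .params import ModelParams, UtilityPair, UTILITY_INDEXES

__all__ = [
    "discount_factor",
    "discounted_qalys",
    "discounted_costs",
    "compute_ce",
    "compute_ce_all",
    "net_monetary_benefit",
    "CEResult",
    "ArmOutcome",
]


def discount_factor(t, r: float):
    """Present-value multiplier (1+r)^(-t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    out = (1.0 + r) ** (-t)
    return float(out) if out.ndim == 0 else out


def _occupancy_sums(trace: StateTrace, r: float,
                    half_cycle: bool) -> tuple[float, float]:
    """Discounted occupancy-time in (NoHL, HL) over cycles 1..n."""
    t = trace.t[1:]
    if half_cycle:
        no = 0.5 * (trace.p_no_hl[:-1] + trace.p_no_hl[1:])
        hl = 0.5 * (trace.p_hl[:-1] + trace.p_hl[1:])
        d = discount_factor(t - 0.5, r)
    else:
        no = trace.p_no_hl[1:]
        hl = trace.p_hl[1:]
        d = discount_factor(t, r)
    return float(np.sum(d * no)), float(np.sum(d * hl))


def discounted_qalys(trace: StateTrace, u: UtilityPair, r: float,
                     half_cycle: bool = False) -> float:
    """Discounted quality-adjusted life years accrued by the cohort."""
    occ_no, occ_hl = _occupancy_sums(trace, r, half_cycle)
    return occ_no * u.u_no_hl + occ_hl * u.u_hl


def discounted_costs(trace: StateTrace, costs, arm: str, r: float,
                     onset_mass: np.ndarray | None = None) -> float:
    """Discounted lifetime cost for one cohort trace.

    ``onset_mass`` defaults to the trace's own per-cycle new-HL mass; it can
    be overridden for hypothetical streams in tests.
    """
    if arm == "XRT":
        total = costs.c_xrt_course
    elif arm == "PT":
        total = costs.c_pt_course
    else:
        raise ValueError(f"arm must be 'XRT' or 'PT', got {arm!r}")

    m = trace.onset_mass if onset_mass is None else np.asarray(onset_mass)
    alive = trace.p_alive
    n = trace.n_cycles
    onset_package = costs.c_hearing_test + costs.c_fitting_test + costs.c_hearing_aid
    for s in np.nonzero(m[: n + 1])[0]:
        mass = m[s]
        if mass <= 0.0:
            continue
        total += mass * onset_package * discount_factor(int(s), r)
        # cohort survival ratio: mortality is state-independent, so the
        # onset cohort decays like the whole alive mass
        for j in (1, 2):  # annual hearing test for two years after onset
            t = int(s) + j
            if t <= n:
                frac = alive[t] / alive[s]
                total += mass * frac * costs.c_hearing_test * discount_factor(t, r)
        k = costs.aid_lifetime
        t = int(s) + k
        while t <= n:  # hearing-aid replacement for life
            frac = alive[t] / alive[s]
            total += mass * frac * costs.c_hearing_aid * discount_factor(t, r)
            t += k
    return float(total)


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ArmOutcome:
    """Risk-group-mixed discounted outcomes of one treatment arm.

    QALYs for any utility pair follow from the two occupancy sums, so one
    arm evaluation serves all three instruments.
    """

    arm: str
    cost: float
    occ_no_hl: float    # discounted years alive without hearing loss
    occ_hl: float       # discounted years alive with hearing loss
    trace: StateTrace   # mixed trace (inspection/plotting)

    def qalys(self, u: UtilityPair) -> float:
        return self.occ_no_hl * u.u_no_hl + self.occ_hl * u.u_hl


def run_arm(params: ModelParams, life_table: LifeTable, arm: str) -> ArmOutcome:
    """Run both risk groups for one arm and mix them 70/30."""
    r = params.econ.discount_rate
    weights = {
        "average": 1.0 - params.p_high_risk,
        "high": params.p_high_risk,
    }
    groups = {"average": params.avg_risk, "high": params.high_risk}
    cost = 0.0
    occ_no = 0.0
    occ_hl = 0.0
    mixed = []
    for name, g in groups.items():
        risk = g.hl_risk_xrt if arm == "XRT" else g.hl_risk_pt
        spec = ArmSpec(arm=arm, risk_group=name,
                       hl_lifetime_risk=risk, os5=g.os5)
        mort = MortalitySchedule(os5=g.os5, life_table=life_table,
                                 start_age=params.start_age)
        trace = run_cohort(spec, mort, params)
        w = weights[name]
        cost += w * discounted_costs(trace, params.costs, arm, r)
        o_no, o_hl = _occupancy_sums(trace, r, params.half_cycle_correction)
        occ_no += w * o_no
        occ_hl += w * o_hl
        mixed.append((w, trace))
    return ArmOutcome(arm=arm, cost=cost, occ_no_hl=occ_no, occ_hl=occ_hl,
                      trace=mix_cohorts(mixed))


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness of proton vs photon therapy."""

    utility_index: str
    cost_xrt: float
    cost_pt: float
    qaly_xrt: float
    qaly_pt: float

    @property
    def delta_cost(self) -> float:
        return self.cost_pt - self.cost_xrt

    @property
    def delta_qaly(self) -> float:
        return self.qaly_pt - self.qaly_xrt

    @property
    def icer_defined(self) -> bool:
        return self.delta_qaly != 0.0

    @property
    def icer(self) -> float | None:
        """USD per QALY gained; None when the QALY difference is zero."""
        if not self.icer_defined:
            return None
        return self.delta_cost / self.delta_qaly

    def to_row(self) -> dict:
        return {
            "utility_index": self.utility_index,
            "cost_xrt": self.cost_xrt, "cost_pt": self.cost_pt,
            "qaly_xrt": self.qaly_xrt, "qaly_pt": self.qaly_pt,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "icer": self.icer,
        }


def compute_ce(params: ModelParams, life_table: LifeTable,
               utility_index: str) -> CEResult:
    """Full base-case evaluation for one utility instrument."""
    return compute_ce_all(params, life_table)[utility_index]


def compute_ce_all(params: ModelParams,
                   life_table: LifeTable) -> dict[str, CEResult]:
    """Evaluate both arms once and report all three utility instruments."""
    xrt = run_arm(params, life_table, "XRT")
    pt = run_arm(params, life_table, "PT")
    out = {}
    for index in UTILITY_INDEXES:
        u = params.utilities[index]
        out[index] = CEResult(
            utility_index=index,
            cost_xrt=xrt.cost, cost_pt=pt.cost,
            qaly_xrt=xrt.qalys(u), qaly_pt=pt.qalys(u),
        )
    return out


def net_monetary_benefit(res: CEResult, wtp: float) -> float:
    """wtp * delta_qaly - delta_cost (positive = acceptable at that WTP)."""
    return wtp * res.delta_qaly - res.delta_cost


def results_frame(results: Iterable[CEResult]) -> pd.DataFrame:
    """One row per utility instrument, in the published table's layout."""
    return pd.DataFrame([r.to_row() for r in results])
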