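"""Three-state annual-cycle Markov cohort model.

States: alive without hearing loss (NoHL), alive with Grade 3-4 hearing
loss (HL, permanent, hearing-aided), Dead (absorbing).  The cohort starts
treatment at age 6 and is followed in one-year cycles until age 100.

Within each cycle, death is applied first (state-independent annual
probability from the mortality schedule), then hearing-loss conversion
among the surviving NoHL occupants.  With this ordering the hearing-loss
prevalence among survivors at the plateau equals the lifetime risk exactly,
which is how the tabulated per-arm risks are defined.

Hearing loss begins one year after treatment and its cumulative incidence
among survivors rises in equal increments until it plateaus at the lifetime
risk in year 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mortality import MortalitySchedule
from .params import ModelParams

__all__ = ["ArmSpec", "StateTrace", "onset_fraction", "run_cohort", "mix_cohorts"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm x risk group combination."""

    arm: str               # "XRT" or "PT"
    risk_group: str        # "average" or "high"
    hl_lifetime_risk: float
    os5: float

    def __post_init__(self):
        if self.arm not in ("XRT", "PT"):
            raise ValueError(f"arm must be 'XRT' or 'PT', got {self.arm!r}")
        if not (0.0 <= self.hl_lifetime_risk <= 1.0):
            raise ValueError("hl_lifetime_risk must be in [0, 1]")


@dataclass
class StateTrace:
    """Per-cycle occupancy of the three states for one cohort.

    Arrays are indexed by cycle t = 0..n; ``age[t] = start_age + t``.
    ``onset_mass[t]`` is the cohort mass newly converting to HL during
    cycle t (zero at t=0), and ``hazard[t]`` the death probability applied
    in the transition into cycle t.
    """

    t: np.ndarray
    age: np.ndarray
    p_no_hl: np.ndarray
    p_hl: np.ndarray
    p_dead: np.ndarray
    onset_mass: np.ndarray
    hazard: np.ndarray

    def __post_init__(self):
        sums = self.p_no_hl + self.p_hl + self.p_dead
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("state vectors do not sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.t.size - 1

    @property
    def p_alive(self) -> np.ndarray:
        return self.p_no_hl + self.p_hl

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "age": self.age,
            "p_no_hl": self.p_no_hl, "p_hl": self.p_hl, "p_dead": self.p_dead,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cumulative_incidence(t: int, lifetime_risk: float,
                         onset_start: int, onset_plateau: int) -> float:
    """Cumulative HL incidence among survivors by the end of cycle t.

    Zero before ``onset_start``; rises in equal increments over cycles
    onset_start..onset_plateau; equals ``lifetime_risk`` from the plateau on.
    """
    if t < onset_start:
        return 0.0
    if t >= onset_plateau:
        return lifetime_risk
    steps = onset_plateau - onset_start + 1
    done = t - onset_start + 1
    return lifetime_risk * done / steps


def onset_fraction(t: int, lifetime_risk: float,
                   onset_start: int = 1, onset_plateau: int = 3) -> float:
    """Conditional per-cycle NoHL -> HL transition probability at cycle t.

    Chosen so that the cumulative incidence among survivors follows
    :func:`cumulative_incidence` exactly under death-first ordering.
    """
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t}")
    if not (0.0 <= lifetime_risk <= 1.0):
        raise ValueError("lifetime_risk must be in [0, 1]")
    prev = cumulative_incidence(t - 1, lifetime_risk, onset_start, onset_plateau)
    cur = cumulative_incidence(t, lifetime_risk, onset_start, onset_plateau)
    if cur == prev:
        return 0.0
    if prev >= 1.0:
        return 0.0
    return (cur - prev) / (1.0 - prev)


def run_cohort(spec: ArmSpec, mort: MortalitySchedule,
               params: ModelParams) -> StateTrace:
    """Run the cohort recursion for one arm x risk group.

    The t=0 vector is (1, 0, 0); each cycle applies death first, then HL
    conversion among surviving NoHL occupants; Dead is absorbing.
    """
    n = params.n_cycles
    q = mort.hazard_vector(n)

    p_no = np.empty(n + 1)
    p_hl = np.empty(n + 1)
    p_dead = np.empty(n + 1)
    onset = np.zeros(n + 1)
    p_no[0], p_hl[0], p_dead[0] = 1.0, 0.0, 0.0

    for t in range(1, n + 1):
        qt = q[t - 1]
        no = p_no[t - 1] * (1.0 - qt)
        hl = p_hl[t - 1] * (1.0 - qt)
        dead = p_dead[t - 1] + (p_no[t - 1] + p_hl[t - 1]) * qt
        h = onset_fraction(
            t, spec.hl_lifetime_risk,
            params.onset_start_year, params.onset_plateau_year,
        )
        new_hl = no * h
        p_no[t] = no - new_hl
        p_hl[t] = hl + new_hl
        p_dead[t] = dead
        onset[t] = new_hl

    t_axis = np.arange(n + 1)
    return StateTrace(
        t=t_axis,
        age=params.start_age + t_axis,
        p_no_hl=p_no, p_hl=p_hl, p_dead=p_dead,
        onset_mass=onset,
        hazard=np.concatenate([[0.0], q]),
    )


def mix_cohorts(traces: Sequence[tuple[float, StateTrace]]) -> StateTrace:
    """Cycle-wise convex combination of cohort traces (e.g. risk-group mix)."""
    if not traces:
        raise ValueError("need at least one (weight, trace) pair")
    weights = np.array([w for w, _ in traces], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")
    n = traces[0][1].t.size
    for _, tr in traces:
        if tr.t.size != n:
            raise ValueError("traces have mismatched lengths")
    first = traces[0][1]

    def mix(attr: str) -> np.ndarray:
        return np.sum(
            [w * getattr(tr, attr) for w, tr in traces], axis=0
        )

    return StateTrace(
        t=first.t.copy(), age=first.age.copy(),
        p_no_hl=mix("p_no_hl"), p_hl=mix("p_hl"), p_dead=mix("p_dead"),
        onset_mass=mix("onset_mass"),
        # the mixed hazard is occupancy-weighted, not a plain convex mix;
        # stored for inspection only and not used downstream
        hazard=mix("hazard"),
    )
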