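"""Annual death probabilities for the cohort model.

Years 1-5 after treatment use a constant disease-driven annual hazard
calibrated so that five-year survival reproduces the trial-based 5-year
overall survival of the risk group exactly.  Disease mortality plateaus
after year 5; from year 6 onward only background all-cause mortality
applies, read from an age-indexed life table of annual death probabilities
q(a).

The trial survival curves are treated as all-cause within years 1-5
(no background mortality is added on top, which would double-count), and
the hearing-loss state does not alter survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalitySchedule",
    "disease_hazard_from_os5",
    "load_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities q(a) for ages 0..max_age."""

    qx: np.ndarray  # index = age in years

    def __post_init__(self):
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", q)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("life table must be a non-empty 1-D q(a) array")
        if np.any(q < 0) or np.any(q > 1):
            bad = int(np.argmax((q < 0) | (q > 1)))
            raise ValueError(f"q({bad})={q[bad]!r} outside [0, 1]")

    @property
    def max_age(self) -> int:
        return self.qx.size - 1

    def q(self, age: int) -> float:
        """Annual death probability at integer age ``age``."""
        if age < 0:
            raise ValueError(f"age {age} < 0")
        if age > self.max_age:
            raise ValueError(
                f"age {age} beyond life-table end ({self.max_age}); "
                "extend the table or clamp its tail"
            )
        return float(self.qx[age])

    def clamped(self, terminal_age: int | None = None) -> "LifeTable":
        """Copy with q forced to 1 at ``terminal_age`` (default: table end)."""
        q = self.qx.copy()
        a = self.max_age if terminal_age is None else terminal_age
        q[a] = 1.0
        return LifeTable(q)

    def life_expectancy(self, age: int = 0) -> float:
        """Period life expectancy at ``age`` (midpoint person-years)."""
        surv = np.cumprod(1.0 - self.qx[age:])
        # e(a) = sum of years lived; deaths contribute half the year
        l = np.concatenate([[1.0], surv])
        return float(np.sum((l[:-1] + l[1:]) / 2.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(self.qx.size), "qx": self.qx})


def disease_hazard_from_os5(os5: float) -> float:
    """Constant annual death probability q with (1-q)^5 = os5."""
    if not (0.0 < os5 <= 1.0):
        raise ValueError(f"5-year overall survival must be in (0, 1], got {os5!r}")
    return 1.0 - os5 ** 0.2


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual death probability as a function of follow-up time and age."""

    os5: float
    life_table: LifeTable
    start_age: int = 6
    disease_years: int = 5

    @property
    def disease_hazard(self) -> float:
        return disease_hazard_from_os5(self.os5)

    def annual_death_prob(self, age: int, t: int) -> float:
        """Death probability during year ``t`` after treatment.

        ``age`` is the attained age at cycle ``t`` (= start_age + t).
        Years 1..5 use the constant disease hazard; later years use the
        background life-table probability at the attained age.
        """
        if t < 1:
            raise ValueError(f"first transition occurs at t=1, got t={t}")
        if age != self.start_age + t:
            raise ValueError(
                f"inconsistent age {age} for t={t} (expected {self.start_age + t})"
            )
        if t <= self.disease_years:
            return self.disease_hazard
        return self.life_table.q(age)

    def hazard_vector(self, n_cycles: int) -> np.ndarray:
        """q_t for t = 1..n_cycles as an array of length n_cycles."""
        out = np.empty(n_cycles)
        for t in range(1, n_cycles + 1):
            out[t - 1] = self.annual_death_prob(self.start_age + t, t)
        return out


def load_life_table(path: str | Path, max_age: int | None = None,
                    clamp_terminal: bool = False) -> LifeTable:
    """Read a two-column delimited text life table (age, qx).

    Ages must be contiguous from 0.  ``max_age`` additionally requires the
    table to reach at least that age; ``clamp_terminal`` forces q=1 at the
    final age so the last cycle is absorbing.
    """
    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "age" not in cols or "qx" not in cols:
        raise ValueError("life table needs 'age' and 'qx' columns")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    expected = np.arange(ages.min(), ages.max() + 1)
    if ages.min() != 0:
        raise ValueError("life table must start at age 0")
    if ages.size != expected.size or np.any(ages != expected):
        missing = sorted(set(expected) - set(ages))
        raise ValueError(f"life table has gaps at ages {missing[:5]}")
    if max_age is not None and ages.max() < max_age:
        raise ValueError(
            f"life table ends at age {ages.max()}, needs at least {max_age}"
        )
    lt = LifeTable(df["qx"].to_numpy(dtype=float))
    return lt.clamped() if clamp_terminal else lt


def save_life_table(lt: LifeTable, path: str | Path) -> None:
    lt.to_frame().to_csv(path, index=False)
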