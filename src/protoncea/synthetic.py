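"""Synthetic inputs: a stand-in life table and deterministic test fixtures.

The analysis needs an age-indexed all-cause mortality table for a modern
low-mortality population.  The official Japanese complete life table is not
redistributed here; instead a synthetic table is generated from a
Gompertz-Makeham hazard

    mu(a) = makeham + gompertz_scale * exp(gompertz_rate * a)

whose three parameters are calibrated so that period life expectancy at
birth is about 82 years (both sexes, modern-Japan ballpark) with a
realistic exponential rise of q(a) at older ages.  The table is synthetic
and approximate, not official; the cost-effectiveness results are shown by
test to be insensitive to moderate perturbations of its parameters.

Generation is fully deterministic: the module always reproduces the bundled
``data/lifetable_synthetic_jp.csv`` bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .mortality import LifeTable, load_life_table, save_life_table
from .params import ModelParams, default_params

__all__ = [
    "GompertzMakehamParams",
    "DEFAULT_GM",
    "generate_life_table",
    "bundled_life_table",
    "generate_toy_fixture",
    "FIXTURES",
]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Parameters of the Gompertz-Makeham annual hazard (per-year units)."""

    makeham: float = 4.0e-4         # age-independent background hazard
    gompertz_scale: float = 5.0e-6  # senescent hazard at age 0
    gompertz_rate: float = 0.115    # exponential increase per year of age

    def validate(self) -> None:
        for name in ("makeham", "gompertz_scale", "gompertz_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def level_scaled(self, factor: float) -> "GompertzMakehamParams":
        """Hazard-level perturbation: the two level parameters (makeham,
        gompertz_scale) multiplied by ``factor``, i.e. mortality uniformly
        ``factor`` times higher at every age.  The rate parameter sits in an
        exponent, so it is not a level and is left alone."""
        return replace(
            self,
            makeham=self.makeham * factor,
            gompertz_scale=self.gompertz_scale * factor,
        )


#: Calibrated defaults: life expectancy at birth ~= 82 years over ages 0-100.
DEFAULT_GM = GompertzMakehamParams()


def generate_life_table(p: GompertzMakehamParams = DEFAULT_GM,
                        max_age: int = 100) -> LifeTable:
    """Annual death probabilities q(a) = 1 - exp(-mu(a)) for ages 0..max_age."""
    p.validate()
    ages = np.arange(0, max_age + 1)
    hazard = p.makeham + p.gompertz_scale * np.exp(p.gompertz_rate * ages)
    return LifeTable(1.0 - np.exp(-hazard))


def write_bundled_table(path: str | Path) -> None:
    """Regenerate the shipped synthetic life-table CSV (deterministic)."""
    save_life_table(generate_life_table(), path)


def bundled_life_table() -> LifeTable:
    """Load the life table CSV shipped with the package."""
    with resources.as_file(
        resources.files("protoncea").joinpath("data/lifetable_synthetic_jp.csv")
    ) as f:
        return load_life_table(f, max_age=100)


# ----------------------------------------------------------------------
# Toy fixtures with closed-form expected behaviour

FIXTURES = ("null_risk", "certain_death_y5", "flat_mortality", "base_case")


def generate_toy_fixture(name: str) -> tuple[ModelParams, LifeTable]:
    """Deterministic small inputs used by the unit tests.

    null_risk
        Hearing-loss risk zero in both arms: the only incremental quantity
        left is the radiation-course price difference, and the ICER is
        undefined (zero QALY gain).
    certain_death_y5
        5-year survival ~0 in both groups: all rewards come from the first
        five cycles.
    flat_mortality
        Constant q = 0.02 at every age with perfect 5-year survival: the
        discounted life-years have a geometric-series closed form.
    base_case
        Alias for the default parameters plus the bundled life table.
    """
    if name == "base_case":
        return default_params(), bundled_life_table()
    p = default_params()
    if name == "null_risk":
        for g in (p.avg_risk, p.high_risk):
            g.hl_risk_xrt = 0.0
            g.hl_risk_pt = 0.0
        # tabulated risk ranges no longer bracket the zeroed base values
        for key in list(p.ranges):
            if key.startswith("hl_risk"):
                del p.ranges[key]
        lt = bundled_life_table()
    elif name == "certain_death_y5":
        for g in (p.avg_risk, p.high_risk):
            g.os5 = 1e-12
        for key in ("os5_average", "os5_high"):
            del p.ranges[key]
        lt = bundled_life_table()
    elif name == "flat_mortality":
        for g in (p.avg_risk, p.high_risk):
            g.os5 = (1.0 - 0.02) ** 5
        for key in ("os5_average", "os5_high"):
            del p.ranges[key]
        lt = LifeTable(np.full(101, 0.02))
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    p.validate()
    return p, lt
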