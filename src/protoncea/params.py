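"""Model parameters: definition, validation, defaults, YAML (de)serialization.

The default parameter set encodes the published inputs of the decision model:
trial-based 5-year overall survival per risk group, Grade 3-4 hearing-loss
risks per treatment arm derived from mean cochlear dose, health-state
utilities for three preference-based instruments (EQ-5D, HUI3, SF-6D),
direct medical costs from the payer perspective, and the economic settings
(3% annual discount, willingness-to-pay threshold of $46,729/QALY).

Every uncertain parameter carries a triangular range (low, mode=base, high)
used by the one-way and probabilistic sensitivity analyses.  Parameters whose
published table gives no interval default to +/-25% of the base value, the
same half-width the source analysis assumed for its cost inputs.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import yaml

__all__ = [
    "ParamError",
    "RiskGroupParams",
    "UtilityPair",
    "CostSet",
    "EconSettings",
    "TriangularRange",
    "ModelParams",
    "default_params",
    "load_params",
    "save_params",
    "get_param",
    "set_param",
    "UTILITY_INDEXES",
    "RANGED_PARAMS",
]

#: Canonical order of the utility instruments.
UTILITY_INDEXES = ("EQ-5D", "HUI3", "SF-6D")


class ParamError(ValueError):
    """Validation failure; ``key`` names the offending parameter."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


def _check_prob(key: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParamError(key, f"probability {value!r} outside [0, 1]")


def _check_nonneg(key: str, value: float) -> None:
    if value < 0:
        raise ParamError(key, f"value {value!r} must be >= 0")


@dataclass
class RiskGroupParams:
    """Survival and ototoxicity inputs for one prognostic risk group."""

    os5: float            # 5-year overall survival
    hl_risk_xrt: float    # lifetime Grade 3-4 hearing-loss risk, photon arm
    hl_risk_pt: float     # lifetime Grade 3-4 hearing-loss risk, proton arm
    dose_xrt_gy: float    # mean cochlear dose, photon arm (Gy)
    dose_pt_gy: float     # mean cochlear dose, proton arm (Gy)

    def validate(self, prefix: str) -> None:
        _check_prob(f"{prefix}.os5", self.os5)
        _check_prob(f"{prefix}.hl_risk_xrt", self.hl_risk_xrt)
        _check_prob(f"{prefix}.hl_risk_pt", self.hl_risk_pt)
        _check_nonneg(f"{prefix}.dose_xrt_gy", self.dose_xrt_gy)
        _check_nonneg(f"{prefix}.dose_pt_gy", self.dose_pt_gy)
        # non-strict so degenerate equal-risk scenarios stay expressible
        if self.dose_pt_gy < self.dose_xrt_gy and (
            self.hl_risk_pt > self.hl_risk_xrt
        ):
            raise ParamError(
                f"{prefix}.hl_risk_pt",
                "proton hearing-loss risk must not exceed the photon risk "
                "when the proton cochlear dose is lower",
            )


@dataclass
class UtilityPair:
    """Utility weights of the two alive states under one instrument."""

    u_no_hl: float   # alive without hearing loss
    u_hl: float      # alive with hearing loss, using hearing aids

    def validate(self, prefix: str) -> None:
        if not (0.0 <= self.u_hl <= self.u_no_hl <= 1.0):
            raise ParamError(
                prefix, f"requires 0 <= u_hl <= u_no_hl <= 1, "
                f"got u_hl={self.u_hl!r}, u_no_hl={self.u_no_hl!r}"
            )


@dataclass
class CostSet:
    """Direct medical costs (USD), payer perspective."""

    c_xrt_course: float
    c_pt_course: float
    c_hearing_test: float
    c_fitting_test: float
    c_hearing_aid: float
    aid_lifetime: int = 5   # years between hearing-aid replacements

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "aid_lifetime":
                if v < 1:
                    raise ParamError("aid_lifetime", f"must be >= 1, got {v!r}")
            else:
                _check_nonneg(f.name, v)


@dataclass
class EconSettings:
    discount_rate: float = 0.03
    wtp: float = 46_729.0          # USD per QALY (JPY 5 million)
    jpy_per_usd: float = 107.0     # reporting only

    def validate(self) -> None:
        _check_nonneg("discount_rate", self.discount_rate)
        if self.wtp <= 0:
            raise ParamError("wtp", f"must be > 0, got {self.wtp!r}")


@dataclass(frozen=True)
class TriangularRange:
    """Support and mode of a triangular distribution; mode is the base value."""

    low: float
    mode: float
    high: float

    def validate(self, key: str) -> None:
        if not (self.low <= self.mode <= self.high):
            raise ParamError(
                key, f"range requires low <= mode <= high, got "
                f"({self.low!r}, {self.mode!r}, {self.high!r})"
            )


# Registry of ranged parameters: name -> attribute path inside ModelParams.
RANGED_PARAMS: dict[str, tuple[str, ...]] = {
    "os5_average": ("avg_risk", "os5"),
    "os5_high": ("high_risk", "os5"),
    "hl_risk_xrt_average": ("avg_risk", "hl_risk_xrt"),
    "hl_risk_xrt_high": ("high_risk", "hl_risk_xrt"),
    "hl_risk_pt_average": ("avg_risk", "hl_risk_pt"),
    "hl_risk_pt_high": ("high_risk", "hl_risk_pt"),
    "p_high_risk": ("p_high_risk",),
    "u_hl_eq5d": ("utilities", "EQ-5D", "u_hl"),
    "u_hl_hui3": ("utilities", "HUI3", "u_hl"),
    "u_hl_sf6d": ("utilities", "SF-6D", "u_hl"),
    "c_xrt_course": ("costs", "c_xrt_course"),
    "c_pt_course": ("costs", "c_pt_course"),
    "c_hearing_test": ("costs", "c_hearing_test"),
    "c_fitting_test": ("costs", "c_fitting_test"),
    "c_hearing_aid": ("costs", "c_hearing_aid"),
    "discount_rate": ("econ", "discount_rate"),
}

#: Which utility-range name belongs to which instrument.
UTILITY_RANGE_NAMES = {
    "EQ-5D": "u_hl_eq5d",
    "HUI3": "u_hl_hui3",
    "SF-6D": "u_hl_sf6d",
}


@dataclass
class ModelParams:
    """Complete input set of the cost-utility model."""

    avg_risk: RiskGroupParams
    high_risk: RiskGroupParams
    p_high_risk: float
    utilities: dict[str, UtilityPair]
    costs: CostSet
    econ: EconSettings
    ranges: dict[str, TriangularRange]
    start_age: int = 6
    horizon_age: int = 100
    onset_start_year: int = 1
    onset_plateau_year: int = 3
    half_cycle_correction: bool = False

    # ------------------------------------------------------------------
    def validate(self) -> None:
        self.avg_risk.validate("avg_risk")
        self.high_risk.validate("high_risk")
        _check_prob("p_high_risk", self.p_high_risk)
        for name in UTILITY_INDEXES:
            if name not in self.utilities:
                raise ParamError(f"utilities[{name}]", "missing utility index")
            self.utilities[name].validate(f"utilities[{name}]")
        self.costs.validate()
        self.econ.validate()
        if not (self.start_age < self.horizon_age):
            raise ParamError("start_age", "must be below horizon_age")
        if not (0 <= self.onset_start_year <= self.onset_plateau_year):
            raise ParamError(
                "onset_start_year", "must satisfy 0 <= start <= plateau"
            )
        for key, rng in self.ranges.items():
            rng.validate(f"ranges[{key}]")
            if key in RANGED_PARAMS:
                base = get_param(self, key)
                if not (rng.low <= base <= rng.high):
                    raise ParamError(
                        f"ranges[{key}]",
                        f"base value {base!r} outside [{rng.low!r}, {rng.high!r}]",
                    )

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    @property
    def n_cycles(self) -> int:
        """Number of annual cycles from treatment to the model horizon."""
        return self.horizon_age - self.start_age


# ----------------------------------------------------------------------
# Attribute-path access used by the sensitivity analyses.

def _resolve(params: ModelParams, path: tuple[str, ...]):
    obj: Any = params
    for step in path[:-1]:
        if isinstance(obj, dict):
            obj = obj[step]
        else:
            obj = getattr(obj, step)
    return obj, path[-1]


def get_param(params: ModelParams, name: str) -> float:
    """Read a ranged parameter by its registry name."""
    obj, leaf = _resolve(params, RANGED_PARAMS[name])
    return getattr(obj, leaf)


def set_param(params: ModelParams, name: str, value: float) -> ModelParams:
    """Return a copy of ``params`` with one ranged parameter replaced."""
    out = params.copy()
    obj, leaf = _resolve(out, RANGED_PARAMS[name])
    setattr(obj, leaf, value)
    return out


# ----------------------------------------------------------------------
# Defaults

def _pm25(base: float) -> tuple[float, float]:
    return base * 0.75, base * 1.25


def default_params() -> ModelParams:
    """The shipped base-case parameter set."""
    avg = RiskGroupParams(
        os5=0.85, hl_risk_xrt=0.39, hl_risk_pt=0.1555,
        dose_xrt_gy=46.4, dose_pt_gy=29.3,
    )
    high = RiskGroupParams(
        os5=0.70, hl_risk_xrt=0.4711, hl_risk_pt=0.2653,
        dose_xrt_gy=50.0, dose_pt_gy=39.6,
    )
    utilities = {
        "EQ-5D": UtilityPair(u_no_hl=1.0, u_hl=0.807),
        "HUI3": UtilityPair(u_no_hl=1.0, u_hl=0.644),
        "SF-6D": UtilityPair(u_no_hl=1.0, u_hl=0.792),
    }
    costs = CostSet(
        c_xrt_course=3082.20,
        c_pt_course=26_943.90,
        c_hearing_test=65.4,
        c_fitting_test=121.5,
        c_hearing_aid=2086.9,
        aid_lifetime=5,
    )
    econ = EconSettings(discount_rate=0.03, wtp=46_729.0, jpy_per_usd=107.0)
    ranges = {
        "os5_average": TriangularRange(0.75, 0.85, 0.94),
        "os5_high": TriangularRange(0.54, 0.70, 0.84),
        "hl_risk_xrt_average": TriangularRange(0.3699, 0.39, 0.41),
        "hl_risk_xrt_high": TriangularRange(0.4455, 0.4711, 0.4967),
        "hl_risk_pt_average": TriangularRange(0.0497, 0.1555, 0.2612),
        "hl_risk_pt_high": TriangularRange(0.1836, 0.2653, 0.3471),
        "p_high_risk": TriangularRange(0.25, 0.30, 0.35),
        "u_hl_eq5d": TriangularRange(0.784, 0.807, 0.830),
        "u_hl_hui3": TriangularRange(0.626, 0.644, 0.663),
        "u_hl_sf6d": TriangularRange(0.779, 0.792, 0.804),
        "c_xrt_course": TriangularRange(2311.7, 3082.20, 3852.8),
        "c_pt_course": TriangularRange(20_207.9, 26_943.90, 33_679.9),
        "c_hearing_aid": TriangularRange(1565.2, 2086.9, 2608.6),
        "c_hearing_test": TriangularRange(_pm25(65.4)[0], 65.4, _pm25(65.4)[1]),
        "c_fitting_test": TriangularRange(_pm25(121.5)[0], 121.5, _pm25(121.5)[1]),
        "discount_rate": TriangularRange(0.0, 0.03, 0.07),
    }
    p = ModelParams(
        avg_risk=avg, high_risk=high, p_high_risk=0.30,
        utilities=utilities, costs=costs, econ=econ, ranges=ranges,
    )
    p.validate()
    return p


# ----------------------------------------------------------------------
# Flat YAML serialization

_SCALAR_KEYS: dict[str, tuple[str, ...]] = {
    "os5_average": ("avg_risk", "os5"),
    "os5_high": ("high_risk", "os5"),
    "hl_risk_xrt_average": ("avg_risk", "hl_risk_xrt"),
    "hl_risk_xrt_high": ("high_risk", "hl_risk_xrt"),
    "hl_risk_pt_average": ("avg_risk", "hl_risk_pt"),
    "hl_risk_pt_high": ("high_risk", "hl_risk_pt"),
    "dose_xrt_average_gy": ("avg_risk", "dose_xrt_gy"),
    "dose_xrt_high_gy": ("high_risk", "dose_xrt_gy"),
    "dose_pt_average_gy": ("avg_risk", "dose_pt_gy"),
    "dose_pt_high_gy": ("high_risk", "dose_pt_gy"),
    "p_high_risk": ("p_high_risk",),
    "u_no_hl_eq5d": ("utilities", "EQ-5D", "u_no_hl"),
    "u_hl_eq5d": ("utilities", "EQ-5D", "u_hl"),
    "u_no_hl_hui3": ("utilities", "HUI3", "u_no_hl"),
    "u_hl_hui3": ("utilities", "HUI3", "u_hl"),
    "u_no_hl_sf6d": ("utilities", "SF-6D", "u_no_hl"),
    "u_hl_sf6d": ("utilities", "SF-6D", "u_hl"),
    "c_xrt_course": ("costs", "c_xrt_course"),
    "c_pt_course": ("costs", "c_pt_course"),
    "c_hearing_test": ("costs", "c_hearing_test"),
    "c_fitting_test": ("costs", "c_fitting_test"),
    "c_hearing_aid": ("costs", "c_hearing_aid"),
    "aid_lifetime": ("costs", "aid_lifetime"),
    "discount_rate": ("econ", "discount_rate"),
    "wtp": ("econ", "wtp"),
    "jpy_per_usd": ("econ", "jpy_per_usd"),
    "start_age": ("start_age",),
    "horizon_age": ("horizon_age",),
    "onset_start_year": ("onset_start_year",),
    "onset_plateau_year": ("onset_plateau_year",),
    "half_cycle_correction": ("half_cycle_correction",),
}


def params_to_dict(p: ModelParams) -> dict[str, Any]:
    """Flatten a ModelParams to the documented configuration mapping."""
    out: dict[str, Any] = {}
    for key, path in _SCALAR_KEYS.items():
        obj, leaf = _resolve(p, path)
        out[key] = getattr(obj, leaf)
    out["ranges"] = {
        name: {"low": r.low, "mode": r.mode, "high": r.high}
        for name, r in sorted(p.ranges.items())
    }
    return out


def params_from_dict(d: dict[str, Any]) -> ModelParams:
    """Build ModelParams from a (possibly partial) configuration mapping.

    Unknown keys raise :class:`ParamError` to catch typos; missing keys fall
    back to the defaults.
    """
    p = default_params()
    d = dict(d or {})
    ranges = d.pop("ranges", None)
    for key, value in d.items():
        if key not in _SCALAR_KEYS:
            raise ParamError(key, "unknown configuration key")
        obj, leaf = _resolve(p, _SCALAR_KEYS[key])
        setattr(obj, leaf, value)
    if ranges is not None:
        # a provided ranges mapping is authoritative and replaces the
        # default set in full (save_params always writes the full set)
        p.ranges = {}
        for name, spec in ranges.items():
            if name not in RANGED_PARAMS:
                raise ParamError(f"ranges[{name}]", "unknown ranged parameter")
            try:
                p.ranges[name] = TriangularRange(
                    float(spec["low"]), float(spec["mode"]), float(spec["high"])
                )
            except (KeyError, TypeError) as exc:
                raise ParamError(
                    f"ranges[{name}]", "expected mapping with low/mode/high"
                ) from exc
    p.validate()
    return p


def load_params(path: str | Path) -> ModelParams:
    """Load and validate a YAML configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParamError("<root>", "configuration must be a mapping")
    return params_from_dict(data)


def save_params(p: ModelParams, path: str | Path) -> None:
    """Write a configuration file that :func:`load_params` reads back exactly."""
    Path(path).write_text(
        yaml.safe_dump(params_to_dict(p), sort_keys=True, default_flow_style=False)
    )


def dump_params_json(p: ModelParams, path: str | Path) -> None:
    """Normalized JSON parameter dump for provenance logging."""
    Path(path).write_text(json.dumps(params_to_dict(p), indent=2, sort_keys=True))


def iter_ranged(p: ModelParams) -> Iterator[tuple[str, TriangularRange]]:
    """Ranged parameters in registry order."""
    for name in RANGED_PARAMS:
        if name in p.ranges:
            yield name, p.ranges[name]
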