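"""One-way (tornado) and probabilistic sensitivity analysis, and CEACs.

The tornado analysis re-evaluates the ICER with each uncertain parameter at
the low and high end of its range, holding everything else at base.  The
probabilistic analysis draws every ranged parameter jointly and
independently from a triangular(low, mode=base, high) distribution and
re-runs the full model for each draw.  The discount rate is one of the
varied parameters, drawn from triangular(0, 0.03, 0.07): all the model's
uncertain variables fluctuate simultaneously, and the acceptability
probabilities below 100% at the willingness-to-pay threshold arise chiefly
from high-discount draws combined with unfavourable proton-arm draws
(``include_discount=False`` restricts the sampling to the tabulated
parameter ranges).  Cost-effectiveness acceptability
curves report, per willingness-to-pay value, the fraction of draws with
positive incremental net monetary benefit; the "integrated" curve pools
the three utility instruments' draws with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .economics import compute_ce, compute_ce_all
from .mortality import LifeTable
from .params import (
    ModelParams, TriangularRange, UTILITY_INDEXES, UTILITY_RANGE_NAMES,
    RANGED_PARAMS, _resolve, set_param,
)

__all__ = [
    "sample_triangular",
    "TornadoEntry",
    "one_way",
    "PSAResult",
    "run_psa",
    "CEACCurve",
    "ceac",
    "default_wtp_grid",
]


def sample_triangular(rng: np.random.Generator, tr: TriangularRange,
                      size: int | None = None):
    """Inverse-CDF draw(s) from Triangular(low, mode, high)."""
    u = rng.random(size)
    return triangular_ppf(u, tr.low, tr.mode, tr.high)


def triangular_ppf(u, low: float, mode: float, high: float):
    """Quantile function of the triangular distribution."""
    u = np.asarray(u, dtype=float)
    width = high - low
    if width == 0.0:
        out = np.full_like(u, mode)
        return float(out) if out.ndim == 0 else out
    fc = (mode - low) / width
    left = low + np.sqrt(u * width * (mode - low))
    right = high - np.sqrt((1.0 - u) * width * (high - mode))
    out = np.where(u < fc, left, right)
    # guard the degenerate edges (mode == low or mode == high)
    out = np.clip(out, low, high)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# One-way (tornado)

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _index_ranged_names(params: ModelParams, utility_index: str) -> list[str]:
    """Ranged parameters relevant to one utility instrument's analysis:
    every ranged parameter except the other instruments' utilities."""
    other_utils = {
        name for idx, name in UTILITY_RANGE_NAMES.items() if idx != utility_index
    }
    return [n for n in RANGED_PARAMS
            if n in params.ranges and n not in other_utils]


def one_way(params: ModelParams, life_table: LifeTable,
            utility_index: str) -> list[TornadoEntry]:
    """Tornado analysis: ICER at each parameter's range endpoints.

    Entries are sorted by descending spread.
    """
    entries = []
    for name in _index_ranged_names(params, utility_index):
        tr = params.ranges[name]
        icers = []
        for value in (tr.low, tr.high):
            res = compute_ce(set_param(params, name, value),
                             life_table, utility_index)
            icers.append(res.icer if res.icer_defined else np.nan)
        entries.append(TornadoEntry(name, icers[0], icers[1]))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "icer_at_low": e.icer_at_low,
         "icer_at_high": e.icer_at_high, "spread": e.spread}
        for e in entries
    ])


# ----------------------------------------------------------------------
# Probabilistic sensitivity analysis

def psa_param_names(params: ModelParams,
                    include_discount: bool = True) -> list[str]:
    """Parameters sampled in the PSA: every ranged parameter, the discount
    rate included by default."""
    return [n for n in RANGED_PARAMS
            if n in params.ranges
            and (include_discount or n != "discount_rate")]


def _apply_draw(base: ModelParams, names: Sequence[str],
                values: Sequence[float]) -> ModelParams:
    p = base.copy()
    for name, value in zip(names, values):
        obj, leaf = _resolve(p, RANGED_PARAMS[name])
        setattr(obj, leaf, float(value))
    return p


@dataclass
class PSAResult:
    """Monte Carlo parameter draws with their incremental outcomes.

    ``samples`` holds one tidy DataFrame per utility instrument, each with
    the drawn parameter values, ``delta_cost``, ``delta_qaly`` and a
    ``risk_order_violated`` flag (proton risk drawn above photon risk in
    either group; draws are kept as drawn, only flagged).
    """

    seed: int
    n: int
    samples: dict[str, pd.DataFrame]

    def pooled(self, indexes: Sequence[str] = UTILITY_INDEXES) -> pd.DataFrame:
        """Equal-weight pool of the per-instrument sample sets."""
        return pd.concat(
            [self.samples[i] for i in indexes], ignore_index=True
        )


def run_psa(params: ModelParams, life_table: LifeTable, n: int,
            seed: int, include_discount: bool = True) -> PSAResult:
    """Joint triangular Monte Carlo over all ranged parameters.

    Each of the ``n`` iterations draws every PSA parameter once and runs the
    full model; incremental outcomes are recorded per utility instrument
    (the cost difference depends on the drawn discount rate only, the QALY
    difference additionally uses that instrument's drawn utility).  Fully
    reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = psa_param_names(params, include_discount)
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(names)))
    draws = np.empty_like(u)
    for j, name in enumerate(names):
        tr = params.ranges[name]
        draws[:, j] = triangular_ppf(u[:, j], tr.low, tr.mode, tr.high)

    rows = {idx: [] for idx in UTILITY_INDEXES}
    i_pt_avg = names.index("hl_risk_pt_average")
    i_xrt_avg = names.index("hl_risk_xrt_average")
    i_pt_high = names.index("hl_risk_pt_high")
    i_xrt_high = names.index("hl_risk_xrt_high")
    for i in range(n):
        p = _apply_draw(params, names, draws[i])
        flagged = (
            draws[i, i_pt_avg] >= draws[i, i_xrt_avg]
            or draws[i, i_pt_high] >= draws[i, i_xrt_high]
        )
        results = compute_ce_all(p, life_table)
        base_row = dict(zip(names, draws[i]))
        base_row["draw"] = i
        base_row["risk_order_violated"] = flagged
        for idx in UTILITY_INDEXES:
            row = dict(base_row)
            row["utility_index"] = idx
            row["delta_cost"] = results[idx].delta_cost
            row["delta_qaly"] = results[idx].delta_qaly
            rows[idx].append(row)

    samples = {idx: pd.DataFrame(rows[idx]) for idx in UTILITY_INDEXES}
    return PSAResult(seed=seed, n=n, samples=samples)


# ----------------------------------------------------------------------
# Cost-effectiveness acceptability curves

def default_wtp_grid() -> np.ndarray:
    """0 to 150,000 USD/QALY in 1,000-unit steps, plus the 46,729 threshold."""
    grid = np.arange(0.0, 150_001.0, 1000.0)
    return np.unique(np.concatenate([grid, [46_729.0]]))


@dataclass(frozen=True)
class CEACCurve:
    scope: str               # one utility instrument or "integrated"
    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        """Acceptance probability at a grid value (exact match required)."""
        idx = np.nonzero(self.wtp == wtp)[0]
        if idx.size == 0:
            raise KeyError(f"wtp {wtp!r} not on the curve's grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wtp": self.wtp, "p_acceptable": self.probability,
            "scope": self.scope,
        })


def ceac(samples: pd.DataFrame, wtp_grid: np.ndarray | None = None,
         scope: str = "") -> CEACCurve:
    """Acceptability curve from PSA samples.

    At each willingness-to-pay value, the probability is the fraction of
    draws whose net monetary benefit (wtp * delta_qaly - delta_cost) is
    positive.
    """
    if len(samples) == 0:
        raise ValueError("empty PSA sample set")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    prob = np.mean(nmb > 0.0, axis=1)
    return CEACCurve(scope=scope, wtp=grid, probability=prob)


def all_ceacs(psa: PSAResult,
              wtp_grid: np.ndarray | None = None) -> dict[str, CEACCurve]:
    """Per-instrument curves plus the integrated (pooled) curve."""
    out = {
        idx: ceac(psa.samples[idx], wtp_grid, scope=idx)
        for idx in UTILITY_INDEXES
    }
    out["integrated"] = ceac(psa.pooled(), wtp_grid, scope="integrated")
    return out
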