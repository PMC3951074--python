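"""High-level model object tying the pipeline together.

``CostUtilityModel`` bundles a parameter set and a life table;
``fit()`` evaluates the Markov model for both arms and returns a
``CostUtilityResults`` object carrying the per-instrument incremental
results, with ``summary()`` for a readable table and methods for the
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import CEResult, compute_ce_all, net_monetary_benefit, results_frame
from .mortality import LifeTable, load_life_table
from .params import ModelParams, default_params, load_params, UTILITY_INDEXES
from .sensitivity import (
    CEACCurve, PSAResult, TornadoEntry, all_ceacs, one_way, run_psa,
)


class CostUtilityModel:
    """Lifetime Markov cost-utility comparison of proton vs photon therapy."""

    def __init__(self, params: ModelParams | None = None,
                 life_table: LifeTable | None = None):
        if params is None:
            params = default_params()
        if life_table is None:
            from .synthetic import bundled_life_table
            life_table = bundled_life_table()
        params.validate()
        self.params = params
        self.life_table = life_table

    @classmethod
    def from_files(cls, config: str | Path | None = None,
                   life_table: str | Path | None = None) -> "CostUtilityModel":
        p = load_params(config) if config else None
        lt = None
        if life_table:
            lt = load_life_table(life_table, max_age=None)
        m = cls(p, lt)
        # the table must cover the model horizon
        if m.life_table.max_age < m.params.horizon_age:
            raise ValueError(
                f"life table ends at age {m.life_table.max_age}, "
                f"model horizon is {m.params.horizon_age}"
            )
        return m

    def fit(self) -> "CostUtilityResults":
        """Run the base-case analysis for all three utility instruments."""
        return CostUtilityResults(self, compute_ce_all(self.params, self.life_table))

    # convenience passthroughs -----------------------------------------
    def tornado(self, utility_index: str) -> list[TornadoEntry]:
        return one_way(self.params, self.life_table, utility_index)

    def psa(self, n: int = 10_000, seed: int = 20240101,
            include_discount: bool = True) -> PSAResult:
        return run_psa(self.params, self.life_table, n, seed, include_discount)


@dataclass
class CostUtilityResults:
    """Base-case results for the three utility instruments."""

    model: CostUtilityModel
    by_index: dict[str, CEResult]

    def __getitem__(self, index: str) -> CEResult:
        return self.by_index[index]

    def frame(self) -> pd.DataFrame:
        return results_frame(self.by_index.values())

    def ceacs(self, psa: PSAResult) -> dict[str, CEACCurve]:
        return all_ceacs(psa)

    def summary(self) -> str:
        wtp = self.model.params.econ.wtp
        lines = [
            "Cost-utility analysis: proton beam vs X-ray radiotherapy",
            f"(cohort age {self.model.params.start_age} to "
            f"{self.model.params.horizon_age}, discount "
            f"{self.model.params.econ.discount_rate:.1%}, "
            f"WTP ${wtp:,.0f}/QALY)",
            "",
            f"{'index':<7}{'cost XRT':>12}{'cost PT':>12}"
            f"{'QALY XRT':>10}{'QALY PT':>10}"
            f"{'dCost':>10}{'dQALY':>8}{'ICER':>10}{'NMB':>10}",
        ]
        for idx in UTILITY_INDEXES:
            r = self.by_index[idx]
            icer = f"{r.icer:,.0f}" if r.icer_defined else "undef"
            lines.append(
                f"{idx:<7}{r.cost_xrt:>12,.2f}{r.cost_pt:>12,.2f}"
                f"{r.qaly_xrt:>10.2f}{r.qaly_pt:>10.2f}"
                f"{r.delta_cost:>10,.0f}{r.delta_qaly:>8.2f}"
                f"{icer:>10}{net_monetary_benefit(r, wtp):>10,.0f}"
            )
        return "\n".join(lines)
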