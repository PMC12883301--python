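"""Scenario runner and tabular reporting.

Runs the model x IVa-surgery-rate grid, one upfront and one FNAC-first
cohort per combination, and collects per-arm cost summaries plus the
FNAC-vs-upfront savings into a flat table — the tabular equivalent of the
cost-distribution figures usually shown for such analyses.  The
complication table is purely descriptive: complication rates are reported
alongside but never enter the simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .builder import ArmSpec, apply_iva_scenario, build_fnac_arm, build_upfront_arm
from .params import (
    BUILTIN_MODEL_IDS,
    CostTable,
    ModelParameters,
    builtin_cost_table,
    builtin_currency,
    builtin_parameters,
)
from .simulate import SimSummary, compare_arms, simulate, substream
from .tree import expected_cost

__all__ = ["ScenarioGrid", "run_scenarios", "complication_table", "DEFAULT_IVA_RATES"]

DEFAULT_IVA_RATES: Tuple[float, ...] = (1.0, 0.7, 0.0)


@dataclass
class ScenarioGrid:
    """A cross-product of cohort models and IVa surgery-rate scenarios."""

    models: Sequence[str] = BUILTIN_MODEL_IDS
    iva_rates: Sequence[float] = DEFAULT_IVA_RATES
    n: int = 10_000
    seed: int = 0
    out_dir: Optional[Path] = None
    params_overrides: Dict[str, ModelParameters] = field(default_factory=dict)
    costs_overrides: Dict[str, CostTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("models: at least one model id required")
        if not self.iva_rates:
            raise ValueError("iva_rates: at least one rate required")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for r in self.iva_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"iva_rates: {r!r} outside [0, 1]")

    def resolve(self, model_id: str) -> Tuple[ModelParameters, CostTable]:
        params = self.params_overrides.get(model_id)
        if params is None:
            params = builtin_parameters(model_id)
        costs = self.costs_overrides.get(model_id)
        if costs is None:
            costs = builtin_cost_table(builtin_currency(model_id))
        return params, costs


def _summary_row(summary: SimSummary, analytic: float) -> dict:
    md = summary.metadata
    return {
        "model": md.get("model_id"),
        "arm": md.get("arm"),
        "iva_rate": md.get("iva_surgery_rate"),
        "currency": summary.currency,
        "n": summary.n,
        "mean": round(summary.mean),
        "mean_exact": summary.mean,
        "sd": summary.sd,
        "se": summary.se,
        "median": summary.median,
        "q025": summary.q025,
        "q975": summary.q975,
        "analytic_expected": analytic,
    }


def run_scenarios(grid: ScenarioGrid) -> pd.DataFrame:
    """Run every (model, arm, IVa rate) combination of ``grid``.

    Returns one row per simulated arm: the upfront arm once per model (it
    does not depend on the IVa rate) and the FNAC-first arm once per rate,
    the latter carrying the absolute and truncated-percent saving against
    the upfront arm.  Reproducible per seed: each combination draws from
    its own sub-stream of the master seed.  ``mean`` is rounded to whole
    currency units for presentation; ``mean_exact`` keeps full precision.
    """
    rows = []
    for mi, model_id in enumerate(grid.models):
        params, costs = grid.resolve(model_id)
        spec = ArmSpec(params=params, costs=costs)
        upfront_tree = build_upfront_arm(spec)
        upfront = simulate(upfront_tree, n=grid.n, seed=substream(grid.seed, mi, 0))
        upfront.seed = grid.seed
        rows.append(_summary_row(upfront, expected_cost(upfront_tree)))
        for ri, rate in enumerate(grid.iva_rates):
            scen_params = apply_iva_scenario(params, rate)
            fnac_tree = build_fnac_arm(ArmSpec(params=scen_params, costs=costs))
            fnac = simulate(fnac_tree, n=grid.n, seed=substream(grid.seed, mi, 1 + ri))
            fnac.seed = grid.seed
            row = _summary_row(fnac, expected_cost(fnac_tree))
            red = compare_arms(upfront, fnac)
            row.update(
                upfront_mean=upfront.mean,
                absolute_saving=red.absolute_saving,
                percent_saving=red.percent_saving,
                percent_saving_truncated=red.percent_saving_truncated,
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    if "percent_saving_truncated" in table:
        table["percent_saving_truncated"] = table["percent_saving_truncated"].astype("Int64")
    if grid.out_dir is not None:
        _write_outputs(grid, table)
    return table


def _write_outputs(grid: ScenarioGrid, table: pd.DataFrame) -> None:
    out = Path(grid.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "scenario_results.csv", index=False)
    meta = {
        "models": list(grid.models),
        "iva_rates": [float(r) for r in grid.iva_rates],
        "n": grid.n,
        "seed": grid.seed,
        "parameter_fingerprint": {
            m: grid.resolve(m)[0].model_dump(mode="json") for m in grid.models
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    complication_table().to_csv(out / "complications.csv", index=False)


_COMPLICATIONS = [
    ("FNAC (ultrasound-guided)", "< 1"),
    ("Partial parotidectomy", "3.5"),
    ("Submandibulectomy", "3.4-7.7"),
    ("Total parotidectomy + neck dissection", "13.9"),
    ("Submandibulectomy + neck dissection", "11-52"),
    ("Neck dissection", "11-52"),
]


def complication_table() -> pd.DataFrame:
    """Descriptive complication-rate table (percent, literature estimates).

    Reported for context only; complication costs are deliberately not part
    of the simulated pathways.
    """
    return pd.DataFrame(_COMPLICATIONS, columns=["procedure", "complication_rate_pct"])


def cost_histogram(costs: np.ndarray, bins: int = 50) -> pd.DataFrame:
    """Binned cohort cost counts (CSV-friendly re-plotting support)."""
    counts, edges = np.histogram(costs, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
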