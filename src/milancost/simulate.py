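"""Seeded Monte Carlo cohort simulation over a decision tree.

Each simulated patient is one root-to-terminal walk: every chance node is
resolved by a single uniform draw tested against the cumulative branch
probabilities in declared branch order, decision nodes follow their chosen
branch, and incremental costs accumulate along the way.  With a fixed seed
the trajectory sequence — and therefore every summary statistic — is
bit-reproducible.

Sub-streams are derived from a single master seed via
``numpy.random.SeedSequence(master_seed, spawn_key=...)`` so that each
(model, arm, scenario) combination has its own independent, reproducible
stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .tree import DecisionTree, InvalidTreeError, expected_cost, validate_tree

__all__ = [
    "Trajectory",
    "SimSummary",
    "CostReduction",
    "sample_trajectory",
    "simulate",
    "compare_arms",
    "convergence_check",
    "substream",
]


@dataclass
class Trajectory:
    """One simulated patient: event sequence and accumulated cost."""

    events: List[str]
    total_cost: float
    is_malignant: bool
    n_fnac: int
    n_surgeries: int


@dataclass
class SimSummary:
    """Per-arm cost distribution summary of one simulated cohort."""

    n: int
    seed: Optional[int]
    mean: float
    sd: float
    se: float
    median: float
    q025: float
    q975: float
    currency: str
    metadata: dict = field(default_factory=dict)
    costs: Optional[np.ndarray] = None
    n_malignant: int = 0
    mean_fnac: float = 0.0
    mean_surgeries: float = 0.0


@dataclass
class CostReduction:
    """FNAC-first versus upfront-surgery saving per case.

    ``percent_saving_truncated`` is the percentage truncated toward zero
    (not rounded), the convention used for reporting; the full-precision
    percentage is kept alongside.
    """

    upfront_mean: float
    fnac_mean: float

    @property
    def absolute_saving(self) -> float:
        return self.upfront_mean - self.fnac_mean

    @property
    def percent_saving(self) -> float:
        return 100.0 * self.absolute_saving / self.upfront_mean

    @property
    def percent_saving_truncated(self) -> int:
        return math.trunc(self.percent_saving)


def sample_trajectory(tree: DecisionTree, rng: np.random.Generator) -> Trajectory:
    """Draw one patient trajectory from ``tree`` using ``rng``.

    Assumes the tree has already been validated (``simulate`` validates
    once per cohort).
    """
    events: List[str] = []
    cost = 0.0
    malignant = False
    n_fnac = 0
    n_surgeries = 0
    node = tree.root
    while True:
        events.append(node.label)
        cost += node.incremental_cost
        if "malignant" in node.tags:
            malignant = True
        if "fnac" in node.tags:
            n_fnac += 1
        if "surgery" in node.tags:
            n_surgeries += 1
        if node.kind == "terminal":
            return Trajectory(events, cost, malignant, n_fnac, n_surgeries)
        if node.kind == "decision":
            (branch,) = [b for b in node.branches if b.chosen]
            node = branch.child
            continue
        u = rng.random()
        acc = 0.0
        branch = node.branches[-1]  # numerical guard: residual mass -> last branch
        for b in node.branches:
            acc += b.probability
            if u < acc:
                branch = b
                break
        node = branch.child


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator derived from a master seed and an integer key."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def simulate(
    tree: DecisionTree,
    n: int = 10_000,
    seed: Union[int, np.random.Generator, None] = 0,
    keep: bool = False,
) -> SimSummary:
    """Simulate a cohort of ``n`` patients through ``tree``.

    Parameters
    ----------
    tree
        A valid decision tree.
    n
        Cohort size (the analyses here use 10,000 by default).
    seed
        Integer seed, ready-made ``numpy`` generator, or None for
        nondeterministic entropy.
    keep
        Retain the per-patient cost vector on the summary (``costs``).
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    violations = validate_tree(tree)
    if violations:
        raise InvalidTreeError("; ".join(violations))
    if isinstance(seed, np.random.Generator):
        rng, seed_repr = seed, None
    else:
        rng, seed_repr = np.random.default_rng(seed), seed

    costs = np.empty(n)
    n_malignant = 0
    total_fnac = 0
    total_surgeries = 0
    for i in range(n):
        traj = sample_trajectory(tree, rng)
        costs[i] = traj.total_cost
        n_malignant += traj.is_malignant
        total_fnac += traj.n_fnac
        total_surgeries += traj.n_surgeries

    sd = float(np.std(costs, ddof=1)) if n > 1 else 0.0
    q025, median, q975 = np.quantile(costs, [0.025, 0.5, 0.975])
    return SimSummary(
        n=n,
        seed=seed_repr,
        mean=float(np.mean(costs)),
        sd=sd,
        se=sd / math.sqrt(n),
        median=float(median),
        q025=float(q025),
        q975=float(q975),
        currency=tree.currency.value,
        metadata=dict(tree.metadata),
        costs=costs if keep else None,
        n_malignant=int(n_malignant),
        mean_fnac=total_fnac / n,
        mean_surgeries=total_surgeries / n,
    )


def trajectories_frame(tree: DecisionTree, n: int, seed: int) -> pd.DataFrame:
    """Per-patient trajectory table (for CSV export)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        t = sample_trajectory(tree, rng)
        rows.append(
            {
                "patient_id": i,
                "events": " -> ".join(t.events),
                "is_malignant": t.is_malignant,
                "n_fnac": t.n_fnac,
                "n_surgeries": t.n_surgeries,
                "cost": t.total_cost,
            }
        )
    return pd.DataFrame(rows)


def compare_arms(upfront: SimSummary, fnac: SimSummary) -> CostReduction:
    """Cost reduction of FNAC-first relative to upfront surgery.

    Both summaries must come from the same jurisdiction (currency) and the
    same cohort model.
    """
    if upfront.currency != fnac.currency:
        raise ValueError(
            f"currency mismatch: {upfront.currency} vs {fnac.currency}"
        )
    mu = upfront.metadata.get("model_id")
    mf = fnac.metadata.get("model_id")
    if mu is not None and mf is not None and mu != mf:
        raise ValueError(f"model mismatch: {mu!r} vs {mf!r}")
    return CostReduction(upfront_mean=upfront.mean, fnac_mean=fnac.mean)


@dataclass
class ConvergenceReport:
    expected: float
    mean: float
    se: float
    z: float
    ok: bool


def convergence_check(tree: DecisionTree, summary: SimSummary) -> ConvergenceReport:
    """Compare the Monte Carlo mean to the exact tree expectation.

    Flags the run if the mean deviates by more than 3.5 standard errors
    (false-alarm probability < 1/2000 per check).  Deterministic trees
    (se = 0) must match exactly.
    """
    exact = expected_cost(tree)
    if summary.se == 0.0:
        ok = math.isclose(summary.mean, exact, rel_tol=1e-12, abs_tol=1e-9)
        z = 0.0 if ok else math.inf
    else:
        z = (summary.mean - exact) / summary.se
        ok = abs(z) <= 3.5
    return ConvergenceReport(expected=exact, mean=summary.mean, se=summary.se, z=z, ok=ok)
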