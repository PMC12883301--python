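"""Decision-tree representation and two independent exact evaluators.

Costs attach to nodes as increments: the cost of a root-to-terminal path is
the sum of the incremental costs of every node on it.  Expected cost can be
computed two ways — recursive roll-back (:func:`expected_cost`) and
exhaustive path enumeration (:func:`enumerate_paths`) — which serve as each
other's oracle in the test suite.

Decision nodes are not optimized over: each carries exactly one branch
marked ``chosen``, because the analysis compares fixed strategies rather
than solving for a policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pandas as pd

from .params import SUM_TOL, Currency

__all__ = [
    "Node",
    "Branch",
    "DecisionTree",
    "InvalidTreeError",
    "terminal",
    "chance",
    "decision",
    "validate_tree",
    "expected_cost",
    "enumerate_paths",
    "tree_to_text",
    "tree_to_json",
]

#: relative tolerance when comparing the two exact evaluators
ORACLE_RTOL = 1e-6


class InvalidTreeError(ValueError):
    """Raised when a structurally invalid tree is evaluated."""


@dataclass
class Branch:
    child: "Node"
    probability: Optional[float] = None  # None on decision branches
    chosen: bool = False
    label: str = ""


@dataclass
class Node:
    kind: str  # "decision" | "chance" | "terminal"
    label: str
    incremental_cost: float = 0.0
    branches: List[Branch] = field(default_factory=list)
    tags: frozenset = frozenset()


def terminal(label: str, cost: float = 0.0, tags=()) -> Node:
    return Node("terminal", label, cost, [], frozenset(tags))


def chance(label: str, cost: float, branches: List[Tuple[float, Node]], tags=()) -> Node:
    return Node(
        "chance",
        label,
        cost,
        [Branch(child=c, probability=p) for p, c in branches],
        frozenset(tags),
    )


def decision(label: str, cost: float, options: List[Tuple[str, Node]], chosen: str) -> Node:
    branches = [
        Branch(child=c, label=name, chosen=(name == chosen)) for name, c in options
    ]
    if sum(b.chosen for b in branches) != 1:
        raise ValueError(f"decision {label!r}: chosen option {chosen!r} not among options")
    return Node("decision", label, 0.0, branches, frozenset())


@dataclass
class DecisionTree:
    root: Node
    currency: Currency
    metadata: Dict[str, object] = field(default_factory=dict)


def validate_tree(tree: DecisionTree) -> List[str]:
    """Return a list of invariant violations; empty iff the tree is valid.

    Checks: branch probabilities in [0, 1] summing to one at chance nodes,
    exactly one chosen branch at decision nodes, non-negative incremental
    costs, terminals without branches, and tree-ness (single parent, no
    cycles).
    """
    violations: List[str] = []
    seen: set = set()

    def walk(node: Node, path: str) -> None:
        here = f"{path}/{node.label}"
        if id(node) in seen:
            violations.append(f"{here}: node reachable via multiple parents (not a tree)")
            return
        seen.add(id(node))
        if node.incremental_cost < 0:
            violations.append(f"{here}: negative incremental_cost {node.incremental_cost}")
        if node.kind == "terminal":
            if node.branches:
                violations.append(f"{here}: terminal node has branches")
            return
        if not node.branches:
            violations.append(f"{here}: {node.kind} node has no branches")
            return
        if node.kind == "chance":
            total = 0.0
            for b in node.branches:
                p = b.probability
                if p is None or not (0.0 <= p <= 1.0):
                    violations.append(f"{here}: branch probability {p!r} outside [0, 1]")
                else:
                    total += p
            if abs(total - 1.0) > SUM_TOL:
                violations.append(f"{here}: branch probabilities sum to {total!r}")
        elif node.kind == "decision":
            if sum(b.chosen for b in node.branches) != 1:
                violations.append(f"{here}: decision node needs exactly one chosen branch")
        else:
            violations.append(f"{here}: unknown node kind {node.kind!r}")
        for b in node.branches:
            walk(b.child, here)

    walk(tree.root, "")
    return violations


def _require_valid(tree: DecisionTree) -> None:
    violations = validate_tree(tree)
    if violations:
        raise InvalidTreeError("; ".join(violations))


def expected_cost(tree: DecisionTree) -> float:
    """Exact expected path cost by recursive roll-back."""
    _require_valid(tree)

    def roll(node: Node) -> float:
        if node.kind == "terminal":
            return node.incremental_cost
        if node.kind == "decision":
            (chosen,) = [b for b in node.branches if b.chosen]
            return node.incremental_cost + roll(chosen.child)
        return node.incremental_cost + sum(
            b.probability * roll(b.child) for b in node.branches
        )

    return roll(tree.root)


def enumerate_paths(tree: DecisionTree) -> pd.DataFrame:
    """Exhaustive root-to-terminal path table.

    Returns a DataFrame with columns ``path`` (" -> "-joined node labels),
    ``probability`` and ``cost``.  Its probability-weighted mean cost is the
    brute-force counterpart of :func:`expected_cost`.
    """
    _require_valid(tree)
    rows: List[Tuple[str, float, float]] = []

    def walk(node: Node, labels: List[str], prob: float, cost: float) -> None:
        labels = labels + [node.label]
        cost += node.incremental_cost
        if node.kind == "terminal":
            rows.append((" -> ".join(labels), prob, cost))
            return
        if node.kind == "decision":
            (chosen,) = [b for b in node.branches if b.chosen]
            walk(chosen.child, labels, prob, cost)
            return
        for b in node.branches:
            walk(b.child, labels, prob * b.probability, cost)

    walk(tree.root, [], 1.0, 0.0)
    return pd.DataFrame(rows, columns=["path", "probability", "cost"])


def path_expected_cost(paths: pd.DataFrame) -> float:
    """Expectation from a path table: sum of probability * cost."""
    return float((paths["probability"] * paths["cost"]).sum())


def iter_nodes(tree: DecisionTree) -> Iterator[Node]:
    stack = [tree.root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(b.child for b in node.branches)


def tree_to_text(tree: DecisionTree) -> str:
    """Indented plain-text rendering for documentation and diffing."""
    lines: List[str] = []

    def walk(node: Node, prefix: str, edge: str) -> None:
        cost = f" +{node.incremental_cost:g}" if node.incremental_cost else ""
        lines.append(f"{prefix}{edge}[{node.kind}] {node.label}{cost}")
        for b in node.branches:
            if node.kind == "chance":
                tag = f"(p={b.probability:g}) "
            else:
                tag = "(chosen) " if b.chosen else f"({b.label or 'option'}) "
            walk(b.child, prefix + "  ", tag)

    walk(tree.root, "", "")
    return "\n".join(lines)


def tree_to_json(tree: DecisionTree) -> str:
    def node_dict(node: Node) -> dict:
        return {
            "kind": node.kind,
            "label": node.label,
            "incremental_cost": node.incremental_cost,
            "tags": sorted(node.tags),
            "branches": [
                {
                    "probability": b.probability,
                    "chosen": b.chosen,
                    "label": b.label,
                    "child": node_dict(b.child),
                }
                for b in node.branches
            ],
        }

    return json.dumps(
        {
            "currency": tree.currency.value,
            "metadata": tree.metadata,
            "root": node_dict(tree.root),
        },
        indent=2,
    )
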