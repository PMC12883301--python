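import numpy as np
import pytest

from milancost import (
    ArmSpec,
    MilanCategory,
    ModelParameters,
    builtin_cost_table,
    builtin_parameters,
)
from milancost.params import builtin_currency
from milancost.tree import DecisionTree, Node, chance, terminal
from milancost.params import Currency


@pytest.fixture(scope="session")
def params_1a():
    return builtin_parameters("1a")


@pytest.fixture(scope="session")
def params_1b():
    return builtin_parameters("1b")


@pytest.fixture(scope="session")
def params_1c():
    return builtin_parameters("1c")


@pytest.fixture(scope="session")
def usd_costs():
    return builtin_cost_table("USD")


@pytest.fixture(scope="session")
def eur_costs():
    return builtin_cost_table("EUR")


def builtin_spec(model_id: str) -> ArmSpec:
    return ArmSpec(
        params=builtin_parameters(model_id),
        costs=builtin_cost_table(builtin_currency(model_id)),
    )


def concentrated_params(
    category: MilanCategory,
    base: ModelParameters,
    second_category: MilanCategory = None,
    **overrides,
) -> ModelParameters:
    """Parameters with all category mass on one category (structural tests)."""
    dist = {c: 1.0 if c is category else 0.0 for c in MilanCategory}
    second = dist
    if second_category is not None:
        second = {c: 1.0 if c is second_category else 0.0 for c in MilanCategory}
    return base.model_copy(
        update={"category_dist": dist, "second_fnac_dist": second, **overrides}
    )


def toy_two_branch(p: float = 0.5, lo: float = 0.0, hi: float = 100.0) -> DecisionTree:
    root = chance(
        "toss", 0.0, [(p, terminal("hi", hi)), (1.0 - p, terminal("lo", lo))]
    )
    return DecisionTree(root=root, currency=Currency.USD)


def random_tree(rng: np.random.Generator, max_depth: int = 6, max_branch: int = 4) -> DecisionTree:
    """Random finite tree with chance/terminal nodes (oracle-equivalence tests)."""

    counter = [0]

    def make(depth: int) -> Node:
        counter[0] += 1
        label = f"n{counter[0]}"
        cost = float(rng.uniform(0, 1000))
        if depth >= max_depth or rng.random() < 0.3:
            return terminal(label, cost)
        k = int(rng.integers(2, max_branch + 1))
        raw = rng.dirichlet(np.ones(k))
        probs = raw / raw.sum()
        probs[-1] = 1.0 - probs[:-1].sum()
        return chance(label, cost, [(float(p), make(depth + 1)) for p in probs])

    root = make(0)
    if root.kind == "terminal":  # ensure at least one branching level
        root = chance("root", 0.0, [(1.0, root)])
    return DecisionTree(root=root, currency=Currency.USD)
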