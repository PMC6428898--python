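import random

import pytest

from rxncycle import (
    DelaySpec,
    build_minicdc,
    compile_network,
    g0_attractor,
)
from rxncycle.compile import And, BooleanNetwork, Const, Expr, NodeKind, NodeSpec, Not, Or, Ref


@pytest.fixture(scope="session")
def minicdc():
    return build_minicdc()


@pytest.fixture(scope="session")
def minicdc_network(minicdc):
    return compile_network(minicdc.system, minicdc.default_delays())


@pytest.fixture(scope="session")
def minicdc_g0(minicdc_network):
    return g0_attractor(minicdc_network)


@pytest.fixture(scope="session")
def minicdc_wt(minicdc_network, minicdc_g0):
    from rxncycle import find_attractor

    return find_attractor(
        minicdc_network, minicdc_g0.states[0], {"[Nutrients]": True}
    )


# ---------------------------------------------------------------------------
# random Boolean networks (for oracle-equivalence properties)
# ---------------------------------------------------------------------------

def random_expr(rng: random.Random, ids: list[str], depth: int = 2) -> Expr:
    if depth == 0 or rng.random() < 0.4:
        r = rng.random()
        if r < 0.1:
            return Const(rng.random() < 0.5)
        return Ref(rng.choice(ids))
    op = rng.choice(["and", "or", "not"])
    if op == "not":
        return Not(random_expr(rng, ids, depth - 1))
    k = rng.randint(2, 3)
    children = tuple(random_expr(rng, ids, depth - 1) for _ in range(k))
    return And(children) if op == "and" else Or(children)


def random_network(seed: int, max_nodes: int = 14) -> BooleanNetwork:
    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    ids = [f"n{i}" for i in range(n)]
    nodes = [
        NodeSpec(i, NodeKind.STATE, random_expr(rng, ids), neutral=rng.random() < 0.5)
        for i in ids
    ]
    initial = {i: rng.random() < 0.5 for i in ids}
    return BooleanNetwork(nodes, initial)


# ---------------------------------------------------------------------------
# independent brute-force oracle (naive recursive evaluation, list scan)
# ---------------------------------------------------------------------------

def naive_eval(expr: Expr, values: dict) -> bool:
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Ref):
        return values[expr.target]
    if isinstance(expr, Not):
        return not naive_eval(expr.child, values)
    if isinstance(expr, And):
        return all(naive_eval(c, values) for c in expr.children)
    if isinstance(expr, Or):
        return any(naive_eval(c, values) for c in expr.children)
    raise TypeError(type(expr))


def naive_step(network: BooleanNetwork, values: dict, clamps=None) -> dict:
    clamps = clamps or {}
    out = {}
    for node in network.nodes:
        if node.id in clamps:
            out[node.id] = clamps[node.id]
        else:
            out[node.id] = naive_eval(node.update, values)
    return out


def naive_attractor(network: BooleanNetwork, init=None, clamps=None, limit=40000):
    """Exhaustive trajectory simulation: record every visited state and stop
    at the first recurrence."""
    clamps = clamps or {}
    values = dict(init if init is not None else network.initial)
    values.update(clamps)
    keys: list[tuple] = []
    seen: set[tuple] = set()
    key = lambda v: tuple(v[n.id] for n in network.nodes)
    while len(keys) <= limit:
        k = key(values)
        if k in seen:
            start = keys.index(k)
            cycle = keys[start:]
            return start, len(cycle), cycle
        keys.append(k)
        seen.add(k)
        values = naive_step(network, values, clamps)
    raise AssertionError("oracle exceeded its own limit")
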