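"""Synchronous simulation and attractor detection.

All nodes update simultaneously from the previous state; clamped nodes take
their clamp value at every step, including step 0.  The dynamics are
deterministic, so the trajectory from any state eventually revisits a state
and the segment between first and second visit is the attractor: a point
attractor (period 1) or a cycle whose period is automatically minimal
(every state inside the detected loop was visited exactly once before).

Cycle detection hashes full state vectors with a first-seen-time dictionary,
which is exact and cheap at this scale (a few thousand nodes, periods of
hundreds).  Exceeding the step budget raises — never silently truncates.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .compile import BooleanNetwork, Const, Expr, Not, Ref, And, Or

Clamps = Mapping[str, bool]
NetworkState = tuple[bool, ...]


class BudgetExceededError(RuntimeError):
    """No recurrence found within the step budget."""

    def __init__(self, max_steps: int):
        super().__init__(f"no attractor found within {max_steps} steps")
        self.max_steps = max_steps


@dataclass
class Attractor:
    kind: str  # "point" | "cycle"
    period: int
    transient: int
    states: list[NetworkState]
    node_ids: list[str]
    initial: NetworkState
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    def values(self, node_id: str) -> list[bool]:
        """The node's value at each step of one attractor period."""
        i = self._index[node_id]
        return [s[i] for s in self.states]

    def is_point(self) -> bool:
        return self.kind == "point"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "period": self.period,
            "transient": self.transient,
            "nodes": self.node_ids,
            "states": [[int(v) for v in s] for s in self.states],
        }


def _expr_source(e: Expr, index: Mapping[str, int]) -> str:
    if isinstance(e, Const):
        return "True" if e.value else "False"
    if isinstance(e, Ref):
        return f"s[{index[e.target]}]"
    if isinstance(e, Not):
        return f"(not {_expr_source(e.child, index)})"
    if isinstance(e, And):
        return "(" + " and ".join(_expr_source(c, index) for c in e.children) + ")"
    if isinstance(e, Or):
        return "(" + " or ".join(_expr_source(c, index) for c in e.children) + ")"
    raise TypeError(type(e))


class _Stepper:
    """Pre-compiled synchronous update function for one (network, clamps)."""

    def __init__(self, network: BooleanNetwork, clamps: Clamps | None = None):
        clamps = dict(clamps or {})
        for node_id in clamps:
            require_node(network, node_id)
        index = network.index
        parts: list[str] = []
        for n in network.nodes:
            if n.id in clamps:
                parts.append("True" if clamps[n.id] else "False")
            else:
                parts.append(_expr_source(n.update, index))
        src = "lambda s: (" + ",".join(parts) + ("," if parts else "") + ")"
        self._fn = eval(src)  # noqa: S307 - generated from our own AST
        self._clamps = clamps
        self._network = network

    def clamp_state(self, state: NetworkState) -> NetworkState:
        if not self._clamps:
            return state
        out = list(state)
        for node_id, value in self._clamps.items():
            out[self._network.index[node_id]] = value
        return tuple(out)

    def __call__(self, state: NetworkState) -> NetworkState:
        return self._fn(state)


def require_node(network: BooleanNetwork, node_id: str) -> None:
    if node_id not in network.index:
        close = difflib.get_close_matches(node_id, network.index.keys(), n=3)
        hint = f"; did you mean {', '.join(close)}?" if close else ""
        raise KeyError(f"unknown node {node_id!r}{hint}")


def step(
    network: BooleanNetwork, state: NetworkState, clamps: Clamps | None = None
) -> NetworkState:
    """One synchronous update (clamped nodes keep their clamp value)."""
    stepper = _Stepper(network, clamps)
    return stepper(stepper.clamp_state(state))


def as_state(network: BooleanNetwork, values: Mapping[str, bool]) -> NetworkState:
    return tuple(bool(values[n.id]) for n in network.nodes)


def simulate(
    network: BooleanNetwork,
    init: NetworkState | None = None,
    clamps: Clamps | None = None,
    n_steps: int = 100,
) -> list[NetworkState]:
    """The trajectory ``[state_0, ..., state_n]`` (clamps applied from step 0)."""
    stepper = _Stepper(network, clamps)
    state = stepper.clamp_state(init if init is not None else network.initial_vector())
    trajectory = [state]
    for _ in range(n_steps):
        state = stepper(state)
        trajectory.append(state)
    return trajectory


def find_attractor(
    network: BooleanNetwork,
    init: NetworkState | None = None,
    clamps: Clamps | None = None,
    max_steps: int = 100_000,
) -> Attractor:
    """Iterate until a state recurs; return the attractor with minimal
    period and the transient length.  Deterministic given its inputs."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    stepper = _Stepper(network, clamps)
    state = stepper.clamp_state(init if init is not None else network.initial_vector())
    seen: dict[NetworkState, int] = {}
    trajectory: list[NetworkState] = []
    for t in range(max_steps + 1):
        if state in seen:
            t0 = seen[state]
            cycle = trajectory[t0:]
            return Attractor(
                kind="point" if len(cycle) == 1 else "cycle",
                period=len(cycle),
                transient=t0,
                states=cycle,
                node_ids=[n.id for n in network.nodes],
                initial=trajectory[0],
            )
        seen[state] = t
        trajectory.append(state)
        state = stepper(state)
    raise BudgetExceededError(max_steps)


def readout(
    source: Attractor | Sequence[NetworkState],
    network: BooleanNetwork,
    node_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-step Boolean table restricted to the requested nodes."""
    for node_id in node_ids:
        require_node(network, node_id)
    states = source.states if isinstance(source, Attractor) else list(source)
    data = {
        node_id: [int(s[network.index[node_id]]) for s in states] for node_id in node_ids
    }
    frame = pd.DataFrame(data)
    frame.index.name = "step"
    return frame


def run_phases(
    network: BooleanNetwork,
    phases: Sequence[Clamps],
    init: NetworkState | None = None,
    max_steps: int = 100_000,
) -> list[Attractor]:
    """Sequential release-then-arrest protocol: run to an attractor under
    each clamp set in turn, starting each phase from the first state of the
    previous phase's attractor."""
    attractors: list[Attractor] = []
    state = init
    for clamps in phases:
        attractor = find_attractor(network, state, clamps, max_steps)
        attractors.append(attractor)
        state = attractor.states[0]
    return attractors
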