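"""Compile a reaction-contingency system into a bipartite Boolean model.

The compiled network is parameter-free and uniquely defined by the system:
one Boolean node per elemental reaction, per elemental state (neutral states
included), per Boolean gate and per global (inputs, outputs and macro-cycle
states), plus optional delay chains implementing timescale separation.

Update-rule semantics are population-level: a state node means "this
elemental state is present in the population", so mutually exclusive states
may be simultaneously true and no exclusivity is enforced at runtime.

Rule builders
-------------
*Reaction nodes* fire when both reactants are present (presence factor = OR
over the component's state nodes) and the contingencies hold: requirement
(``!``) effectors conjoined, inhibition (``x``) effectors negated, Boolean
gates referenced through their own nodes, and quantitative ``k+``/``k-``
effectors contributing nothing in the Boolean regime.  Source states are
deliberately *not* part of the reaction rule: a reaction node reads as
"catalytic opportunity".

*State nodes* follow ``production OR (self AND NOT consumption)``, where
production requires the producing reaction together with its source states,
and consumption a consuming reaction with its other sources, or any active
degradation covering the state.  Degrading a bound component releases the
partner's unbound neutral.

*Delay chains* require a reaction's rule to hold over a window of
consecutive steps before the reaction fires, making transcription and
replication-progression reactions slow relative to signalling.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .core import (
    ElementalReaction,
    Modifier,
    RxnconSystem,
    RxnconError,
    SkeletonRule,
    State,
    StateKind,
    is_gate_id,
    is_global_id,
)
from .validate import validate

HISTONES = "[Histones]"
DEFAULT_DELAY = 20
REPLICATION_TAG = "replication"


class CompileError(RxnconError):
    pass


# ---------------------------------------------------------------------------
# update expressions
# ---------------------------------------------------------------------------

class Expr:
    """Immutable Boolean update-expression tree."""

    __slots__ = ()

    def refs(self) -> Iterator[str]:
        yield from ()


@dataclass(frozen=True)
class Const(Expr):
    value: bool


@dataclass(frozen=True)
class Ref(Expr):
    target: str

    def refs(self) -> Iterator[str]:
        yield self.target


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def refs(self) -> Iterator[str]:
        yield from self.child.refs()


@dataclass(frozen=True)
class And(Expr):
    children: tuple[Expr, ...]

    def refs(self) -> Iterator[str]:
        for c in self.children:
            yield from c.refs()


@dataclass(frozen=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def refs(self) -> Iterator[str]:
        for c in self.children:
            yield from c.refs()


TRUE = Const(True)
FALSE = Const(False)


def make_and(children: Iterable[Expr]) -> Expr:
    flat: list[Expr] = []
    for c in children:
        if isinstance(c, Const):
            if not c.value:
                return FALSE
            continue
        if isinstance(c, And):
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        return TRUE
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def make_or(children: Iterable[Expr]) -> Expr:
    flat: list[Expr] = []
    for c in children:
        if isinstance(c, Const):
            if c.value:
                return TRUE
            continue
        if isinstance(c, Or):
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        return FALSE
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


def expr_to_json(e: Expr):
    if isinstance(e, Const):
        return e.value
    if isinstance(e, Ref):
        return {"ref": e.target}
    if isinstance(e, Not):
        return {"not": expr_to_json(e.child)}
    if isinstance(e, And):
        return {"and": [expr_to_json(c) for c in e.children]}
    if isinstance(e, Or):
        return {"or": [expr_to_json(c) for c in e.children]}
    raise TypeError(type(e))


def expr_from_json(data) -> Expr:
    if isinstance(data, bool):
        return Const(data)
    if "ref" in data:
        return Ref(data["ref"])
    if "not" in data:
        return Not(expr_from_json(data["not"]))
    if "and" in data:
        return And(tuple(expr_from_json(c) for c in data["and"]))
    if "or" in data:
        return Or(tuple(expr_from_json(c) for c in data["or"]))
    raise ValueError(data)


def expr_to_text(e: Expr, name=lambda t: t) -> str:
    """Render in the ``&``, ``|``, ``!`` syntax of plain-text Boolean-network
    formats."""
    if isinstance(e, Const):
        return "1" if e.value else "0"
    if isinstance(e, Ref):
        return name(e.target)
    if isinstance(e, Not):
        return f"!{_paren(e.child, name)}"
    if isinstance(e, And):
        return " & ".join(_paren(c, name) for c in e.children)
    if isinstance(e, Or):
        return " | ".join(_paren(c, name) for c in e.children)
    raise TypeError(type(e))


def _paren(e: Expr, name) -> str:
    text = expr_to_text(e, name)
    if isinstance(e, (And, Or)):
        return f"({text})"
    return text


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class NodeKind(str, Enum):
    STATE = "state"
    REACTION = "reaction"
    GATE = "gate"
    GLOBAL = "global"
    DELAY = "delay"


@dataclass
class NodeSpec:
    id: str
    kind: NodeKind
    update: Expr
    neutral: bool = False  # neutral elemental states start true
    provenance: str = ""  # originating system object (reaction/state id)


@dataclass
class DelaySpec:
    """Per-reaction delay-chain lengths (``k`` extra nodes per reaction).

    The default rule applies ``k = 20`` to every transcription reaction and
    to macro-cycle reactions tagged as replication progression.
    """

    delays: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def none() -> "DelaySpec":
        return DelaySpec({})

    @staticmethod
    def default_for(system: RxnconSystem, k: int = DEFAULT_DELAY) -> "DelaySpec":
        delays = {}
        for r in system.reactions:
            if r.rtype.rule is SkeletonRule.TRSC or REPLICATION_TAG in r.tags:
                delays[r.id] = k
        return DelaySpec(delays)

    def validate_against(self, reaction_ids: set[str]) -> None:
        for rid, k in self.delays.items():
            if rid not in reaction_ids:
                raise CompileError(f"delay on unknown reaction {rid!r}")
            if k < 0:
                raise CompileError(f"negative delay for {rid!r}")


class BooleanNetwork:
    """A compiled bipartite Boolean model.

    Nodes are held in canonical order (states, reactions, gates, globals,
    delays — each in system order); compilation is deterministic, so the
    serialised form and its hash are stable across runs and platforms.
    """

    def __init__(self, nodes: list[NodeSpec], initial: dict[str, bool]):
        self.nodes = nodes
        self.index = {n.id: i for i, n in enumerate(nodes)}
        if len(self.index) != len(nodes):
            raise CompileError("duplicate node ids")
        self.initial = initial
        for n in nodes:
            for ref in n.update.refs():
                if ref not in self.index:
                    raise CompileError(f"node {n.id}: unresolved reference {ref!r}")

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[self.index[node_id]]

    def census(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n in self.nodes:
            counts[n.kind.value] = counts.get(n.kind.value, 0) + 1
        counts["total"] = len(self.nodes)
        return counts

    def initial_vector(self) -> tuple[bool, ...]:
        return tuple(self.initial[n.id] for n in self.nodes)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind.value,
                    "update": expr_to_json(n.update),
                    "neutral": n.neutral,
                    "provenance": n.provenance,
                }
                for n in self.nodes
            ],
            "initial": [self.initial[n.id] for n in self.nodes],
        }
        return json.dumps(payload, indent=None, separators=(",", ":"), sort_keys=False)

    @staticmethod
    def from_json(text: str) -> "BooleanNetwork":
        payload = json.loads(text)
        nodes = [
            NodeSpec(
                d["id"],
                NodeKind(d["kind"]),
                expr_from_json(d["update"]),
                d.get("neutral", False),
                d.get("provenance", ""),
            )
            for d in payload["nodes"]
        ]
        initial = {n.id: v for n, v in zip(nodes, payload["initial"])}
        return BooleanNetwork(nodes, initial)

    def stable_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_bnet(self) -> str:
        """Export in the plain-text ``targets, factors`` format, one line per
        node, rules in ``&``/``|``/``!`` syntax.  Node ids are mangled to
        bare identifiers; the mapping is stable."""
        names = {n.id: mangle(n.id) for n in self.nodes}
        lines = ["targets, factors"]
        for n in self.nodes:
            lines.append(f"{names[n.id]}, {expr_to_text(n.update, lambda t: names[t])}")
        return "\n".join(lines) + "\n"


_MANGLE_RE = re.compile(r"[^A-Za-z0-9_]")


def mangle(node_id: str) -> str:
    out = _MANGLE_RE.sub("_", node_id)
    if out and out[0].isdigit():
        out = "n" + out
    return out


# ---------------------------------------------------------------------------
# rule builders
# ---------------------------------------------------------------------------

def _presence_expr(component: str | None, system: RxnconSystem) -> Expr:
    if component is None:  # macro-transition pseudo-component
        return TRUE
    states = system.states_of_component(component)
    if not states:
        return TRUE
    return make_or(Ref(str(s)) for s in states)


def _effector_expr(effector: str) -> Expr:
    return Ref(effector)


def reaction_update_rule(reaction: ElementalReaction, system: RxnconSystem) -> Expr:
    """Presence factors AND requirements AND negated inhibitions.

    ``k+``/``k-`` contingencies are parsed and stored but compile to no-ops.
    """
    comp_a, comp_b = reaction.effective_components()
    terms: list[Expr] = [_presence_expr(comp_a, system)]
    if comp_b != comp_a or comp_b is None:
        terms.append(_presence_expr(comp_b, system))
    for row in system.reaction_contingencies(reaction.id):
        if row.modifier is Modifier.REQUIREMENT:
            terms.append(_effector_expr(row.effector))
        elif row.modifier is Modifier.INHIBITION:
            terms.append(Not(_effector_expr(row.effector)))
        # POSITIVE / NEGATIVE: quantitative, non-blocking -> no term
    return make_and(terms)


def _production_term(reaction: ElementalReaction, system: RxnconSystem, state: State) -> Expr:
    sources = sorted(str(s) for s in system.skeletons[reaction.id].consumed)
    return make_and([Ref(reaction.id), *(Ref(s) for s in sources)])


def _consumption_term(reaction: ElementalReaction, system: RxnconSystem, state: State) -> Expr:
    others = sorted(
        str(s) for s in system.skeletons[reaction.id].consumed if str(s) != str(state)
    )
    return make_and([Ref(reaction.id), *(Ref(s) for s in others)])


def state_update_rule(state: State, system: RxnconSystem) -> Expr:
    """``production OR (self AND NOT consumption)`` for one state node."""
    sid = str(state)
    production: list[Expr] = []
    for r in system.producers(state):
        production.append(_production_term(r, system, state))
    for r in system.synthesisers(state):
        production.append(Ref(r.id))  # synthesis needs no source gating
    consumption: list[Expr] = []
    for r in system.consumers(state):
        consumption.append(_consumption_term(r, system, state))
    for r in system.degraders(state):
        consumption.append(Ref(r.id))
    # degradation of a bound component releases the partner's unbound neutral
    if state.kind is StateKind.UNBOUND:
        locus = state.first
        for other in system.states:
            if other.kind is not StateKind.BOND or locus not in other.loci:
                continue
            for r in system.degraders(other):
                if r.target_component() != locus.component:  # type: ignore[union-attr]
                    production.append(make_and([Ref(r.id), Ref(str(other))]))
    retention = make_and([Ref(sid), Not(make_or(consumption))]) if consumption else Ref(sid)
    return make_or([*production, retention])


def global_update_rule(name: str, system: RxnconSystem) -> Expr:
    """Macro states follow state-rule semantics; outputs defined by
    contingencies conjoin their requirements; pure inputs hold their value
    (they are meant to be clamped)."""
    state = State.global_(name)
    producers = system.producers(state)
    consumers = system.consumers(state)
    if producers or consumers:
        return state_update_rule(state, system)
    defining = [
        c
        for c in system.contingencies
        if c.target == name and not c.modifier.is_boolean_membership
    ]
    if defining:
        terms: list[Expr] = []
        for row in defining:
            if row.modifier is Modifier.REQUIREMENT:
                terms.append(_effector_expr(row.effector))
            elif row.modifier is Modifier.INHIBITION:
                terms.append(Not(_effector_expr(row.effector)))
        return make_and(terms)
    return Ref(name)


def gate_update_rule(gate_id: str, system: RxnconSystem) -> Expr:
    gate = system.gates[gate_id]
    children = [_effector_expr(c) for c in gate.children]
    if gate.gtype is Modifier.AND:
        return make_and(children)
    if gate.gtype is Modifier.OR:
        return make_or(children)
    if len(children) != 1:
        raise CompileError(f"NOT gate {gate_id} must have exactly one child")
    return Not(children[0])


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def compile_network(
    system: RxnconSystem,
    delays: DelaySpec | None = None,
    initial_overrides: Mapping[str, bool] | None = None,
) -> BooleanNetwork:
    """Compile a system into its uniquely defined bipartite Boolean model.

    Raises :class:`CompileError` if validation finds hard errors (dangling
    effectors, gate cycles, ...).
    """
    system._require_finalised()
    report = validate(system)
    if report.errors:
        raise CompileError(
            "system has hard validation errors:\n"
            + "\n".join(str(f) for f in report.errors)
        )

    nodes: list[NodeSpec] = []
    for s in system.states:
        if s.kind is StateKind.GLOBAL:
            continue
        nodes.append(
            NodeSpec(str(s), NodeKind.STATE, state_update_rule(s, system), s.is_neutral)
        )
    for r in system.reactions:
        nodes.append(
            NodeSpec(r.id, NodeKind.REACTION, reaction_update_rule(r, system), provenance=r.uid)
        )
    for gid in system.gates:
        nodes.append(NodeSpec(gid, NodeKind.GATE, gate_update_rule(gid, system)))
    for name in system.globals:
        nodes.append(NodeSpec(name, NodeKind.GLOBAL, global_update_rule(name, system)))

    network = BooleanNetwork(nodes, _default_initial(nodes, system, initial_overrides))
    if delays is not None and delays.delays:
        network = insert_delays(network, delays)
    return network


def _default_initial(
    nodes: list[NodeSpec],
    system: RxnconSystem | None,
    overrides: Mapping[str, bool] | None,
) -> dict[str, bool]:
    ids = {n.id for n in nodes}
    initial: dict[str, bool] = {}
    for n in nodes:
        if n.kind is NodeKind.STATE:
            initial[n.id] = n.neutral
        else:
            initial[n.id] = False
    if HISTONES in ids:
        initial[HISTONES] = True
    if system is not None:
        for node_id in system.initial_true:
            if node_id not in ids:
                raise CompileError(f"initial override of unknown node {node_id!r}")
            initial[node_id] = True
    for node_id, value in (overrides or {}).items():
        if node_id not in ids:
            raise CompileError(f"initial override of unknown node {node_id!r}")
        initial[node_id] = bool(value)
    return initial


def default_initial_vector(
    network: BooleanNetwork, overrides: Mapping[str, bool] | None = None
) -> dict[str, bool]:
    """The default start state: neutral states present, everything else off,
    globals false except explicit overrides (``[Histones]`` defaults to
    true)."""
    return _default_initial(
        [n for n in network.nodes], None, overrides
    )


def insert_delays(network: BooleanNetwork, delays: DelaySpec) -> BooleanNetwork:
    """Add delay chains: for delay ``k`` the reaction fires only after its
    undelayed rule has held over a window of consecutive steps; the chain
    resets whenever the rule goes false.  Adds exactly ``k`` nodes per
    delayed reaction."""
    reaction_ids = {n.id for n in network.nodes if n.kind is NodeKind.REACTION}
    delays.validate_against(reaction_ids)
    nodes = [NodeSpec(n.id, n.kind, n.update, n.neutral, n.provenance) for n in network.nodes]
    initial = dict(network.initial)
    by_id = {n.id: n for n in nodes}
    delay_nodes: list[NodeSpec] = []
    for n in network.nodes:  # canonical order
        if n.kind is not NodeKind.REACTION:
            continue
        k = delays.delays.get(n.id, 0)
        if k <= 0:
            continue
        base_rule = n.update
        prev: str | None = None
        for i in range(1, k + 1):
            did = f"{n.id}#d{i}"
            rule = base_rule if prev is None else make_and([Ref(prev), base_rule])
            delay_nodes.append(NodeSpec(did, NodeKind.DELAY, rule, provenance=n.id))
            initial[did] = False
            prev = did
        by_id[n.id].update = make_and([Ref(prev), base_rule])  # type: ignore[arg-type]
    return BooleanNetwork(nodes + delay_nodes, initial)
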