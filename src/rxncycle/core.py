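"""Reaction-contingency knowledge bases.

The central abstractions are *elemental states* (site-specific observables:
a bond between two named domains, a covalent modification at a named residue,
or their neutral complements), *elemental reactions* (indivisible reaction
events defined purely by the elemental states they produce, consume,
synthesise or degrade) and *contingencies* (constraints stating which states,
inputs or Boolean combinations thereof must be true or false for a reaction
to fire).  A :class:`RxnconSystem` bundles these together with Boolean gates
and a coarse-grained macro-cycle layer, and exposes the indexes the compiler
and validators need.

Canonical string grammar
------------------------
``A_[x]--B_[y]``    bond between domain ``x`` of ``A`` and domain ``y`` of ``B``
``A_[x]--0``        unbound neutral of domain ``x``
``A_[r]-P``         modification ``P`` at residue ``r``
``A_[r]-0``         unmodified neutral of residue ``r``
``A``               degenerate component-presence state (stateless components)
``[Name]``          global input/output or macro-cycle state
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping


class RxnconError(Exception):
    """Base class for knowledge-base errors."""


class SkeletonError(RxnconError):
    """A reaction's component/locus resolution does not match its type."""


class StateSyntaxError(RxnconError):
    """A state string does not follow the canonical grammar."""


# ---------------------------------------------------------------------------
# components and loci
# ---------------------------------------------------------------------------

class ComponentKind(str, Enum):
    PROTEIN = "protein"
    GENE = "gene"
    MRNA = "mRNA"
    COMPLEX = "multimeric-complex"
    CHROMOSOMAL = "chromosomal-feature"
    ACTIVITY = "enzymatic-activity"
    SMALL_MOLECULE = "small-molecule"


class LocusKind(str, Enum):
    DOMAIN = "domain"
    RESIDUE = "residue"


@dataclass(frozen=True, order=True)
class Locus:
    """A named domain or residue on a component."""

    component: str
    name: str
    kind: LocusKind

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.component}_[{self.name}]"


@dataclass(frozen=True)
class Component:
    name: str
    kind: ComponentKind = ComponentKind.PROTEIN
    #: for gene/mRNA components: the protein they encode
    linked: str | None = None


GENE_SUFFIX = "gene"
MRNA_SUFFIX = "mRNA"


def gene_of(protein: str) -> str:
    return protein + GENE_SUFFIX


def mrna_of(protein: str) -> str:
    return protein + MRNA_SUFFIX


def infer_component_kind(name: str) -> tuple[ComponentKind, str | None]:
    """Infer a component's kind (and encoded protein) from its name.

    Gene and mRNA components follow the ``Xgene`` / ``XmRNA`` naming
    convention used throughout; everything else defaults to protein and may
    be overridden when constructing a system.
    """
    if name.endswith(GENE_SUFFIX) and len(name) > len(GENE_SUFFIX):
        return ComponentKind.GENE, name[: -len(GENE_SUFFIX)]
    if name.endswith(MRNA_SUFFIX) and len(name) > len(MRNA_SUFFIX):
        return ComponentKind.MRNA, name[: -len(MRNA_SUFFIX)]
    return ComponentKind.PROTEIN, None


# ---------------------------------------------------------------------------
# elemental states
# ---------------------------------------------------------------------------

class StateKind(str, Enum):
    BOND = "bond"
    UNBOUND = "unbound"
    MOD = "modification"
    UNMOD = "unmodified"
    COMPONENT = "component"
    GLOBAL = "global"


@dataclass(frozen=True, order=True)
class State:
    """An elemental state, identified by its canonical string."""

    kind: StateKind
    first: Locus | None = None
    second: Locus | None = None
    mod: str | None = None
    name: str | None = None

    # -- constructors -------------------------------------------------------

    @staticmethod
    def bond(a: Locus, b: Locus) -> "State":
        if a.kind is not LocusKind.DOMAIN or b.kind is not LocusKind.DOMAIN:
            raise SkeletonError(f"bonds attach only to domain loci: {a}, {b}")
        lo, hi = sorted((a, b))
        return State(StateKind.BOND, first=lo, second=hi)

    @staticmethod
    def unbound(a: Locus) -> "State":
        if a.kind is not LocusKind.DOMAIN:
            raise SkeletonError(f"unbound neutral requires a domain locus: {a}")
        return State(StateKind.UNBOUND, first=a)

    @staticmethod
    def modification(a: Locus, mod: str) -> "State":
        if a.kind is not LocusKind.RESIDUE:
            raise SkeletonError(f"modifications attach only to residue loci: {a}")
        return State(StateKind.MOD, first=a, mod=mod)

    @staticmethod
    def unmodified(a: Locus) -> "State":
        if a.kind is not LocusKind.RESIDUE:
            raise SkeletonError(f"unmodified neutral requires a residue locus: {a}")
        return State(StateKind.UNMOD, first=a)

    @staticmethod
    def component(name: str) -> "State":
        return State(StateKind.COMPONENT, name=name)

    @staticmethod
    def global_(name: str) -> "State":
        if not (name.startswith("[") and name.endswith("]")):
            name = f"[{name}]"
        return State(StateKind.GLOBAL, name=name)

    # -- properties ---------------------------------------------------------

    @property
    def is_neutral(self) -> bool:
        return self.kind in (StateKind.UNBOUND, StateKind.UNMOD, StateKind.COMPONENT)

    @property
    def components(self) -> tuple[str, ...]:
        """Names of the components this state belongs to."""
        if self.kind is StateKind.GLOBAL:
            return ()
        if self.kind is StateKind.COMPONENT:
            return (self.name,)  # type: ignore[arg-type]
        if self.kind is StateKind.BOND:
            a, b = self.first.component, self.second.component  # type: ignore[union-attr]
            return (a,) if a == b else (a, b)
        return (self.first.component,)  # type: ignore[union-attr]

    @property
    def loci(self) -> tuple[Locus, ...]:
        if self.kind is StateKind.BOND:
            return (self.first, self.second)  # type: ignore[return-value]
        if self.first is not None:
            return (self.first,)
        return ()

    def neutral_complements(self) -> tuple["State", ...]:
        """The neutral complement(s) at each locus of a non-neutral state."""
        if self.kind is StateKind.BOND:
            return (State.unbound(self.first), State.unbound(self.second))  # type: ignore[arg-type]
        if self.kind is StateKind.MOD:
            return (State.unmodified(self.first),)  # type: ignore[arg-type]
        return ()

    def __str__(self) -> str:
        if self.kind is StateKind.BOND:
            return f"{self.first}--{self.second}"
        if self.kind is StateKind.UNBOUND:
            return f"{self.first}--0"
        if self.kind is StateKind.MOD:
            return f"{self.first}-{self.mod}"
        if self.kind is StateKind.UNMOD:
            return f"{self.first}-0"
        return self.name  # type: ignore[return-value]


_LOCUS_RE = re.compile(r"^(?P<comp>[^\[\]\s]+)_\[(?P<name>[^\[\]]+)\]$")


def _parse_locus(text: str, kind: LocusKind) -> Locus:
    m = _LOCUS_RE.match(text)
    if not m:
        raise StateSyntaxError(f"cannot parse locus {text!r}")
    return Locus(m.group("comp"), m.group("name"), kind)


def parse_state(text: str) -> State:
    """Parse a canonical state string (see module docstring for the grammar)."""
    text = text.strip()
    if not text:
        raise StateSyntaxError("empty state string")
    if text.startswith("[") and text.endswith("]"):
        return State.global_(text)
    if "--" in text:
        left, right = text.split("--", 1)
        if right == "0":
            return State.unbound(_parse_locus(left, LocusKind.DOMAIN))
        return State.bond(
            _parse_locus(left, LocusKind.DOMAIN), _parse_locus(right, LocusKind.DOMAIN)
        )
    m = re.match(r"^(?P<locus>.+_\[[^\[\]]+\])-(?P<mod>[A-Za-z0-9]+)$", text)
    if m:
        locus = _parse_locus(m.group("locus"), LocusKind.RESIDUE)
        if m.group("mod") == "0":
            return State.unmodified(locus)
        return State.modification(locus, m.group("mod"))
    if re.match(r"^[^\[\]\s-]+$", text):
        return State.component(text)
    raise StateSyntaxError(f"cannot parse state {text!r}")


# ---------------------------------------------------------------------------
# reaction types (data-driven catalogue)
# ---------------------------------------------------------------------------

class SkeletonRule(str, Enum):
    """Template deciding how a reaction's skeleton states are generated."""

    BIND = "bind"
    UNBIND = "unbind"
    MOD_ADD = "mod-add"
    MOD_REMOVE = "mod-remove"
    TRSC = "transcription"
    TRSL = "translation"
    DEG = "degradation"
    SYN = "synthesis"
    MACRO = "macro-transition"


@dataclass(frozen=True)
class ReactionType:
    name: str
    rule: SkeletonRule
    mod: str | None = None  # modification kind for MOD_ADD / MOD_REMOVE


def default_catalogue() -> dict[str, ReactionType]:
    """The built-in reaction-type catalogue.

    Covers bond formation/dissociation (inter- and intramolecular),
    phosphorylation/dephosphorylation, ubiquitylation/deubiquitylation,
    transcription, translation, degradation, synthesis and macro-cycle
    transitions.  The catalogue is data: extend or replace entries to bind a
    model file that declares other type names.
    """
    types = [
        ReactionType("ppi+", SkeletonRule.BIND),
        ReactionType("ppi-", SkeletonRule.UNBIND),
        ReactionType("ipi+", SkeletonRule.BIND),
        ReactionType("ipi-", SkeletonRule.UNBIND),
        ReactionType("p+", SkeletonRule.MOD_ADD, mod="P"),
        ReactionType("p-", SkeletonRule.MOD_REMOVE, mod="P"),
        ReactionType("ub+", SkeletonRule.MOD_ADD, mod="Ub"),
        ReactionType("ub-", SkeletonRule.MOD_REMOVE, mod="Ub"),
        ReactionType("trsc", SkeletonRule.TRSC),
        ReactionType("trsl", SkeletonRule.TRSL),
        ReactionType("deg", SkeletonRule.DEG),
        ReactionType("syn", SkeletonRule.SYN),
        ReactionType("mt", SkeletonRule.MACRO),
    ]
    return {t.name: t for t in types}


# ---------------------------------------------------------------------------
# elemental reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One side (A or B) of an elemental reaction: a component plus the
    domain or residue it acts through, where the reaction type requires one.
    """

    name: str
    domain: str | None = None
    residue: str | None = None

    def __str__(self) -> str:
        if self.residue is not None:
            return f"{self.name}_[{self.residue}]"
        if self.domain is not None:
            return f"{self.name}_[{self.domain}]"
        return self.name


@dataclass(frozen=True)
class Skeleton:
    """The state sets an elemental reaction touches."""

    produced: frozenset[State] = frozenset()
    consumed: frozenset[State] = frozenset()
    synthesised: frozenset[State] = frozenset()
    degraded: frozenset[State] = frozenset()


@dataclass(frozen=True)
class ElementalReaction:
    uid: str
    rtype: ReactionType
    a: ComponentSpec
    b: ComponentSpec
    tags: frozenset[str] = frozenset()
    extra: tuple[tuple[str, str], ...] = ()  # preserved unknown columns

    @property
    def id(self) -> str:
        return f"{self.a}_{self.rtype.name}_{self.b}"

    @property
    def is_macro(self) -> bool:
        return self.rtype.rule is SkeletonRule.MACRO

    def target_component(self) -> str:
        """The component acted on (side B, resolved for trsc/trsl)."""
        if self.rtype.rule is SkeletonRule.TRSC:
            return mrna_of(self.b.name)
        return self.b.name

    def effective_components(self) -> tuple[str | None, str | None]:
        """The components whose presence gates the reaction (A, B).

        ``None`` marks a macro-transition side (a global pseudo-component
        whose presence factor is constant true).  For transcription the B
        side resolves to the gene, for translation to the mRNA, so that
        deleting gene or transcript silences the reaction.
        """
        if self.rtype.rule is SkeletonRule.MACRO:
            return None, None
        a = self.a.name
        if self.rtype.rule is SkeletonRule.TRSC:
            return a, gene_of(self.b.name)
        if self.rtype.rule is SkeletonRule.TRSL:
            return a, mrna_of(self.b.name)
        return a, self.b.name


def _domain_locus(spec: ComponentSpec, reaction_id: str) -> Locus:
    if spec.residue is not None:
        raise SkeletonError(
            f"{reaction_id}: bond reactions attach to domains, "
            f"but {spec.name} gives residue {spec.residue!r}"
        )
    if spec.domain is None:
        raise SkeletonError(f"{reaction_id}: {spec.name} needs a domain")
    return Locus(spec.name, spec.domain, LocusKind.DOMAIN)


def _residue_locus(spec: ComponentSpec, reaction_id: str) -> Locus:
    if spec.domain is not None and spec.residue is None:
        raise SkeletonError(
            f"{reaction_id}: modification reactions attach to residues, "
            f"but {spec.name} gives domain {spec.domain!r}"
        )
    if spec.residue is None:
        raise SkeletonError(f"{reaction_id}: {spec.name} needs a residue")
    return Locus(spec.name, spec.residue, LocusKind.RESIDUE)


def local_skeleton(reaction: ElementalReaction) -> Skeleton:
    """Context-free part of a reaction's skeleton.

    Degradation, synthesis and translation targets are expanded against the
    system's full state universe in :meth:`RxnconSystem.finalise`; here they
    contribute nothing yet.
    """
    rule = reaction.rtype.rule
    rid = reaction.id
    if rule is SkeletonRule.BIND:
        la = _domain_locus(reaction.a, rid)
        lb = _domain_locus(reaction.b, rid)
        bond = State.bond(la, lb)
        return Skeleton(
            produced=frozenset({bond}),
            consumed=frozenset({State.unbound(la), State.unbound(lb)}),
        )
    if rule is SkeletonRule.UNBIND:
        la = _domain_locus(reaction.a, rid)
        lb = _domain_locus(reaction.b, rid)
        bond = State.bond(la, lb)
        return Skeleton(
            produced=frozenset({State.unbound(la), State.unbound(lb)}),
            consumed=frozenset({bond}),
        )
    if rule in (SkeletonRule.MOD_ADD, SkeletonRule.MOD_REMOVE):
        lb = _residue_locus(reaction.b, rid)
        mod = State.modification(lb, reaction.rtype.mod or "P")
        neutral = State.unmodified(lb)
        if rule is SkeletonRule.MOD_ADD:
            return Skeleton(produced=frozenset({mod}), consumed=frozenset({neutral}))
        return Skeleton(produced=frozenset({neutral}), consumed=frozenset({mod}))
    if rule is SkeletonRule.TRSC:
        return Skeleton(synthesised=frozenset({State.component(mrna_of(reaction.b.name))}))
    if rule is SkeletonRule.MACRO:
        return Skeleton(
            produced=frozenset({State.global_(reaction.b.name)}),
            consumed=frozenset({State.global_(reaction.a.name)}),
        )
    # TRSL / SYN / DEG are expanded against the system at finalisation.
    return Skeleton()


# ---------------------------------------------------------------------------
# contingencies and Boolean gates
# ---------------------------------------------------------------------------

class Modifier(str, Enum):
    REQUIREMENT = "!"
    INHIBITION = "x"
    POSITIVE = "k+"
    NEGATIVE = "k-"
    AND = "AND"
    OR = "OR"
    NOT = "NOT"

    @property
    def is_boolean_membership(self) -> bool:
        return self in (Modifier.AND, Modifier.OR, Modifier.NOT)


_STRUCT_RE = re.compile(r"@\d+")


def is_gate_id(text: str) -> bool:
    return text.startswith("<") and text.endswith(">")


def is_global_id(text: str) -> bool:
    return text.startswith("[") and text.endswith("]")


@dataclass(frozen=True)
class Contingency:
    """A constraint on a reaction, gate or global output.

    ``effector`` is a canonical state string, a global ``[Name]`` or a gate
    ``<name>``.  Structure annotations (``@n`` molecule-instance markers on
    structured complexes) are preserved verbatim in ``annotation`` but carry
    no extra runtime semantics in the population-level Boolean regime.
    """

    uid: str
    target: str
    effector: str
    modifier: Modifier
    annotation: str = ""
    extra: tuple[tuple[str, str], ...] = ()

    @staticmethod
    def strip_structure(effector: str) -> tuple[str, str]:
        stripped = _STRUCT_RE.sub("", effector)
        return stripped, (effector if stripped != effector else "")


@dataclass
class BooleanGate:
    id: str  # "<name>"
    gtype: Modifier  # AND / OR / NOT
    children: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the system
# ---------------------------------------------------------------------------

class RxnconSystem:
    """A parsed reaction-contingency system with derived indexes.

    Build one by adding reactions and contingencies (gate-membership rows
    included) and then calling :meth:`finalise`, which derives components,
    the elemental-state universe, full skeletons and producer/consumer
    indexes.  Parsing and the synthetic generators do this for you.
    """

    def __init__(
        self,
        catalogue: Mapping[str, ReactionType] | None = None,
        component_kinds: Mapping[str, ComponentKind] | None = None,
    ) -> None:
        self.catalogue: dict[str, ReactionType] = dict(catalogue or default_catalogue())
        self.reactions: list[ElementalReaction] = []
        self.contingencies: list[Contingency] = []
        self.gates: dict[str, BooleanGate] = {}
        self.initial_true: list[str] = []  # declared initial-true overrides
        self._kind_overrides: dict[str, ComponentKind] = dict(component_kinds or {})
        self._finalised = False
        # derived
        self.components: dict[str, Component] = {}
        self.states: list[State] = []
        self.skeletons: dict[str, Skeleton] = {}
        self.globals: list[str] = []

    # -- construction -------------------------------------------------------

    def add_reaction(
        self,
        rtype: str,
        a: ComponentSpec,
        b: ComponentSpec,
        uid: str | None = None,
        tags: Iterable[str] = (),
        extra: Iterable[tuple[str, str]] = (),
    ) -> ElementalReaction:
        if rtype not in self.catalogue:
            raise RxnconError(f"unknown reaction type {rtype!r}")
        reaction = ElementalReaction(
            uid=uid or f"R{len(self.reactions) + 1}",
            rtype=self.catalogue[rtype],
            a=a,
            b=b,
            tags=frozenset(tags),
            extra=tuple(extra),
        )
        self.reactions.append(reaction)
        self._finalised = False
        return reaction

    def add_contingency(
        self,
        target: str,
        effector: str,
        modifier: Modifier | str,
        uid: str | None = None,
        extra: Iterable[tuple[str, str]] = (),
    ) -> Contingency:
        modifier = Modifier(modifier)
        stripped, annotation = Contingency.strip_structure(effector.strip())
        if not is_gate_id(stripped) and not is_global_id(stripped):
            stripped = str(parse_state(stripped))  # canonicalise
        row = Contingency(
            uid=uid or f"C{len(self.contingencies) + 1}",
            target=target.strip(),
            effector=stripped,
            modifier=modifier,
            annotation=annotation,
            extra=tuple(extra),
        )
        self.contingencies.append(row)
        if modifier.is_boolean_membership:
            if not is_gate_id(row.target):
                raise RxnconError(
                    f"contingency {row.uid}: boolean membership requires a "
                    f"<gate> target, got {row.target!r}"
                )
            gate = self.gates.setdefault(row.target, BooleanGate(row.target, modifier))
            if gate.gtype is not modifier:
                raise RxnconError(
                    f"gate {row.target} mixes {gate.gtype.value} and {modifier.value}"
                )
            gate.children.append(row.effector)
            gate.annotations.append(row.annotation)
        self._finalised = False
        return row

    def declare_initial_true(self, node_id: str) -> None:
        if node_id not in self.initial_true:
            self.initial_true.append(node_id)
        self._finalised = False

    # -- finalisation -------------------------------------------------------

    def finalise(self) -> "RxnconSystem":
        """Derive components, the state universe and full skeletons."""
        self._derive_components()
        universe: dict[str, State] = {}

        def _add(state: State) -> None:
            universe.setdefault(str(state), state)

        local: dict[str, Skeleton] = {}
        for r in self.reactions:
            sk = local_skeleton(r)
            local[r.id] = sk
            for s in (*sorted(sk.produced), *sorted(sk.consumed), *sorted(sk.synthesised)):
                _add(s)
        # component-presence states for components with no locus-bearing state
        with_loci = {
            c for s in universe.values() for c in s.components if s.kind is not StateKind.GLOBAL
        }
        for name in self.components:
            if name not in with_loci:
                _add(State.component(name))
        #: states grounded in reaction skeletons / component presence —
        #: anything an effector adds beyond these is undefined (validation)
        self._grounded_state_ids = set(universe)
        # effector states (may add globals and component states)
        for row in self.contingencies:
            for eff in self._effector_leaves(row.effector):
                if is_gate_id(eff):
                    continue
                if is_global_id(eff):
                    _add(State.global_(eff))
                else:
                    _add(parse_state(eff))
        for row in self.contingencies:
            if is_global_id(row.target):
                _add(State.global_(row.target))
        for node in self.initial_true:
            if is_global_id(node):
                _add(State.global_(node))

        # context-dependent skeleton expansion
        def states_of(component: str) -> list[State]:
            return [
                s
                for s in universe.values()
                if s.kind is not StateKind.GLOBAL and component in s.components
            ]

        self.skeletons = {}
        for r in self.reactions:
            sk = local[r.id]
            rule = r.rtype.rule
            if rule in (SkeletonRule.SYN, SkeletonRule.TRSL, SkeletonRule.TRSC):
                target = r.target_component()
                neutrals = [s for s in states_of(target) if s.is_neutral]
                if not neutrals:
                    comp = State.component(target)
                    _add(comp)
                    neutrals = [comp]
                sk = Skeleton(synthesised=frozenset(neutrals))
            elif rule is SkeletonRule.DEG:
                target = r.target_component()
                degraded = states_of(target)
                if not degraded:
                    comp = State.component(target)
                    _add(comp)
                    degraded = [comp]
                sk = Skeleton(degraded=frozenset(degraded))
            if sk.produced & sk.consumed:
                raise RxnconError(f"{r.id}: produced and consumed sets overlap")
            self.skeletons[r.id] = sk

        order = {StateKind.GLOBAL: 1}
        self.states = sorted(
            universe.values(), key=lambda s: (order.get(s.kind, 0), str(s))
        )
        self.globals = [str(s) for s in self.states if s.kind is StateKind.GLOBAL]
        self._finalised = True
        return self

    def _derive_components(self) -> None:
        names: list[str] = []
        for r in self.reactions:
            for side in r.effective_components():
                if side is not None and side not in names:
                    names.append(side)
            if r.rtype.rule is SkeletonRule.TRSC:
                for extra_name in (mrna_of(r.b.name), r.b.name):
                    if extra_name not in names:
                        names.append(extra_name)
        for row in self.contingencies:
            for eff in self._effector_leaves(row.effector):
                if is_gate_id(eff) or is_global_id(eff):
                    continue
                for comp in parse_state(eff).components:
                    if comp not in names:
                        names.append(comp)
        self.components = {}
        for name in sorted(names):
            kind, linked = infer_component_kind(name)
            kind = self._kind_overrides.get(name, kind)
            self.components[name] = Component(name, kind, linked)

    def _effector_leaves(
        self, effector: str, _seen: frozenset[str] = frozenset()
    ) -> Iterator[str]:
        if is_gate_id(effector):
            if effector in _seen:  # gate cycle; reported by validation
                return
            gate = self.gates.get(effector)
            if gate is None:
                return
            for child in gate.children:
                yield from self._effector_leaves(child, _seen | {effector})
        else:
            yield effector

    # -- indexes ------------------------------------------------------------

    def _require_finalised(self) -> None:
        if not self._finalised:
            self.finalise()

    def states_of_component(self, name: str) -> list[State]:
        self._require_finalised()
        return [
            s
            for s in self.states
            if s.kind is not StateKind.GLOBAL and name in s.components
        ]

    def producers(self, state: State | str) -> list[ElementalReaction]:
        sid = str(state)
        self._require_finalised()
        return [
            r
            for r in self.reactions
            if any(str(s) == sid for s in self.skeletons[r.id].produced)
        ]

    def consumers(self, state: State | str) -> list[ElementalReaction]:
        sid = str(state)
        self._require_finalised()
        return [
            r
            for r in self.reactions
            if any(str(s) == sid for s in self.skeletons[r.id].consumed)
        ]

    def synthesisers(self, state: State | str) -> list[ElementalReaction]:
        sid = str(state)
        self._require_finalised()
        return [
            r
            for r in self.reactions
            if any(str(s) == sid for s in self.skeletons[r.id].synthesised)
        ]

    def degraders(self, state: State | str) -> list[ElementalReaction]:
        sid = str(state)
        self._require_finalised()
        return [
            r
            for r in self.reactions
            if any(str(s) == sid for s in self.skeletons[r.id].degraded)
        ]

    def degraders_of_component(self, name: str) -> list[ElementalReaction]:
        self._require_finalised()
        return [
            r
            for r in self.reactions
            if r.rtype.rule is SkeletonRule.DEG and r.target_component() == name
        ]

    def reaction_by_id(self, rid: str) -> ElementalReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_contingencies(self, rid: str) -> list[Contingency]:
        return [
            c
            for c in self.contingencies
            if c.target == rid and not c.modifier.is_boolean_membership
        ]

    def macro_states(self) -> list[str]:
        """Globals produced or consumed by macro-cycle transitions."""
        self._require_finalised()
        seen: list[str] = []
        for r in self.reactions:
            if r.is_macro:
                for s in (State.global_(r.a.name), State.global_(r.b.name)):
                    if str(s) not in seen:
                        seen.append(str(s))
        return seen

    # -- mutual exclusion ---------------------------------------------------

    def mutual_exclusion_groups(self) -> list[list[State]]:
        """Group locus-bearing states by locus.

        Every bond and unbound state of one domain locus forms one group, as
        does every modification/unmodified pair of one residue locus; the
        groups partition the locus-bearing states (bonds belong to the group
        of each of their two loci).
        """
        self._require_finalised()
        groups: dict[Locus, list[State]] = {}
        for s in self.states:
            for locus in s.loci:
                groups.setdefault(locus, []).append(s)
        return [groups[k] for k in sorted(groups)]

    # -- equality -----------------------------------------------------------

    def semantically_equal(self, other: "RxnconSystem") -> bool:
        """Content equality ignoring row order within sheets."""
        self._require_finalised()
        other._require_finalised()

        def rxn_key(r: ElementalReaction):
            return (r.id, r.rtype.name, tuple(sorted(r.tags)), tuple(sorted(r.extra)))

        def cont_key(c: Contingency):
            return (c.target, c.effector, c.modifier.value, c.annotation)

        return (
            sorted(map(rxn_key, self.reactions)) == sorted(map(rxn_key, other.reactions))
            and sorted(map(cont_key, self.contingencies))
            == sorted(map(cont_key, other.contingencies))
            and sorted(self.initial_true) == sorted(other.initial_true)
            and set(self.components) == set(other.components)
        )


def skeleton_states(reaction: ElementalReaction, system: RxnconSystem) -> Skeleton:
    """The produced/consumed/synthesised/degraded sets of one reaction.

    Deterministic given the reaction and the system it lives in; degradation
    and synthesis sets are expanded against the system's state universe.
    """
    system._require_finalised()
    return system.skeletons[reaction.id]
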