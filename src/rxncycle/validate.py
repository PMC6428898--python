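"""System consistency checks.

The validator operationalises the knowledge-base construction assumptions:
every reversible covalent modification and every synthesised component is
turned over (removal or degradation exists) unless flagged stable, every
contingency effector is producible or global, synthesised components can be
degraded, and Boolean gates form an acyclic graph.  Violations are collected
into a report — turnover issues are warnings (the assumption is lifted
case-by-case via the ``no-turnover`` tag), structural issues are errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    Modifier,
    RxnconSystem,
    SkeletonRule,
    State,
    StateSyntaxError,
    is_gate_id,
    is_global_id,
    parse_state,
)

NO_TURNOVER_TAG = "no-turnover"


@dataclass(frozen=True)
class Finding:
    code: str
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, code: str, severity: str, message: str) -> None:
        self.findings.append(Finding(code, severity, message))

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.findings

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [
                {"code": f.code, "severity": f.severity, "message": f.message}
                for f in self.findings
            ],
        }


def validate(system: RxnconSystem) -> ValidationReport:
    """Run all consistency checks on a finalised system."""
    system._require_finalised()
    report = ValidationReport()
    _check_effectors(system, report)
    _check_targets(system, report)
    _check_turnover(system, report)
    _check_synthesis_turnover(system, report)
    _check_gate_cycles(system, report)
    return report


def _known_state_ids(system: RxnconSystem) -> set[str]:
    return {str(s) for s in system.states}


def _check_effectors(system: RxnconSystem, report: ValidationReport) -> None:
    known = _known_state_ids(system)
    reaction_ids = {r.id for r in system.reactions}
    for row in system.contingencies:
        if row.modifier.is_boolean_membership:
            continue
        for eff in system._effector_leaves(row.effector):
            if is_gate_id(eff):
                if eff not in system.gates:
                    report.add(
                        "undefined-gate",
                        "error",
                        f"contingency {row.uid} references undefined gate {eff}",
                    )
                continue
            if is_global_id(eff):
                continue  # globals are declared by use
            try:
                state = parse_state(eff)
            except StateSyntaxError:
                report.add(
                    "bad-effector",
                    "error",
                    f"contingency {row.uid}: unparseable effector {eff!r}",
                )
                continue
            if eff not in system._grounded_state_ids:
                report.add(
                    "undefined-effector",
                    "error",
                    f"contingency {row.uid}: effector {eff} appears in no "
                    f"reaction skeleton",
                )
                continue
            if state.is_neutral:
                continue  # neutrals are true by default, always "producible"
            if not system.producers(state) and not system.synthesisers(state):
                report.add(
                    "dangling-effector",
                    "warning",
                    f"contingency {row.uid}: effector {eff} has no producing "
                    f"reaction",
                )
        # self-reference: the effector must not be the target itself
        if row.effector == row.target:
            report.add(
                "self-contingency",
                "error",
                f"contingency {row.uid} targets its own effector {row.target}",
            )
    # unused gates are harmless; gates whose children are unknown states:
    for gate in system.gates.values():
        for child in gate.children:
            if is_gate_id(child) or is_global_id(child):
                continue
            if child not in system._grounded_state_ids:
                report.add(
                    "undefined-effector",
                    "error",
                    f"gate {gate.id}: child {child} appears in no reaction "
                    f"skeleton",
                )
    _ = reaction_ids  # reserved for future target checks


def _check_targets(system: RxnconSystem, report: ValidationReport) -> None:
    reaction_ids = {r.id for r in system.reactions}
    for row in system.contingencies:
        if row.modifier.is_boolean_membership:
            continue
        t = row.target
        if is_gate_id(t) and t not in system.gates:
            report.add(
                "undefined-gate", "error", f"contingency {row.uid} targets undefined gate {t}"
            )
        elif not is_gate_id(t) and not is_global_id(t) and t not in reaction_ids:
            report.add(
                "undefined-target",
                "error",
                f"contingency {row.uid} targets unknown reaction {t!r}",
            )


def _check_turnover(system: RxnconSystem, report: ValidationReport) -> None:
    removals: set[tuple[str, str, str]] = set()
    for r in system.reactions:
        if r.rtype.rule is SkeletonRule.MOD_REMOVE:
            for s in system.skeletons[r.id].consumed:
                if s.mod is not None:
                    removals.add((s.first.component, s.first.name, s.mod))  # type: ignore[union-attr]
    for r in system.reactions:
        if r.rtype.rule is not SkeletonRule.MOD_ADD or NO_TURNOVER_TAG in r.tags:
            continue
        for s in system.skeletons[r.id].produced:
            if s.mod is None:
                continue
            comp = s.first.component  # type: ignore[union-attr]
            key = (comp, s.first.name, s.mod)  # type: ignore[union-attr]
            if key not in removals and not system.degraders_of_component(comp):
                report.add(
                    "turnover",
                    "warning",
                    f"{r.id}: modification {s} has neither a removal reaction "
                    f"nor degradation of {comp} (flag '{NO_TURNOVER_TAG}' to "
                    f"silence)",
                )


def _check_synthesis_turnover(system: RxnconSystem, report: ValidationReport) -> None:
    for r in system.reactions:
        if r.rtype.rule not in (SkeletonRule.SYN, SkeletonRule.TRSL, SkeletonRule.TRSC):
            continue
        if NO_TURNOVER_TAG in r.tags:
            continue
        target = r.target_component()
        if not system.degraders_of_component(target):
            report.add(
                "no-degradation",
                "warning",
                f"{r.id}: synthesised component {target} has no degradation "
                f"reaction",
            )


def _check_gate_cycles(system: RxnconSystem, report: ValidationReport) -> None:
    colour: dict[str, int] = {}

    def visit(gid: str, stack: tuple[str, ...]) -> None:
        if colour.get(gid) == 2:
            return
        if colour.get(gid) == 1:
            report.add(
                "gate-cycle",
                "error",
                f"boolean gate cycle: {' -> '.join(stack + (gid,))}",
            )
            return
        colour[gid] = 1
        gate = system.gates.get(gid)
        if gate is not None:
            if gate.gtype is Modifier.NOT and len(gate.children) != 1:
                report.add(
                    "bad-not-gate",
                    "error",
                    f"NOT gate {gid} must have exactly one child, has "
                    f"{len(gate.children)}",
                )
            for child in gate.children:
                if is_gate_id(child):
                    visit(child, stack + (gid,))
        colour[gid] = 2

    for gid in system.gates:
        visit(gid, ())
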