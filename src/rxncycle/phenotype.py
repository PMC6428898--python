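"""Mutant genotype-to-phenotype prediction.

Mutants are expressed as clamps: deletions force every state of a component
(and of its gene and mRNA) to false, residue locks fix a modification state
and its neutral complement, and constitutive overexpression forces a
transcription reaction node to true.  Each mutant is released from the
wild-type quiescent (G0) attractor with nutrients on, simulated to its
attractor, and the attractor is classified on the coarse-grained macro-state
readout: ordered traversal of all three replication cycles (DNA, spindle
pole body / nuclear division, bud / cell division) per period means
viability; everything else is an arrest or a partial (multinucleate) cycle.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .compile import BooleanNetwork
from .core import (
    RxnconSystem,
    RxnconError,
    SkeletonRule,
    State,
    StateKind,
    gene_of,
    mrna_of,
    parse_state,
)
from .simulate import Attractor, BudgetExceededError, find_attractor

NUTRIENTS = "[Nutrients]"


class MutantError(RxnconError):
    pass


# ---------------------------------------------------------------------------
# mutants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantSpec:
    label: str
    deletions: tuple[str, ...] = ()
    locks: tuple[tuple[str, bool], ...] = ()
    overexpressions: tuple[str, ...] = ()

    def is_empty(self) -> bool:
        return not (self.deletions or self.locks or self.overexpressions)


def apply_mutant(
    network: BooleanNetwork, system: RxnconSystem, spec: MutantSpec
) -> dict[str, bool]:
    """Translate a mutant specification into a clamp set."""
    clamps: dict[str, bool] = {}
    locked_components = {parse_state(s).components for s, _ in spec.locks}
    for comp in spec.deletions:
        if comp not in system.components:
            raise MutantError(f"{spec.label}: unknown component {comp!r}")
        for locked in locked_components:
            if comp in locked:
                raise MutantError(
                    f"{spec.label}: deletion of {comp} conflicts with a lock on "
                    f"one of its states"
                )
        for name in (comp, gene_of(comp), mrna_of(comp)):
            if name not in system.components:
                continue
            for s in system.states_of_component(name):
                clamps[str(s)] = False
    for state_text, value in spec.locks:
        state = parse_state(state_text)
        sid = str(state)
        if sid not in network.index:
            raise MutantError(f"{spec.label}: unknown state {sid!r}")
        clamps[sid] = bool(value)
        if state.kind is StateKind.MOD:
            (neutral,) = state.neutral_complements()
            if str(neutral) in network.index:
                clamps[str(neutral)] = not value
    for entry in spec.overexpressions:
        rid = _resolve_overexpression(system, entry, spec.label)
        clamps[rid] = True
    return clamps


def _resolve_overexpression(system: RxnconSystem, entry: str, label: str) -> str:
    ids = {r.id for r in system.reactions}
    if entry in ids:
        return entry
    candidates = [
        r.id
        for r in system.reactions
        if r.rtype.rule is SkeletonRule.TRSC and r.b.name == entry
    ]
    if len(candidates) == 1:
        return candidates[0]
    raise MutantError(
        f"{label}: cannot resolve overexpression target {entry!r} "
        f"(matches: {candidates or 'none'})"
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CGMMap:
    """Which macro-state node encodes which stage of each replication cycle.

    Stage lists are ordered by progression; roles name the canonical stages
    so the arrest decision table can be written model-independently.
    """

    dna: tuple[tuple[str, str], ...]  # (role, node id), e.g. ("licensed", "[DNAlic]")
    spb: tuple[tuple[str, str], ...]
    bud: tuple[tuple[str, str], ...]

    def cycles(self) -> dict[str, tuple[tuple[str, str], ...]]:
        return {"DNA": self.dna, "SPB": self.spb, "BUD": self.bud}

    def all_nodes(self) -> list[str]:
        return [node for cycle in self.cycles().values() for _, node in cycle]


#: Arrest-stage decision table: first matching row wins.  Keys constrain the
#: active stage role per cycle ("0" = no stage active, None = don't care);
#: ``bud_present`` constrains whether any bud stage beyond "none" is active.
STAGE_TABLE: list[dict] = [
    {"dna": "replicating", "stage": "S", "dna_count": 1, "nuclei": 1},
    {"dna": "segregated", "spb": "separated", "stage": "M", "dna_count": 2, "nuclei": 1},
    {"dna": "replicated", "stage": "G2/M", "dna_count": 2, "nuclei": 1},
    {"dna": "licensed", "stage": "G1", "dna_count": 1, "nuclei": 1},
    {"dna": "0", "spb": "satellite", "stage": "G1", "dna_count": 1, "nuclei": 1},
    {"dna": "0", "spb": "0", "bud_present": True, "stage": "T", "dna_count": 2, "nuclei": 2},
]


def load_stage_table(path: str | Path) -> list[dict]:
    """Load a custom decision table (YAML list of rows like STAGE_TABLE)."""
    import yaml

    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, list):
        raise MutantError("stage table must be a YAML list of mapping rows")
    return table


@dataclass(frozen=True)
class PhenotypeCall:
    viability: str  # "viable" | "lethal"
    mode: str  # "full-cycle" | "partial-cycle-multinucleate" | "point-arrest" | "budget-exceeded"
    stage: str  # "G1" | "S" | "G2/M" | "M" | "T" | "NA"
    profile: tuple[str, ...] = ()  # active macro-state roles (dna, spb, bud)
    dna_count: int | str = "NA"
    nuclei_count: int | str = "NA"
    warnings: tuple[str, ...] = ()


def _active_roles(
    cycle: tuple[tuple[str, str], ...], state: Mapping[str, bool]
) -> list[str]:
    return [role for role, node in cycle if state.get(node, False)]


def _traverses_in_order(
    cycle: tuple[tuple[str, str], ...], attractor: Attractor
) -> bool:
    """Each stage true at least once per period, first activations following
    the declared stage order (cyclically, anchored at the first stage's
    activation)."""
    period = attractor.period
    series = {node: attractor.values(node) for _, node in cycle}
    first_node = cycle[0][1]
    vals = series[first_node]
    if not any(vals):
        return False
    anchor = None
    for t in range(period):
        if vals[t] and not vals[(t - 1) % period]:
            anchor = t
            break
    if anchor is None:  # constantly true first stage: anchor at 0
        anchor = 0
    last = -1
    for _, node in cycle:
        vals = series[node]
        first_t = None
        for off in range(period):
            if vals[(anchor + off) % period]:
                first_t = off
                break
        if first_t is None or first_t < last:
            return False
        last = first_t
    return True


def classify_attractor(
    attractor: Attractor,
    cgm: CGMMap,
    stage_table: Sequence[dict] = STAGE_TABLE,
) -> PhenotypeCall:
    """Map an attractor to a viability/arrest phenotype via the CGM readout."""
    for node in cgm.all_nodes():
        if node not in attractor._index:
            raise MutantError(f"CGM node {node!r} not present in the attractor")
    cycles = cgm.cycles()
    if attractor.kind == "cycle":
        cgm_constant = all(
            len(set(attractor.values(node))) == 1 for node in cgm.all_nodes()
        )
        if not cgm_constant:
            traversal = {
                name: _traverses_in_order(cycle, attractor)
                for name, cycle in cycles.items()
            }
            if all(traversal.values()):
                return PhenotypeCall("viable", "full-cycle", "NA")
            if traversal["DNA"] and traversal["SPB"] and not traversal["BUD"]:
                return PhenotypeCall(
                    "lethal",
                    "partial-cycle-multinucleate",
                    "NA",
                    dna_count="unbounded",
                    nuclei_count="unbounded",
                )
            return PhenotypeCall(
                "lethal",
                "point-arrest",
                "NA",
                warnings=("cyclic attractor with incomplete macro-cycle traversal",),
            )
        # CGM constant over the period: classify like a point arrest
    state0 = dict(zip(attractor.node_ids, attractor.states[0]))
    actives = {name: _active_roles(cycle, state0) for name, cycle in cycles.items()}

    def key(name: str) -> str:
        roles = actives[name]
        if not roles:
            return "0"
        if len(roles) == 1:
            return roles[0]
        return "multi"

    dna, spb, bud = key("DNA"), key("SPB"), key("BUD")
    bud_present = bool(actives["BUD"]) and actives["BUD"] != [cycles["BUD"][0][0]]
    profile = (dna, spb, bud)
    for row in stage_table:
        if "dna" in row and row["dna"] != dna:
            continue
        if "spb" in row and row["spb"] != spb:
            continue
        if "bud" in row and row["bud"] != bud:
            continue
        if "bud_present" in row and row["bud_present"] != bud_present:
            continue
        return PhenotypeCall(
            "lethal",
            "point-arrest",
            row["stage"],
            profile,
            row.get("dna_count", "NA"),
            row.get("nuclei", "NA"),
        )
    return PhenotypeCall(
        "lethal",
        "point-arrest",
        "NA",
        profile,
        warnings=(f"no decision-table row matches profile {profile}",),
    )


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRow:
    spec: MutantSpec
    expected_viability: str  # "viable" | "lethal"
    expected_stage: str = ""


@dataclass
class BenchmarkSummary:
    n_rows: int = 0
    n_correct: int = 0
    correct_lethal: int = 0
    correct_viable: int = 0
    expected_lethal: int = 0
    expected_viable: int = 0
    mismatches: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    arrest_census: Counter = field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_correct": self.n_correct,
            "correct_lethal": self.correct_lethal,
            "correct_viable": self.correct_viable,
            "expected_lethal": self.expected_lethal,
            "expected_viable": self.expected_viable,
            "mismatches": self.mismatches,
            "errors": self.errors,
            "arrest_census": dict(self.arrest_census),
        }


def g0_attractor(network: BooleanNetwork, max_steps: int = 100_000) -> Attractor:
    """The quiescent attractor: default initial vector, all inputs off."""
    return find_attractor(network, max_steps=max_steps)


def run_mutant(
    network: BooleanNetwork,
    system: RxnconSystem,
    spec: MutantSpec,
    cgm: CGMMap,
    g0_state=None,
    max_steps: int = 100_000,
    extra_clamps: Mapping[str, bool] | None = None,
) -> tuple[PhenotypeCall, Attractor | None]:
    """Release one mutant from (modified) G0 with nutrients on and classify."""
    if g0_state is None:
        g0_state = g0_attractor(network, max_steps).states[0]
    clamps = apply_mutant(network, system, spec)
    clamps[NUTRIENTS] = True
    clamps.update(extra_clamps or {})
    try:
        attractor = find_attractor(network, g0_state, clamps, max_steps)
    except BudgetExceededError:
        return (
            PhenotypeCall("lethal", "budget-exceeded", "NA"),
            None,
        )
    return classify_attractor(attractor, cgm), attractor


def benchmark(
    network: BooleanNetwork,
    system: RxnconSystem,
    rows: Sequence[BenchmarkRow],
    cgm: CGMMap,
    max_steps: int = 100_000,
) -> tuple[BenchmarkSummary, list[tuple[BenchmarkRow, PhenotypeCall | None]]]:
    """Simulate every mutant row and score predicted vs expected viability."""
    summary = BenchmarkSummary()
    calls: list[tuple[BenchmarkRow, PhenotypeCall | None]] = []
    g0_state = g0_attractor(network, max_steps).states[0] if rows else None
    for row in rows:
        summary.n_rows += 1
        if row.expected_viability == "lethal":
            summary.expected_lethal += 1
        else:
            summary.expected_viable += 1
        try:
            call, _ = run_mutant(
                network, system, row.spec, cgm, g0_state, max_steps
            )
        except (MutantError, KeyError) as exc:
            summary.errors.append(f"{row.spec.label}: {exc}")
            calls.append((row, None))
            continue
        calls.append((row, call))
        if call.mode == "point-arrest":
            summary.arrest_census[",".join(call.profile)] += 1
        if call.viability == row.expected_viability:
            summary.n_correct += 1
            if call.viability == "lethal":
                summary.correct_lethal += 1
            else:
                summary.correct_viable += 1
        else:
            summary.mismatches.append(
                f"{row.spec.label}: predicted {call.viability} "
                f"({call.mode}, stage {call.stage}), expected {row.expected_viability}"
            )
    return summary, calls


# ---------------------------------------------------------------------------
# mutant table I/O
# ---------------------------------------------------------------------------

def read_mutant_table(path: str | Path) -> list[BenchmarkRow]:
    """Read a mutant benchmark table (TSV or CSV).

    Columns: ``label``, ``deletions`` (``;``-separated), ``locks``
    (``state=0/1`` entries, ``;``-separated), ``overexpress``,
    ``expected_viability`` and optional ``expected_stage``.
    """
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    rows: list[BenchmarkRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for rec in reader:
            locks = []
            for item in (rec.get("locks") or "").split(";"):
                item = item.strip()
                if not item:
                    continue
                state, _, value = item.partition("=")
                locks.append((state.strip(), value.strip() in ("1", "true", "True")))
            spec = MutantSpec(
                label=rec["label"].strip(),
                deletions=tuple(
                    d.strip() for d in (rec.get("deletions") or "").split(";") if d.strip()
                ),
                locks=tuple(locks),
                overexpressions=tuple(
                    o.strip() for o in (rec.get("overexpress") or "").split(";") if o.strip()
                ),
            )
            rows.append(
                BenchmarkRow(
                    spec,
                    rec.get("expected_viability", "").strip() or "viable",
                    rec.get("expected_stage", "").strip(),
                )
            )
    return rows
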