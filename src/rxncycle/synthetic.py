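"""Synthetic reaction-contingency systems and the miniCDC fixture.

Two generators live here.  :func:`generate_random_system` produces valid
random systems with controllable structure for property testing: a
synthesis/degradation scaffold per component first, then bond/modification
decorations, then contingencies sampled only among producible states, so the
result always validates cleanly when the turnover guarantee is on.

:func:`build_minicdc` returns a fixed miniature cell-division-cycle system
(~16 components) whose qualitative behaviour mirrors the genome-scale
phenomenology: quiescent arrest without nutrients, ordered progression of
three coupled macro cycles (DNA replication, spindle-pole-body duplication,
budding) with nutrients, pheromone/hydroxyurea arrests, and sensible mutant
phenotypes.  The exact wiring is an implementation artefact; the behavioural
contract, not the wiring, is the test surface.  The serialised form is
frozen under version control and ``build_minicdc`` must reproduce it
bit-for-bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .compile import DelaySpec
from .core import ComponentSpec, Modifier, RxnconSystem
from .phenotype import CGMMap

FROZEN_MINICDC_RESOURCE = "minicdc.tsv"


# ---------------------------------------------------------------------------
# random systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for random system generation; the seed fully determines the
    output."""

    n_components: int = 10
    n_decorations: int = 15  # bond/modification reactions on top of the scaffold
    reaction_mix: tuple[tuple[str, float], ...] = (
        ("ppi+", 0.35),
        ("p+", 0.35),
        ("p-", 0.10),
        ("ppi-", 0.05),
        ("ub+", 0.15),
    )
    contingency_density: float = 1.0  # expected contingencies per reaction
    gate_prob: float = 0.15
    gate_max_arity: int = 3
    turnover: bool = True  # guarantee every modification/synthesis is turned over
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.reaction_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reaction_mix weights must sum to 1, got {total}")
        if self.n_components < 1:
            raise ValueError("need at least one component")


def _pick(rng: random.Random, mix: tuple[tuple[str, float], ...]) -> str:
    u = rng.random()
    acc = 0.0
    for name, w in mix:
        acc += w
        if u < acc:
            return name
    return mix[-1][0]


def generate_random_system(config: GeneratorConfig) -> RxnconSystem:
    """Generate a valid random system; identical config -> identical system."""
    rng = random.Random(config.seed)
    system = RxnconSystem()
    comps = [f"P{i + 1}" for i in range(config.n_components)]
    used_ids: set[str] = set()

    def add_unique(rtype: str, a: ComponentSpec, b: ComponentSpec) -> bool:
        rid = f"{a}_{rtype}_{b}"
        if rid in used_ids:
            return False
        used_ids.add(rid)
        system.add_reaction(rtype, a, b)
        return True

    # scaffold: synthesis + degradation per component
    for c in comps:
        add_unique("syn", ComponentSpec("Synth"), ComponentSpec(c))
        if config.turnover or rng.random() < 0.7:
            add_unique("deg", ComponentSpec("Prot"), ComponentSpec(c))

    # decorations
    bonds: list[tuple[str, str, str, str]] = []
    mods: list[tuple[str, str, str]] = []  # (component, residue, type name)
    domain_counter = 0
    residue_counter = 0
    for _ in range(config.n_decorations):
        rtype = _pick(rng, config.reaction_mix)
        if rtype in ("ppi+",):
            a, b = rng.choice(comps), rng.choice(comps)
            domain_counter += 1
            da, db = f"d{domain_counter}a", f"d{domain_counter}b"
            if add_unique(
                "ppi+", ComponentSpec(a, domain=da), ComponentSpec(b, domain=db)
            ):
                bonds.append((a, da, b, db))
        elif rtype == "ppi-":
            if not bonds:
                continue
            a, da, b, db = rng.choice(bonds)
            add_unique(
                "ppi-", ComponentSpec(a, domain=da), ComponentSpec(b, domain=db)
            )
        elif rtype in ("p+", "ub+"):
            enzyme, substrate = rng.choice(comps), rng.choice(comps)
            residue_counter += 1
            res = f"r{residue_counter}"
            if add_unique(
                rtype, ComponentSpec(enzyme), ComponentSpec(substrate, residue=res)
            ):
                mods.append((substrate, res, rtype))
        elif rtype == "p-":
            added = [m for m in mods if m[2] == "p+"]
            if not added:
                continue
            substrate, res, _ = rng.choice(added)
            enzyme = rng.choice(comps)
            add_unique(
                "p-", ComponentSpec(enzyme), ComponentSpec(substrate, residue=res)
            )

    system.finalise()

    # contingencies among producible (or synthesised-neutral) states
    producible = sorted(
        {
            str(s)
            for r in system.reactions
            for s in system.skeletons[r.id].produced
        }
    )
    if config.contingency_density > 0 and not producible:
        raise ValueError("contingencies requested but no producible states exist")
    gate_counter = 0
    modifier_mix = (
        (Modifier.REQUIREMENT, 0.4),
        (Modifier.INHIBITION, 0.3),
        (Modifier.POSITIVE, 0.15),
        (Modifier.NEGATIVE, 0.15),
    )
    for r in list(system.reactions):
        n_here = int(config.contingency_density) + (
            1 if rng.random() < config.contingency_density % 1 else 0
        )
        for _ in range(n_here):
            own = {str(s) for sk in (system.skeletons[r.id],) for s in (*sk.produced, *sk.consumed)}
            choices = [s for s in producible if s not in own]
            if not choices:
                continue
            modifier = _pick_modifier(rng, modifier_mix)
            if rng.random() < config.gate_prob and len(choices) >= 2:
                gate_counter += 1
                gid = f"<g{gate_counter}>"
                arity = rng.randint(2, max(2, config.gate_max_arity))
                gtype = rng.choice([Modifier.AND, Modifier.OR])
                for child in rng.sample(choices, min(arity, len(choices))):
                    system.add_contingency(gid, child, gtype)
                system.add_contingency(r.id, gid, modifier)
            else:
                system.add_contingency(r.id, rng.choice(choices), modifier)
    return system.finalise()


def _pick_modifier(rng: random.Random, mix) -> Modifier:
    u = rng.random()
    acc = 0.0
    for m, w in mix:
        acc += w
        if u < acc:
            return m
    return mix[-1][0]


# ---------------------------------------------------------------------------
# miniCDC
# ---------------------------------------------------------------------------

@dataclass
class MiniCDCFixture:
    """The miniature cell-division-cycle system plus everything needed to
    simulate and classify it."""

    system: RxnconSystem
    cgm: CGMMap
    inputs: tuple[str, ...]
    #: regression metadata recorded once from simulation after the fixture
    #: was frozen (see the behavioural-contract tests)
    metadata: dict = field(default_factory=dict)

    def default_delays(self, k: int = 20) -> DelaySpec:
        return DelaySpec.default_for(self.system, k=k)


# canonical state strings used in the wiring
CLN_CDK = "Cdk_[cyc1]--Cln_[cdk]"
CLB_CDK = "Cdk_[cyc2]--Clb_[cdk]"
SIC_CDK = "Cdk_[inh]--Sic_[cdk]"
SIC_P = "Sic_[t]-P"

#: wild-type cycle period of the compiled fixture under default 20-step
#: delays, recorded by simulation once and asserted as a regression value
MINICDC_PERIOD = 80
#: transient from the quiescent state to the cycle under the same protocol
MINICDC_TRANSIENT = 35


def build_minicdc() -> MiniCDCFixture:
    """Construct the frozen miniature cell-cycle fixture.

    Architecture: three regulatory modules gate the three transitions of a
    coarse-grained layer of three macro cycles.

    * G1/S: nutrient-dependent (pheromone-inhibited) transcription of the G1
      cyclin Cln; Cdk-Cln drives DNA licensing->replication, SPB
      satellite->duplication and bud emergence, and removes the CDK
      inhibitor Sic (phosphorylation-triggered degradation).
    * G2/M: the B-type cyclin Clb is transcribed only once DNA replication
      has finished; Cdk-Clb drives segregation, SPB separation and bud
      growth, opposed by Sic.
    * M/G1: the exit phosphatase is transcribed only when segregation and
      SPB separation are both complete (an AND gate), and resets all three
      macro cycles.

    Transcription is slow (default 20-step delay) and so is replication
    progression (tagged); everything is turned over so the system passes
    validation with an empty report.
    """
    system = RxnconSystem()
    C = ComponentSpec

    def rxn(rtype, a, b, tags=()):
        return system.add_reaction(rtype, a, b, tags=tags)

    def cont(target, effector, modifier):
        system.add_contingency(target, effector, modifier)

    # --- G1/S module: Cln expression and Cdk loading -----------------------
    r_trsc_cln = rxn("trsc", C("SBF"), C("Cln"))
    cont(r_trsc_cln.id, "[Nutrients]", "!")
    cont(r_trsc_cln.id, "[Pheromone]", "x")
    rxn("trsl", C("Ribo"), C("Cln"))
    rxn("deg", C("Prt"), C("ClnmRNA"))
    rxn("deg", C("Prt"), C("Cln"))
    rxn("ppi+", C("Cdk", domain="cyc1"), C("Cln", domain="cdk"))

    # --- G2/M module: Clb expression gated on finished replication ---------
    r_trsc_clb = rxn("trsc", C("Mcm1"), C("Clb"))
    cont(r_trsc_clb.id, "[DNAdone]", "!")
    rxn("trsl", C("Ribo"), C("Clb"))
    rxn("deg", C("Prt"), C("ClbmRNA"))
    rxn("deg", C("Prt"), C("Clb"))
    rxn("ppi+", C("Cdk", domain="cyc2"), C("Clb", domain="cdk"))

    # --- M/G1 module: mitotic exit driver ----------------------------------
    r_trsc_exit = rxn("trsc", C("Swi5"), C("Exit"))
    cont("<exitOK>", "[DNAseg]", "AND")
    cont("<exitOK>", "[SPBsep]", "AND")
    cont(r_trsc_exit.id, "<exitOK>", "!")
    rxn("trsl", C("Ribo"), C("Exit"))
    rxn("deg", C("Prt"), C("ExitmRNA"))
    rxn("deg", C("Prt"), C("Exit"))

    # --- CDK inhibitor: Sic blocks cycle entry until phosphorylated --------
    rxn("syn", C("Ribo"), C("Sic"))
    r_deg_sic = rxn("deg", C("Prt"), C("Sic"))
    cont(r_deg_sic.id, SIC_P, "!")
    r_sic_bind = rxn("ppi+", C("Sic", domain="cdk"), C("Cdk", domain="inh"))
    cont(r_sic_bind.id, SIC_P, "x")
    r_sic_p = rxn("p+", C("Cdk"), C("Sic", residue="t"))
    cont(r_sic_p.id, CLN_CDK, "!")

    # --- bystanders (no coupling to the cycle) -----------------------------
    rxn("ppi+", C("Ygp1", domain="b"), C("Ygp2", domain="b"), tags=("no-turnover",))

    # --- coarse-grained macro cycles ---------------------------------------
    def mt(src, dst, tags=()):
        r = rxn("mt", C(src), C(dst), tags=tags)
        cont(r.id, f"[{src}]", "!")
        return r

    r = mt("DNAlic", "DNArep")
    cont(r.id, CLN_CDK, "!")
    cont(r.id, SIC_CDK, "x")
    r = mt("DNArep", "DNAdone", tags=("replication",))
    cont(r.id, "[Histones]", "!")
    cont(r.id, "[HU]", "x")
    r = mt("DNAdone", "DNAseg")
    cont(r.id, CLB_CDK, "!")
    cont(r.id, SIC_CDK, "x")
    cont(r.id, "[NOC]", "x")
    r = mt("DNAseg", "DNAlic")
    cont(r.id, "Exit", "!")

    r = mt("SPBsat", "SPBdup")
    cont(r.id, CLN_CDK, "!")
    cont(r.id, SIC_CDK, "x")
    r = mt("SPBdup", "SPBsep")
    cont(r.id, CLB_CDK, "!")
    cont(r.id, SIC_CDK, "x")
    r = mt("SPBsep", "SPBsat")
    cont(r.id, "Exit", "!")

    r = mt("BUD0", "BUDsmall")
    cont(r.id, CLN_CDK, "!")
    cont(r.id, SIC_CDK, "x")
    cont(r.id, "[LatA]", "x")
    r = mt("BUDsmall", "BUDlarge")
    cont(r.id, CLB_CDK, "!")
    cont(r.id, "[LatA]", "x")
    r = mt("BUDlarge", "BUDdiv")
    cont(r.id, "Exit", "!")
    mt("BUDdiv", "BUD0")

    # quiescent-state macro seeds
    for node in ("[DNAlic]", "[SPBsat]", "[BUD0]", "[Histones]"):
        system.declare_initial_true(node)

    system.finalise()
    cgm = CGMMap(
        dna=(
            ("licensed", "[DNAlic]"),
            ("replicating", "[DNArep]"),
            ("replicated", "[DNAdone]"),
            ("segregated", "[DNAseg]"),
        ),
        spb=(
            ("satellite", "[SPBsat]"),
            ("duplicated", "[SPBdup]"),
            ("separated", "[SPBsep]"),
        ),
        bud=(
            ("none", "[BUD0]"),
            ("small", "[BUDsmall]"),
            ("large", "[BUDlarge]"),
            ("divided", "[BUDdiv]"),
        ),
    )
    return MiniCDCFixture(
        system=system,
        cgm=cgm,
        inputs=("[Nutrients]", "[Pheromone]", "[HU]", "[LatA]", "[NOC]", "[Histones]"),
        metadata={
            "period": MINICDC_PERIOD,
            "transient_from_g0": MINICDC_TRANSIENT,
            "g1_transcription_driver": "SBF",
            "cdk_inhibitor": "Sic",
        },
    )


def frozen_minicdc_text() -> str:
    """The version-controlled serialisation of the miniCDC system."""
    return (
        resources.files("rxncycle").joinpath("data", FROZEN_MINICDC_RESOURCE).read_text()
    )
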