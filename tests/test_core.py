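"""Knowledge-base types, skeleton-state generation and mutual exclusion."""

import pytest
from hypothesis import given, settings, strategies as st

from rxncycle import ComponentSpec, RxnconSystem, parse_state, skeleton_states
from rxncycle.core import (
    Locus,
    LocusKind,
    SkeletonError,
    State,
    StateKind,
    StateSyntaxError,
    infer_component_kind,
)


def _single_reaction_system(rtype, a, b):
    system = RxnconSystem()
    r = system.add_reaction(rtype, a, b)
    system.finalise()
    return system, r


class TestStateGrammar:
    @pytest.mark.parametrize(
        "text,kind",
        [
            ("Cdc28_[cyclin]--Cln1_[cdc28]", StateKind.BOND),
            ("Cdc28_[cyclin]--0", StateKind.UNBOUND),
            ("Cdc28_[T169]-P", StateKind.MOD),
            ("Cdc28_[T169]-0", StateKind.UNMOD),
            ("[Nutrients]", StateKind.GLOBAL),
            ("Cdc14", StateKind.COMPONENT),
        ],
    )
    def test_parse_and_roundtrip(self, text, kind):
        state = parse_state(text)
        assert state.kind is kind
        assert str(parse_state(str(state))) == str(state)

    def test_bond_identity_is_orientation_free(self):
        a = parse_state("A_[x]--B_[y]")
        b = parse_state("B_[y]--A_[x]")
        assert a == b and str(a) == str(b)

    def test_rejects_garbage(self):
        with pytest.raises(StateSyntaxError):
            parse_state("A_[x")

    names = st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
        min_size=1,
        max_size=6,
    )

    @given(comp=names, locus=names, mod=st.sampled_from(["P", "Ub", "Me"]))
    @settings(max_examples=100, derandomize=True)
    def test_modification_roundtrip_property(self, comp, locus, mod):
        state = State.modification(Locus(comp, locus, LocusKind.RESIDUE), mod)
        assert parse_state(str(state)) == state
        (neutral,) = state.neutral_complements()
        assert neutral.is_neutral and neutral.loci == state.loci


class TestSkeletons:
    def test_bond_formation_produces_bond_consumes_neutrals(self):
        # Cdc28 and Cln1 bind via their cyclin and cdc28 binding domains
        system, r = _single_reaction_system(
            "ppi+",
            ComponentSpec("Cdc28", domain="cyclin"),
            ComponentSpec("Cln1", domain="cdc28"),
        )
        sk = skeleton_states(r, system)
        assert {str(s) for s in sk.produced} == {"Cdc28_[cyclin]--Cln1_[cdc28]"}
        assert {str(s) for s in sk.consumed} == {
            "Cdc28_[cyclin]--0",
            "Cln1_[cdc28]--0",
        }
        assert not sk.synthesised and not sk.degraded

    def test_phosphorylation_produces_mod_consumes_neutral(self):
        system, r = _single_reaction_system(
            "p+", ComponentSpec("K"), ComponentSpec("A", residue="r")
        )
        sk = skeleton_states(r, system)
        assert {str(s) for s in sk.produced} == {"A_[r]-P"}
        assert {str(s) for s in sk.consumed} == {"A_[r]-0"}

    def test_degradation_covers_every_state_of_target(self):
        system = RxnconSystem()
        system.add_reaction("ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"))
        system.add_reaction("p+", ComponentSpec("K"), ComponentSpec("A", residue="r"))
        deg = system.add_reaction("deg", ComponentSpec("Prt"), ComponentSpec("A"))
        system.finalise()
        degraded = {str(s) for s in skeleton_states(deg, system).degraded}
        assert degraded == {"A_[x]--0", "A_[x]--B_[y]", "A_[r]-P", "A_[r]-0"}
        sk = skeleton_states(deg, system)
        assert not sk.produced and not sk.consumed

    def test_bond_on_residue_locus_rejected(self):
        system = RxnconSystem()
        system.add_reaction(
            "ppi+", ComponentSpec("A", residue="r"), ComponentSpec("B", domain="y")
        )
        with pytest.raises(SkeletonError):
            system.finalise()

    def test_modification_on_domain_locus_rejected(self):
        system = RxnconSystem()
        system.add_reaction("p+", ComponentSpec("K"), ComponentSpec("A", domain="d"))
        with pytest.raises(SkeletonError):
            system.finalise()

    def test_skeletons_deterministic(self):
        system = RxnconSystem()
        r = system.add_reaction(
            "ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y")
        )
        system.finalise()
        first = skeleton_states(r, system)
        assert skeleton_states(r, system) == first

    def test_transcription_translation_use_gene_and_mrna(self):
        system = RxnconSystem()
        trsc = system.add_reaction("trsc", ComponentSpec("TF"), ComponentSpec("X"))
        trsl = system.add_reaction("trsl", ComponentSpec("Ribo"), ComponentSpec("X"))
        system.finalise()
        assert trsc.effective_components() == ("TF", "Xgene")
        assert trsl.effective_components() == ("Ribo", "XmRNA")
        assert {str(s) for s in skeleton_states(trsc, system).synthesised} == {"XmRNA"}
        assert infer_component_kind("Xgene")[0].value == "gene"
        assert infer_component_kind("XmRNA")[0].value == "mRNA"


class TestMutualExclusion:
    def test_groups_partition_locus_states(self):
        system = RxnconSystem()
        system.add_reaction("ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"))
        system.add_reaction("ppi+", ComponentSpec("A", domain="x"), ComponentSpec("C", domain="z"))
        system.add_reaction("p+", ComponentSpec("K"), ComponentSpec("A", residue="r"))
        system.finalise()
        groups = {
            tuple(sorted(str(s) for s in g)): g for g in system.mutual_exclusion_groups()
        }
        # domain A_[x]: two bonds plus the unbound neutral
        ax = [g for key, g in groups.items() if any("A_[x]--0" in k for k in key)]
        assert len(ax) == 1 and len(ax[0]) == 3
        # residue A_[r]: modified + unmodified
        ar = [g for key, g in groups.items() if any("A_[r]" in k for k in key)]
        assert len(ar) == 1 and len(ar[0]) == 2

    def test_minicdc_group_count_matches_locus_count(self, minicdc):
        system = minicdc.system
        loci = {locus for s in system.states for locus in s.loci}
        assert len(system.mutual_exclusion_groups()) == len(loci)

    def test_every_nonglobal_effector_in_exactly_one_group(self, minicdc):
        system = minicdc.system
        groups = system.mutual_exclusion_groups()
        for c in system.contingencies:
            if c.effector.startswith(("[", "<")):
                continue
            state = parse_state(c.effector)
            if not state.loci:
                continue  # component-presence effector, no locus
            membership = sum(
                1 for g in groups if str(state) in {str(s) for s in g}
            )
            assert membership == len(state.loci)
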