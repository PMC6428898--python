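"""Bipartite Boolean model compilation: node census, update rules, delays,
initial vector, determinism and presence conservation."""

import pytest

from rxncycle import (
    ComponentSpec,
    DelaySpec,
    GeneratorConfig,
    RxnconSystem,
    compile_network,
    find_attractor,
    generate_random_system,
    simulate,
)
from rxncycle.compile import (
    And,
    CompileError,
    Const,
    NodeKind,
    Not,
    Ref,
    insert_delays,
    reaction_update_rule,
)


def _bond_system(**kwargs):
    system = RxnconSystem()
    r = system.add_reaction(
        "ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"),
        tags=("no-turnover",), **kwargs
    )
    return system, r


class TestCompile:
    def test_single_bond_reaction_gives_four_nodes(self):
        """One reaction node, the bond state and the two reactant neutrals."""
        system, _ = _bond_system()
        network = compile_network(system.finalise())
        assert len(network) == 4
        assert network.census() == {"state": 3, "reaction": 1, "total": 4}

    def test_size_law_on_generated_systems(self):
        for seed in range(5):
            system = generate_random_system(GeneratorConfig(n_components=6, seed=seed))
            delays = DelaySpec({system.reactions[0].id: 7})
            network = compile_network(system, delays)
            n_states = sum(1 for n in network.nodes if n.kind is NodeKind.STATE)
            n_rxn = sum(1 for n in network.nodes if n.kind is NodeKind.REACTION)
            n_gates = sum(1 for n in network.nodes if n.kind is NodeKind.GATE)
            n_glob = sum(1 for n in network.nodes if n.kind is NodeKind.GLOBAL)
            n_delay = sum(1 for n in network.nodes if n.kind is NodeKind.DELAY)
            assert len(network) == n_states + n_rxn + n_gates + n_glob + n_delay
            assert n_rxn == len(system.reactions)
            assert n_gates == len(system.gates)
            assert n_delay == 7

    def test_compile_is_deterministic(self, minicdc):
        a = compile_network(minicdc.system, minicdc.default_delays())
        b = compile_network(minicdc.system, minicdc.default_delays())
        assert a.stable_hash() == b.stable_hash()
        assert a.to_json() == b.to_json()

    def test_dangling_effector_blocks_compilation(self):
        system, r = _bond_system()
        system.add_contingency(r.id, "Zzz_[q]-P", "!")
        system.finalise()
        with pytest.raises(CompileError, match="validation errors"):
            compile_network(system)


class TestReactionRules:
    def test_unregulated_reaction_is_presence_factors_only(self):
        system, r = _bond_system()
        system.finalise()
        rule = reaction_update_rule(r, system)
        refs = set(rule.refs())
        assert refs == {"A_[x]--0", "A_[x]--B_[y]", "B_[y]--0"}
        assert not any(isinstance(c, Not) for c in getattr(rule, "children", ()))

    def test_requirement_enters_conjunctively(self):
        system = RxnconSystem()
        r = system.add_reaction(
            "ppi+", ComponentSpec("Cdc28", domain="cyclin"), ComponentSpec("Cln1", domain="cdc28"),
            tags=("no-turnover",),
        )
        system.add_reaction(
            "p+", ComponentSpec("Cak1"), ComponentSpec("Cdc28", residue="T169"),
            tags=("no-turnover",),
        )
        system.add_contingency(r.id, "Cdc28_[T169]-P", "!")
        system.finalise()
        rule = reaction_update_rule(r, system)
        assert isinstance(rule, And)
        assert Ref("Cdc28_[T169]-P") in rule.children

    def test_inhibition_enters_negated(self):
        system, r = _bond_system()
        system.add_reaction(
            "p+", ComponentSpec("K"), ComponentSpec("A", residue="r"), tags=("no-turnover",)
        )
        system.add_contingency(r.id, "A_[r]-P", "x")
        system.finalise()
        rule = reaction_update_rule(r, system)
        assert Not(Ref("A_[r]-P")) in rule.children

    @pytest.mark.parametrize("modifier", ["k+", "k-"])
    def test_quantitative_modifiers_are_no_ops(self, modifier):
        system, r = _bond_system()
        system.add_reaction(
            "p+", ComponentSpec("K"), ComponentSpec("A", residue="r"), tags=("no-turnover",)
        )
        system.add_contingency(r.id, "A_[r]-P", modifier)
        system.finalise()
        plain_system, plain_r = _bond_system()
        plain_system.add_reaction(
            "p+", ComponentSpec("K"), ComponentSpec("A", residue="r"), tags=("no-turnover",)
        )
        plain_system.finalise()
        assert reaction_update_rule(r, system) == reaction_update_rule(
            plain_r, plain_system
        )


class TestStateRules:
    def test_unregulated_state_retains_value(self):
        """With producer and consumer off, the rule reduces to self-retention."""
        system, _ = _bond_system()
        network = compile_network(system.finalise())
        init = dict(network.initial)
        init["A_[x]--B_[y]"] = True
        init["A_[x]--0"] = False  # inconsistent on purpose; nothing fires
        clamps = {"A_[x]_ppi+_B_[y]": False}
        states = simulate(network, tuple(init[n.id] for n in network.nodes), clamps, 3)
        idx = network.index["A_[x]--B_[y]"]
        assert all(s[idx] for s in states)

    def test_opposing_reactions_can_hold_both_states_true(self):
        """Kinase and phosphatase both firing with both sources present keep
        the modified and unmodified states simultaneously true at the next
        step (population-level semantics, no runtime exclusivity)."""
        system = RxnconSystem()
        system.add_reaction("p+", ComponentSpec("K"), ComponentSpec("A", residue="r"))
        system.add_reaction("p-", ComponentSpec("PPT"), ComponentSpec("A", residue="r"))
        network = compile_network(system.finalise())
        values = {n.id: True for n in network.nodes}  # both states, both rxns on
        state = tuple(values[n.id] for n in network.nodes)
        nxt = dict(zip([n.id for n in network.nodes], simulate(network, state, None, 1)[-1]))
        assert nxt["A_[r]-P"] and nxt["A_[r]-0"]
        # and that configuration is self-sustaining
        assert find_attractor(network, state).is_point()

    def test_degradation_clears_target_and_releases_partner(self):
        system = RxnconSystem()
        system.add_reaction(
            "ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"),
            tags=("no-turnover",),
        )
        deg = system.add_reaction("deg", ComponentSpec("Prt"), ComponentSpec("B"))
        system.finalise()
        network = compile_network(system)
        attractor = find_attractor(network)
        final = dict(zip(attractor.node_ids, attractor.states[0]))
        # B is gone entirely; A is back in (or still in) its unbound neutral
        assert not final["B_[y]--0"] and not final["A_[x]--B_[y]"]
        assert final["A_[x]--0"]
        assert deg.id in network.index


class TestDelays:
    def test_delay_adds_exactly_k_nodes(self, minicdc):
        base = compile_network(minicdc.system)
        rid = minicdc.system.reactions[0].id
        delayed = insert_delays(base, DelaySpec({rid: 20}))
        assert len(delayed) == len(base) + 20

    def test_zero_delay_is_identity(self, minicdc):
        base = compile_network(minicdc.system)
        assert insert_delays(base, DelaySpec({})).stable_hash() == base.stable_hash()

    def test_unknown_reaction_delay_is_error(self, minicdc):
        base = compile_network(minicdc.system)
        with pytest.raises(CompileError, match="unknown reaction"):
            insert_delays(base, DelaySpec({"nope": 3}))

    def test_default_delays_cover_transcription_and_replication(self, minicdc):
        delays = minicdc.default_delays()
        ids = set(delays.delays)
        assert ids == {
            "SBF_trsc_Cln",
            "Mcm1_trsc_Clb",
            "Swi5_trsc_Exit",
            "DNArep_mt_DNAdone",
        }
        assert all(k == 20 for k in delays.delays.values())

    @pytest.mark.parametrize("hold,fires", [(19, False), (21, True)])
    def test_window_semantics_against_spec_example(self, hold, fires):
        """A k=20 chain needs its condition to hold long enough: 19 steps is
        never enough, 21 steps fires at step 21."""
        system = RxnconSystem()
        system.add_reaction(
            "ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"),
            tags=("no-turnover",),
        )
        r = system.add_reaction(
            "p+", ComponentSpec("E"), ComponentSpec("A", residue="r"), tags=("no-turnover",)
        )
        system.add_contingency(r.id, "A_[x]--B_[y]", "!")
        system.finalise()
        network = compile_network(system, DelaySpec({r.id: 20}))
        # drive the condition through the bond state by clamping it
        idx = network.index[r.id]
        init = network.initial_vector()
        fired = []
        state = init
        from rxncycle.simulate import step as one_step

        for t in range(1, hold + 5):
            clamp_value = t <= hold
            state = one_step(network, state, {"A_[x]--B_[y]": clamp_value})
            fired.append(state[idx])
        assert any(fired) == fires
        if fires:
            assert fired.index(True) + 1 == 21


class TestInitialVector:
    def test_neutrals_true_everything_else_false(self, minicdc, minicdc_network):
        init = dict(zip([n.id for n in minicdc_network.nodes], minicdc_network.initial_vector()))
        for node in minicdc_network.nodes:
            if node.kind is NodeKind.STATE:
                assert init[node.id] == node.neutral
            elif node.kind in (NodeKind.REACTION, NodeKind.GATE, NodeKind.DELAY):
                assert not init[node.id]
        assert init["[Histones]"]
        # declared quiescent seeds
        for seed in ("[DNAlic]", "[SPBsat]", "[BUD0]"):
            assert init[seed]
        assert not init["[Nutrients]"]

    def test_override_of_unknown_node_is_error(self, minicdc):
        with pytest.raises(CompileError, match="unknown node"):
            compile_network(minicdc.system, initial_overrides={"[Zork]": True})

    def test_empty_system_gives_empty_vector(self):
        network = compile_network(RxnconSystem().finalise())
        assert len(network) == 0 and network.initial_vector() == ()


class TestPresenceConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_component_without_turnover_stays_present(self, seed):
        """A component with neither synthesis nor degradation keeps at least
        one of its states true along any trajectory from the default vector."""
        system = RxnconSystem()
        system.add_reaction(
            "ppi+", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y"),
            tags=("no-turnover",),
        )
        system.add_reaction(
            "p+", ComponentSpec("B"), ComponentSpec("A", residue="r"), tags=("no-turnover",)
        )
        system.add_reaction(
            "ppi-", ComponentSpec("A", domain="x"), ComponentSpec("B", domain="y")
        )
        system.finalise()
        network = compile_network(system)
        a_states = [network.index[str(s)] for s in system.states_of_component("A")]
        import random

        rng = random.Random(seed)
        init = tuple(rng.random() < 0.5 for _ in network.nodes)
        # force presence at t0, then check it is conserved
        init = tuple(
            True if i == a_states[0] else v for i, v in enumerate(init)
        )
        for state in simulate(network, init, None, 50):
            assert any(state[i] for i in a_states)
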