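"""Mutant clamps, attractor classification and benchmarking on miniCDC."""

import pytest

from rxncycle import (
    BenchmarkRow,
    MutantSpec,
    apply_mutant,
    benchmark,
    classify_attractor,
    find_attractor,
    read_mutant_table,
    run_mutant,
)
from rxncycle.phenotype import MutantError


class TestApplyMutant:
    def test_deletion_clamps_protein_gene_and_mrna_states(self, minicdc, minicdc_network):
        clamps = apply_mutant(
            minicdc_network, minicdc.system, MutantSpec("cln", deletions=("Cln",))
        )
        assert clamps == {
            "Cln_[cdk]--0": False,
            "Cdk_[cyc1]--Cln_[cdk]": False,
            "Clngene": False,
            "ClnmRNA": False,
        }

    def test_alanine_lock_fixes_state_and_complement(self, minicdc, minicdc_network):
        clamps = apply_mutant(
            minicdc_network, minicdc.system,
            MutantSpec("sicA", locks=(("Sic_[t]-P", False),)),
        )
        assert clamps == {"Sic_[t]-P": False, "Sic_[t]-0": True}

    def test_overexpression_clamps_transcription_reaction(self, minicdc, minicdc_network):
        clamps = apply_mutant(
            minicdc_network, minicdc.system,
            MutantSpec("oe", overexpressions=("Clb",)),
        )
        assert clamps == {"Mcm1_trsc_Clb": True}

    def test_empty_spec_gives_empty_clamps(self, minicdc, minicdc_network):
        assert apply_mutant(minicdc_network, minicdc.system, MutantSpec("wt")) == {}

    def test_deletion_lock_conflict_rejected(self, minicdc, minicdc_network):
        with pytest.raises(MutantError, match="conflicts"):
            apply_mutant(
                minicdc_network, minicdc.system,
                MutantSpec("bad", deletions=("Sic",), locks=(("Sic_[t]-P", True),)),
            )

    def test_unknown_component_rejected(self, minicdc, minicdc_network):
        with pytest.raises(MutantError, match="unknown component"):
            apply_mutant(
                minicdc_network, minicdc.system, MutantSpec("bad", deletions=("Cln3",))
            )


class TestClassification:
    def test_wild_type_cycle_is_viable(self, minicdc, minicdc_wt):
        call = classify_attractor(minicdc_wt, minicdc.cgm)
        assert call.viability == "viable" and call.mode == "full-cycle"

    def test_g1_arrest_profile(self, minicdc, minicdc_network, minicdc_g0):
        """Deleting the G1 transcription driver arrests with licensed DNA,
        SPB satellite and no bud: a G1 point arrest with 1 DNA, 1 nucleus."""
        call, _ = run_mutant(
            minicdc_network, minicdc.system,
            MutantSpec("sbf", deletions=("SBF",)),
            minicdc.cgm, minicdc_g0.states[0],
        )
        assert call.viability == "lethal"
        assert call.mode == "point-arrest"
        assert call.stage == "G1"
        assert call.profile == ("licensed", "satellite", "none")
        assert (call.dna_count, call.nuclei_count) == (1, 1)

    def test_budless_cycle_is_multinucleate(self, minicdc, minicdc_network, minicdc_g0):
        """Blocking bud formation while DNA and SPB cycles continue gives the
        partial cyclic attractor scored as multinucleate lethality."""
        attractor = find_attractor(
            minicdc_network, minicdc_g0.states[0],
            {"[Nutrients]": True, "[LatA]": True},
        )
        call = classify_attractor(attractor, minicdc.cgm)
        assert call.mode == "partial-cycle-multinucleate"
        assert call.viability == "lethal"
        assert call.dna_count == "unbounded" and call.nuclei_count == "unbounded"

    def test_every_attractor_maps_to_exactly_one_call(self, minicdc, minicdc_network, minicdc_g0):
        for clamps in ({}, {"[Nutrients]": True}, {"[Nutrients]": True, "[HU]": True}):
            attractor = find_attractor(minicdc_network, minicdc_g0.states[0], clamps)
            call = classify_attractor(attractor, minicdc.cgm)
            assert call.viability in ("viable", "lethal")
            assert call.stage in ("G1", "S", "G2/M", "M", "T", "NA")


class TestWildTypeConsistency:
    def test_empty_mutant_reproduces_wild_type_attractor(
        self, minicdc, minicdc_network, minicdc_g0, minicdc_wt
    ):
        call, attractor = run_mutant(
            minicdc_network, minicdc.system, MutantSpec("wt"),
            minicdc.cgm, minicdc_g0.states[0],
        )
        assert call.viability == "viable"
        assert attractor.states == minicdc_wt.states

    def test_inert_bystander_deletion_leaves_cycle_unchanged(
        self, minicdc, minicdc_network, minicdc_g0, minicdc_wt
    ):
        """Ygp1 has no outgoing contingencies and no skeleton overlap with
        the cycle; deleting it must not perturb any non-Ygp node."""
        call, attractor = run_mutant(
            minicdc_network, minicdc.system,
            MutantSpec("ygp1", deletions=("Ygp1",)),
            minicdc.cgm, minicdc_g0.states[0],
        )
        assert call.viability == "viable"
        keep = [
            i
            for i, n in enumerate(minicdc_network.nodes)
            if "Ygp" not in n.id
        ]
        project = lambda states: [tuple(s[i] for i in keep) for s in states]
        assert project(attractor.states) == project(minicdc_wt.states)


class TestBenchmark:
    def test_empty_table_gives_zero_counts(self, minicdc, minicdc_network):
        summary, calls = benchmark(minicdc_network, minicdc.system, [], minicdc.cgm)
        assert summary.n_rows == 0 and summary.n_correct == 0 and not calls

    def test_minicdc_benchmark_scores_designed_expectations(
        self, minicdc, minicdc_network
    ):
        rows = _minicdc_rows()
        summary, calls = benchmark(
            minicdc_network, minicdc.system, rows, minicdc.cgm
        )
        assert summary.n_rows == len(rows)
        assert not summary.errors
        assert summary.n_correct == summary.n_rows
        assert summary.correct_lethal == summary.expected_lethal == 7
        assert summary.correct_viable == summary.expected_viable == 5
        stages = {
            row.spec.label: call.stage for row, call in calls if call.mode == "point-arrest"
        }
        for label, expected in (
            ("sbf", "G1"), ("cdk", "G1"), ("cln", "G1"), ("sicA", "G1"),
            ("mcm1", "G2/M"), ("clb", "G2/M"), ("swi5", "M"),
        ):
            assert stages[label] == expected

    def test_per_row_failures_recorded_and_run_continues(self, minicdc, minicdc_network):
        rows = [
            BenchmarkRow(MutantSpec("bogus", deletions=("NoSuch",)), "lethal"),
            BenchmarkRow(MutantSpec("sic", deletions=("Sic",)), "viable"),
        ]
        summary, calls = benchmark(minicdc_network, minicdc.system, rows, minicdc.cgm)
        assert len(summary.errors) == 1 and "bogus" in summary.errors[0]
        assert summary.n_correct == 1


def _minicdc_rows():
    L, V = "lethal", "viable"
    mk = MutantSpec
    return [
        BenchmarkRow(mk("sbf", deletions=("SBF",)), L, "G1"),
        BenchmarkRow(mk("cdk", deletions=("Cdk",)), L, "G1"),
        BenchmarkRow(mk("cln", deletions=("Cln",)), L, "G1"),
        BenchmarkRow(mk("mcm1", deletions=("Mcm1",)), L, "G2/M"),
        BenchmarkRow(mk("clb", deletions=("Clb",)), L, "G2/M"),
        BenchmarkRow(mk("swi5", deletions=("Swi5",)), L, "M"),
        BenchmarkRow(mk("sicA", locks=(("Sic_[t]-P", False),)), L, "G1"),
        BenchmarkRow(mk("sic", deletions=("Sic",)), V),
        BenchmarkRow(mk("ygp1", deletions=("Ygp1",)), V),
        BenchmarkRow(mk("sicE", locks=(("Sic_[t]-P", True),)), V),
        BenchmarkRow(mk("clb-oe", overexpressions=("Clb",)), V),
        BenchmarkRow(mk("wt"), V),
    ]


class TestMutantTableIO:
    def test_roundtrip_of_tsv_table(self, tmp_path):
        path = tmp_path / "mutants.tsv"
        path.write_text(
            "label\tdeletions\tlocks\toverexpress\texpected_viability\texpected_stage\n"
            "sbf\tSBF\t\t\tlethal\tG1\n"
            "sicA\t\tSic_[t]-P=0\t\tlethal\tG1\n"
            "clb-oe\t\t\tClb\tviable\t\n"
            "double\tSBF;Mcm1\t\t\tlethal\t\n"
        )
        rows = read_mutant_table(path)
        assert [r.spec.label for r in rows] == ["sbf", "sicA", "clb-oe", "double"]
        assert rows[0].spec.deletions == ("SBF",)
        assert rows[1].spec.locks == (("Sic_[t]-P", False),)
        assert rows[2].spec.overexpressions == ("Clb",)
        assert rows[3].spec.deletions == ("SBF", "Mcm1")
        assert rows[0].expected_stage == "G1"
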