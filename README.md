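# rxncycle

Reaction–contingency knowledge bases, parameter-free bipartite Boolean
models, and genotype-to-phenotype prediction for cell-division-cycle
control networks.

## The problem

Signalling networks encode information in site-specific state changes:
bonds between specific protein domains and covalent modifications of
specific residues. Writing a genome-scale mechanistic model of such a
network in terms of fully specified molecular configurations (microstates)
is hopeless — the configuration space explodes combinatorially and the
empirical literature never determines it. The reaction–contingency
formalism avoids this by working at the resolution of the data itself:

* **elemental states** — empirical observables such as `Cdc28_[cyclin]--Cln1_[cdc28]`
  (a bond between two named domains), `Cdc28_[T169]-P` (a phosphorylation at
  a named residue), and their neutral complements (`...--0`, `...-0`);
* **elemental reactions** — indivisible reaction events defined purely by the
  elemental states they produce, consume, synthesise or degrade;
* **contingencies** — constraints stating which states, inputs or Boolean
  combinations thereof must be true (`!`) or false (`x`) — or quantitatively
  favour (`k+`) / disfavour (`k-`) — a reaction.

Such a knowledge base compiles *uniquely* and *without parameters* into a
bipartite Boolean model (bBM): one node per reaction and one per state
(neutrals included), plus gate and input/output nodes. Reaction nodes fire
when their reactants are present and their contingencies hold; state nodes
follow

```
S(t+1) = Production(t)  OR  ( S(t) AND NOT Consumption(t) )
```

where production requires a producing reaction together with its source
states, and consumption a consuming reaction or an active degradation.
The semantics are population-level: mutually exclusive states may be
simultaneously true ("present somewhere in the population"). Timescale
separation is expressed by delay chains — transcription and
replication-progression reactions must see their firing condition hold for
20 consecutive steps — so slow processes are slower than signalling.

Synchronous simulation then yields attractors: a point attractor is an
arrest state, a cyclic attractor a sustained division cycle. A
coarse-grained layer of macro states (DNA: licensed → replicating →
replicated → segregated; spindle pole body: satellite → duplicated →
separated; bud: none → small → large → divided) is read out to classify
each attractor into viability, partial (multinucleate) cycling, or a
G1/S/G2-M/M/T arrest stage. Mutants are clamps: deletions force all states
of a component (and its gene/mRNA) false, residue locks pin a modification
state and its neutral complement, overexpression pins a transcription
reaction true.

## What is in the package

| module | contents |
| --- | --- |
| `rxncycle.core` | domain types, the canonical state grammar, the data-driven reaction-type catalogue, skeleton-state generation, mutual-exclusion groups |
| `rxncycle.io` | SBtab-compatible spreadsheets (`.xlsx`, plain-text TSV, `.xls` via optional xlrd), round-trip-safe |
| `rxncycle.validate` | turnover/synthesis/effector/gate-cycle consistency report |
| `rxncycle.compile` | the bBM compiler: update-rule builders, delay chains, default initial vector, JSON and `targets, factors` export |
| `rxncycle.simulate` | synchronous stepping, clamping, exact attractor detection, readout tables |
| `rxncycle.phenotype` | mutant clamps, attractor classification, benchmark scoring |
| `rxncycle.graph` | bipartite regulatory graph, GraphML/XGMML export |
| `rxncycle.synthetic` | seeded random system generator and the frozen miniCDC fixture |

The **miniCDC** fixture is a hand-auditable ~18-component cell-cycle model
with the same architecture as the genome-scale system it emulates: three
regulatory modules (G1/S, G2/M, M/G1) gating three coupled macro cycles,
inputs for nutrients, pheromone and chemical arrest agents, slow
transcription/replication, and full turnover. Its serialised form is frozen
under version control (`src/rxncycle/data/minicdc.tsv`).

## Worked example

```python
import rxncycle as rc

fx = rc.build_minicdc()
net = rc.compile_network(fx.system, fx.default_delays())
print(net.census())
# {'state': 26, 'reaction': 30, 'gate': 1, 'global': 17, 'delay': 80, 'total': 154}

g0 = rc.g0_attractor(net)              # default vector, all inputs off
print(g0.kind, g0.period)              # point 1  -> quiescent arrest
wt = rc.find_attractor(net, g0.states[0], {"[Nutrients]": True})
print(wt.kind, wt.period, wt.transient)
# cycle 80 35  -> ordered progression through all three macro cycles
print(rc.classify_attractor(wt, fx.cgm).viability)   # viable

call, _ = rc.run_mutant(net, fx.system,
                        rc.MutantSpec("sbf", deletions=("SBF",)),
                        fx.cgm, g0.states[0])
print(call.viability, call.stage, call.profile)
# lethal G1 ('licensed', 'satellite', 'none')
```

The numbers mean: the compiled miniCDC network has 154 Boolean nodes (80 of
them delay nodes from the four slow reactions); without nutrients it settles
into a point attractor with licensed DNA, a satellite-bearing spindle pole
body and no bud; adding nutrients releases a period-80 cycle reached after a
35-step transient; deleting the G1 transcription driver arrests the cycle at
the G1 profile.

The same is available from the shell:

```bash
rxncycle fixture minicdc -o minicdc.tsv
rxncycle validate minicdc.tsv
rxncycle stats minicdc.tsv
rxncycle compile minicdc.tsv -o net.json --bnet net.bnet
rxncycle simulate net.json --clamp '[Nutrients]=1' --nodes '[DNAlic],[DNArep]' -o traj.tsv
rxncycle graph minicdc.tsv --simplified -f graphml -o reg.graphml
```

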