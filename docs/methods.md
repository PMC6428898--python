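# Methods

## Model and assumptions

The package operates on reaction–contingency systems: components carrying
named domain and residue loci; elemental states (bonds, modifications,
their neutral complements, degenerate component-presence states for
components without loci, and bracketed globals); elemental reactions typed
by a data-driven catalogue; and contingencies (`!`, `x`, `k+`, `k-`, plus
AND/OR/NOT gate-membership rows). All elemental states at one locus are
mutually exclusive *in any single molecule*, but the compiled Boolean model
is population-level: a state node means "present in the population", so
exclusive states may be simultaneously true and no exclusivity is enforced
at runtime. This is a deliberate design choice — enforcing microstate
exclusivity would contradict the one-to-many relation between elemental
states and microstates and would destroy sustained cycling.

### Skeleton rules

A reaction's state sets follow deterministically from its type and its two
component specifications. Bond formation produces the bond and consumes the
two unbound neutrals; dissociation is the reverse; modification addition
produces the modified state and consumes the unmodified neutral per
modification kind; transcription synthesises the target's mRNA (gene and
mRNA components are derived by the `Xgene`/`XmRNA` naming convention);
translation synthesises the protein's neutral states; synthesis likewise;
degradation degrades *every* state of the target; macro-cycle transitions
produce the destination and consume the source macro state. Degradation and
synthesis sets necessarily depend on the system's full state universe, so
they are expanded at system finalisation; given the system they are fully
deterministic, which is what the skeleton-determinism property tests check.

### Update rules

* Reaction node: `presence(A) AND presence(B) AND requirements AND NOT
  inhibitions AND gates`. Presence of a component is the OR of its state
  nodes (stateless components contribute a single presence node; the global
  pseudo-components of macro transitions contribute a constant true).
  Source states are *not* conjoined here — a reaction node reads as
  "catalytic opportunity"; source gating lives in the state rules, matching
  the separate source-state edges of the regulatory graph. `k+`/`k-`
  contingencies compile to no-ops: they mark quantitative, non-blocking
  influence and have no truth-functional content in the Boolean regime.
* State node: `production OR (self AND NOT consumption)`; production terms
  are `reaction AND its sources` (synthesis unguarded), consumption terms
  `reaction AND its other sources` or any active degradation covering the
  state. Degrading a bound component additionally re-produces the partner's
  unbound neutral, gated on the bond — otherwise partners would be
  permanently sequestered and cyclic behaviour impossible.
* Gates are materialised as their own nodes with synchronous update (one
  step of propagation latency), not inlined, mirroring the gate nodes of
  the regulatory graph and keeping the node census interpretable.
* Globals: macro states follow state-rule semantics (their producers are
  the macro transitions); outputs defined by contingency rows conjoin their
  requirements; pure inputs hold their value and are meant to be clamped.

### Delays (timescale separation)

A delay of length `k` on a reaction replaces its rule by a chain
`d1 = rule`, `d(i+1) = d(i) AND rule`, `reaction = d(k) AND rule`. The
reaction therefore fires at `t` exactly when the undelayed rule held at the
`k+1` preceding steps, and the chain resets whenever the rule goes false.
The default assigns `k = 20` to every transcription reaction and to
macro-cycle reactions tagged `replication` (the tag column makes the set
overridable in the model file). The chain gates on the reaction's full rule
(presence factors included) rather than on the contingency part alone; the
two differ only when a reactant disappears mid-window, where resetting the
clock is the conservative choice.

### Initial vector and simulation

The default start state has every neutral state true, every non-neutral
state, reaction, gate and delay node false, and globals false except
declared overrides (`[Histones]` defaults to true wherever it exists; the
miniCDC additionally seeds `[DNAlic]`, `[SPBsat]`, `[BUD0]` — quiescent
cells hold licensed origins, a satellite SPB and no bud). Updates are
synchronous and deterministic; clamps override rules at every step
including step 0. Attractor detection hashes full state vectors with a
first-seen-time dictionary: the first recurrence closes the trajectory, the
segment between the two visits is the attractor, and its period is minimal
by construction (every state in the segment was visited exactly once).
Exceeding the step budget raises an explicit error rather than truncating.

### Phenotype classification

Mutants are clamp sets (deletion: all states of the component and of its
gene/mRNA false; residue lock: the modification state pinned and its
neutral complement pinned to the negation; overexpression: the
transcription reaction pinned true) released from the wild-type quiescent
attractor with nutrients on. A cyclic attractor in which all three macro
cycles traverse — every stage true at least once per period, first
activations in stage order, anchored at the first stage's rise — is viable.
A cycle in which DNA and SPB/nuclear-division traverse but the bud cycle
never completes is a partial, multinucleate cycle (unbounded DNA/nuclei
counts). Point attractors, and cycles whose macro-state readout is constant
(a bind/release micro-oscillation can persist in the reaction layer while
the physiology is frozen), are arrests classified by an ordered decision
table over the active stage roles: replicating → S; segregated+separated →
M; replicated → G2/M; licensed → G1; no DNA stage with satellite SPB → G1;
no DNA and no SPB stage with a bud → T (2 DNA, 2 nuclei). Profiles the
table does not cover fall back to stage `NA` with a warning instead of
failing; the table is data and can be replaced from YAML.

## The miniCDC fixture

The fixture emulates the architecture of the genome-scale cell-cycle
system at a hand-auditable size: a G1/S module (nutrient-dependent,
pheromone-inhibited transcription of the G1 cyclin; the cyclin–CDK dimer
drives DNA licensing→replication, SPB satellite→duplication, bud
emergence, and removes the CDK inhibitor via phosphorylation-triggered
degradation), a G2/M module (the B-type cyclin is transcribed only once
replication has finished — the replication checkpoint collapsed into a
single macro-state requirement — and drives segregation, SPB separation and
bud growth), and an M/G1 exit module (the exit driver is transcribed only
when segregation AND separation are complete, and resets all three macro
cycles). Replication progression and all three transcription reactions are
slow (k = 20); every synthesised component and every modification is turned
over, so validation returns an empty report. Two bystander proteins with a
private bond provide a deletion that provably cannot affect the cycle.

What the fixture does *not* emulate: the genome-scale model's size (it has
30 reactions, not 802), redundant cyclins and parallel pathways (single
mutants here are decisive where the real network buffers them), the
Mec1/Rad53 checkpoint signalling chain (HU acts directly on the
replication transition), spatial phenomena, and the published 186-step
period — period and transient (80 and 35 under the default protocol) are
properties of this wiring, recorded once from simulation and asserted as
regression values thereafter. Passing the behavioural contract therefore
shows that the pipeline's semantics support the qualitative phenomenology
(quiescence, ordered triple-cycle progression, stage-specific arrests,
sensible mutant calls), not that any genome-scale count is reproduced.

The random-system generator exists for property testing: it builds a
synthesis/degradation scaffold per component, decorates it with
bond/modification reactions (duplicate reaction ids are skipped), and
samples contingencies only among producible states, so generated systems
always compile and simulate. Its defaults (10 components, 15 decorations,
one expected contingency per reaction, 15 % gate probability) produce
systems in the size regime where exhaustive-trajectory oracles are cheap.

## Numerical and I/O choices

* Canonical state grammar with lexicographically ordered bond partners, so
  `A_[x]--B_[y]` and `B_[y]--A_[x]` are one identity.
* Compilation is deterministic: canonical node order (states, reactions,
  gates, globals, delays — each in system order), stable JSON
  serialisation, SHA-256 hash equality across runs.
* Spreadsheet tables are discovered by their SBtab header line, never by
  sheet name; unknown columns ride along and survive round-trips; the
  column map is configurable for files that name headers differently.
  Legacy `.xls` reading delegates to the optional `xlrd` package.
* The `targets, factors` export mangles node ids to bare identifiers
  (non-alphanumerics to `_`), a stable mapping for plain-text
  Boolean-network tooling.
* Attractor search uses exact hashing; the default budget (10^5 steps) far
  exceeds any trajectory the bundled systems produce, and the budget-
  exceeded outcome is an explicit error/phenotype, never a silent result.

## Known limitations

* Population-level semantics admit two-step bind/release oscillations
  (e.g. a site alternately bound and freed under simultaneous degradation
  and rebinding). The classifier treats attractors whose macro readout is
  constant as arrests for exactly this reason.
* Boolean gate structure annotations (`@n` molecule-instance markers for
  structured complexes) are preserved through parsing and round-trip but
  carry no additional runtime semantics.
* Effector locality (a contingency's state belonging to the reaction's own
  reactants or their complex) is not enforced: the input/output coupling
  between the mechanistic layer and the macro layer legitimately crosses
  that boundary in both directions.
* No asynchronous or probabilistic updating, no exhaustive attractor
  enumeration over initial states, and no export to rule-based or
  quantitative formalisms.
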