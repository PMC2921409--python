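# Methods

## Model class and assumptions

`rulekmc` simulates well-mixed, isothermal systems of molecules built
from components (binding sites, modifiable residues). A component has at
most one bond partner at a time and optionally an internal state drawn
from a declared finite set. Chemical species are connected site graphs;
one tracked copy of a species is a *species instance*. Rules rewrite
exactly one thing per event — one component state, one bond deleted, or
one bond created — so molecule and component counts are conserved.
Synthesis, degradation and compartment trafficking rules are out of
scope, as are rate laws other than mass action.

Rate constants are single-site constants in units of 1/time; for
bimolecular rules the volume is folded into the constant
(k_V = k/(N_A·V)), so no explicit volume appears in the simulator.

## Dialect

The parser accepts `parameters` (arithmetic with `+ - * /` and
parentheses), `molecule types` (optional; inferred from the seed block
if absent), `species`, `reaction rules`, `observables`, and a
`simulate_rm`/`simulate` action (`t_end`, `n_steps`/`n_report`, `seed`;
other action commands are ignored with a warning). Pattern syntax covers
internal states `~s`, explicit bonds `!n`, bound-to-anything `!+`,
unspecified-bond `!?`, concatenation `.` and reactant separation `+`,
with both `->` and `<->` (the latter expanded into two unidirectional
rules, forward before reverse). An omitted component is a full wildcard;
an explicitly listed component without `!` must be unbound. Seed species
must be fully specified (all components, explicit states, no wildcards).

## Rule classes and rates

Every rule is classified from its shape:

| class | shape | rate |
|---|---|---|
| state change | one pattern each side, one state edit | k·Σ_s v(l,s) |
| dissociation | one LHS pattern, one bond deleted, 1 or 2 RHS patterns | k·Σ_s v(l,s), v counting bonded center pairs whose deletion yields the demanded product count |
| association | two `+`-separated LHS patterns, one bond created | f·k·(V1·V2 − Σ_s v1(s)·v2(s)) |
| ring closure (monogamous) | one LHS pattern, new bond within one pattern molecule | k·Σ_s (distinct center pairs inside one molecule) |
| ring closure (non-monogamous) | one LHS pattern, new bond across molecules of one species | k·Σ_s (distinct center pairs across molecules) |

`v(l,s)` counts *distinct reaction-center images*, not matches: a
contextual constraint satisfiable several ways around one center
contributes one instance. The matcher itself returns all injections
(symmetric embeddings included); deduplication happens at the center
level. Consequences of this convention:

* ring classes need no explicit symmetry factor — a symmetric pattern's
  swapped embeddings collapse onto the same unordered center pair;
* associations count ordered (role-1, role-2) pairs and apply f = 1/2
  exactly when the two LHS patterns are textually identical after
  normalization, which reproduces k·n(n−1)/2 for A + A rules;
* for the contrived case of two *different* association patterns whose
  center sets overlap, ordered pairs are counted (two degenerate paths
  per site pair); the oracle mirrors this convention.

The 2-product dissociation condition is checked per bond by a
connectivity test with a tree shortcut (n molecules, n−1 bonds ⇒ every
bond is a bridge), which keeps acyclic-aggregate models linear-cost.
Whether a rule closes rings monogamously or non-monogamously is declared
by its syntax (centers in the same pattern molecule or not), never
auto-detected per instance; the RHS pattern-membership of molecules in a
2-product dissociation is not constrained beyond the product count.

## Simulation loop

Initialization instantiates every seed copy as a particle, computes all
rule rates and observable match numbers de novo — the only de-novo pass
of a run. Per event, deviates are consumed in a fixed order (τ, rule,
reactant(s), center(s)) from one seeded `numpy` generator, so a fixed
seed reproduces a trajectory bit for bit. Rule selection is a linear
scan (adequate for the rule counts considered; a log-N tree would be a
drop-in replacement). Reactant selection is proportional to per-instance
center counts; association draws the first species from the marginal of
the corrected pair distribution, then the partner from the remaining
mass — never by rejection. Events are applied by in-place graph rewrite
followed by re-partitioning the affected molecules into connected
instances (molecule identities preserved).

All center bookkeeping is integer-valued, and per-rule totals are
updated by adding/removing whole-species contributions, so incremental
rates equal de-novo recomputation exactly (the 1e-9 consistency
tolerance in the tests is slack, not a budget); no periodic refresh is
needed, and the activity raises on any negative total as a bookkeeping
guard. Observables (`Molecules` = distinct pattern images, `Species` =
instances containing at least one image) are maintained the same way.
Match numbers count *images*, not injections: a pattern with two
identical free sites contributes one image per matching molecule, which
is the standard reading of match counts in this dialect.

The reported value at a report time is the state at the last event time
at or before it (the jump process is right-continuous piecewise
constant); with r_tot = 0 the remaining grid is filled with the frozen
state.

## Oracles

The oracle module re-implements the combinatorics naively (itertools
search over all molecule/component assignments, own connectivity
checks): agreement with the engine is evidence, not shared code.
`generate_network` closes the rule set over canonical species
(refinement-based canonical labels, cross-checked in tests against
VF2 isomorphism from networkx) and raises a "network too large" error
past a species guard — the failure mode that motivates network-free
simulation. With `bound_by_copy_numbers`, product species needing more
molecules of some type than the seed block provides are dropped; under
conservation those are unreachable, so the truncated network is still
the exact master-equation network for the given seeds. This is what
makes the small multivalent-aggregation benchmark finite (23 species at
6 ligands + 4 receptors) while the same model at 50 + 30 copies — let
alone realistic sizes — cannot be closed at all. Explicit reactions
carry coefficient k × (instances between single copies); propensities
use x_i, x_i·x_j, or x_i(x_i−1)/2 for self-pairs, which matches the
rule-level rates identically. The SSA is the classic direct method;
ODE integration uses LSODA at rtol 1e-8.

## Benchmark fixtures and chosen conditions

Parameter values for the benchmark family are the package's own
documented defaults:

* **Multisite phosphorylation** — n independent two-state sites,
  k_p = k_d = 1/s, 100 substrate copies by default. First order, so the
  stochastic mean equals the ODE solution at any copy number — which is
  why the ODE leg of the dynamics comparison uses this model rather than
  scaled-up copies of the nonlinear ones.
* **TLBR** — trivalent ligand L(s,s,s), bivalent receptor R(s,s); rules:
  free-ligand capture (association), crosslinking (association,
  molecularity 2 — no ring closure rule, so aggregates stay acyclic, and
  2-product dissociation is then always applicable), dissociation.
  β = N_R·k_plus2/k_off controls equilibrium crosslinking. Defaults
  N_L = 50, N_R = 30, k_plus1 = 0.1, k_off = 0.1, β = 0.3 (sub-gel). The
  sol-gel check runs N_L = N_R = 300, k_off = 0.01/s, k_plus1 = 1e-3 and
  β ∈ {0.05, 100} to 30 s — long enough for capture equilibrium and gel
  formation at these rates while keeping the run minutes-scale. The
  dynamics-versus-SSA comparison runs TLBR at N_L = 6, N_R = 4 (β kept
  sub-gel), the size at which the copy-bounded network closes.
* **Stiff pair** — two irreversible first-order state changes with rate
  constants k and φ·k; n0 = 4000 per type keeps thousands of events
  available at any φ. The per-event-cost comparison across φ is
  wall-clock by nature (warm-up plus fixed-size batches).
* **Dimerization** — symmetric association (f = 1/2) plus 2-product
  dissociation; the minimal association benchmark.

The synthetic models emulate the combinatorial structure of signalling
systems (multisite modification, multivalent aggregation, timescale
separation) but not their kinetic heterogeneity: all reactions in a
class share one rate constant, there are no steric or geometric
application conditions, and no synthesis/degradation. Passing tests
therefore certify the simulation machinery on this model class, not the
biological accuracy of any particular parameterization.

## Statistical conventions

Monte-Carlo comparisons use means over independent seeded runs with a
3·SEM band (combined in quadrature when both sides are stochastic);
waiting times use a Kolmogorov–Smirnov test at α = 0.01 on 10⁴ samples;
frequency checks use 3–3.5 standard errors. Run counts (200–500) and
model sizes are chosen to keep the whole suite minutes-scale; all seeds
are fixed in the tests and derived from `--seed` in the acceptance
script.

## Known limitations

* Canonical labeling enumerates permutations within refinement classes;
  highly symmetric species of many dozens of molecules would be
  expensive (irrelevant at oracle scale, guarded by an explicit limit).
* Rule selection and association reactant selection are linear scans —
  per-event cost grows with the number of rules and populated instances.
* One graph edit per rule; no synthesis/degradation/compartments; no
  energy-based or steric application conditions.
* The dialect is a subset: no functions, compartments, local functions
  or fixed species.
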