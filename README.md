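# rulekmc

Network-free, rejection-free kinetic Monte Carlo simulation of rule-based
models of protein–protein interaction systems, written in a subset of the
BioNetGen language (BNGL).

## The problem

A rule set `R = {R_1, …, R_N}` over site graphs — molecules with named
components, internal states and at-most-one-bond sites — implicitly
defines a chemical reaction network. For systems with multivalent
binding or multisite modification that network is combinatorially large
(a substrate with 10 modifiable sites implies 2^10 species), so both
network generation and conventional simulation become impossible.
`rulekmc` simulates such models *directly from the rules*: every
molecule is tracked as a particle, and the cost per reaction event is
independent of the size of the implied network.

## The method

The state is the complete component state Σ_c(t): every component's
internal state and bond partner. Each rule `R_i` (mass action, single-site
rate constant `k_i`) carries a cumulative rate

    r_i(t) = k_i × (number of distinct reaction instances in Σ_c(t)),

computed per rule class — state change, dissociation (with a 1- or
2-product application condition), bimolecular association (molecularity 2,
with the over-counting correction that excludes center pairs inside one
species instance, and a statistical factor 1/2 for symmetric A + A rules),
and monogamous / non-monogamous ring closure (intramolecular bond
formation within one molecule / between molecules of one species).

Each step is a real reaction event (rejection-free):

1. waiting time τ = ln(1/ρ₁)/r_tot, with r_tot = Σ r_i,
2. rule `R_I` chosen by linear scan with probability r_I/r_tot,
3. reactant instance(s) chosen in proportion to their distinct
   reaction-center counts (association samples the corrected
   distinct-instance pair distribution directly — no reject-and-redraw),
4. the graph rewrite is applied and all r_i and observable match numbers
   are updated incrementally; nothing is recomputed from scratch after
   initialization.

An in-package generate-first oracle — exhaustive network closure,
Gillespie direct SSA, and mass-action ODE integration — plus a
brute-force rate enumerator validate the simulator on small models.

## Worked example

```python
import rulekmc as rk

model = rk.make_dimerization(k_plus=0.1, k_minus=1.0, n0=20)
state, activity, _ = rk.initialize(model)
print(activity.rates())          # [19.  0.]  = 0.1 * 20*19/2, and no dimers yet

traj = rk.run(model, rk.SimulationConfig(t_end=2.0, seed=1, n_report=5))
print(traj.names)                # ['FreeA', 'Dimer']
print(traj.values)
```

Output of the run above:

```
[[20.  0.]
 [14.  3.]
 [10.  5.]
 [10.  5.]
 [ 8.  6.]
 [12.  4.]]
```

Twenty monomers associate under the symmetric rule `A(a) + A(a) ->
A(a!1).A(a!1)` at the exact initial cumulative rate k·n(n−1)/2 = 19 s⁻¹
and relax toward the dimerization equilibrium; each row is the observable
vector (free monomers, dimer species count) at one report time.

The same model can be simulated from the shell:

```sh
rulekmc simulate model.bngl --seed 1 --out run    # writes run.gdat, run.info
```

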