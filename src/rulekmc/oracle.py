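"""Generate-first validation oracle.

For small models the reaction network implied by a rule set is derived
exhaustively (fixed-point closure over canonical species), then simulated
by the classic Gillespie direct method and by mass-action ODE
integration.  A brute-force per-rule rate enumerator pins the rule-engine
rate contracts.

The combinatorics here are deliberately a *separate implementation*: the
pattern matcher is a naive itertools search sharing no code with the
engine's backtracking matcher or any ``rate_*`` path, so agreement
between the two routes is evidence, not tautology.

Propensity convention: each explicit reaction stores ``coeff`` = rule
rate constant x (number of distinct reaction instances between single
copies of its reactant species).  The propensity is ``coeff * x_i`` for
one reactant, ``coeff * x_i * x_j`` for two distinct reactant species and
``coeff * x_i * (x_i - 1) / 2`` for a self-pair, which reproduces the
rule-level cumulative rates exactly.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .graphs import (
    BOUND_ANY,
    UNBOUND,
    Molecule,
    PatternGraph,
    SpeciesInstance,
    canonical_label,
    instantiate_pattern,
    render_pattern,
)
from .engine import Rule, RuleClass
from .simulate import ObservableDef, Trajectory, species_observable_value


class NetworkTooLargeError(RuntimeError):
    """Closure exceeded the species guard: the network cannot be generated
    exhaustively at this size (the regime network-free simulation exists for)."""


# ---------------------------------------------------------------------------
# naive matcher (independent of graphs.find_matches)
# ---------------------------------------------------------------------------

def _naive_matches(pattern: PatternGraph, molecules: Sequence[Molecule]):
    """All injections of ``pattern`` into a molecule set, by exhaustive
    itertools search.  Returns comp maps {(mi, ci): (Molecule, comp_idx)}."""
    pmols = pattern.molecules
    out = []
    for mol_choice in itertools.permutations(molecules, len(pmols)):
        if any(m.mtype.name != pm.name for m, pm in zip(mol_choice, pmols)):
            continue
        per_mol: list[list[tuple[int, ...]]] = []
        feasible = True
        for pm, mol in zip(pmols, mol_choice):
            opts = []
            for assign in itertools.permutations(range(len(mol.mtype.components)),
                                                 len(pm.components)):
                ok = True
                for pc, ci in zip(pm.components, assign):
                    cd = mol.mtype.components[ci]
                    bond = mol.bonds[ci]
                    if (cd.name != pc.name
                            or (pc.state is not None and mol.states[ci] != pc.state)
                            or (pc.bond is UNBOUND and bond is not None)
                            or ((pc.bond is BOUND_ANY or isinstance(pc.bond, int))
                                and bond is None)):
                        ok = False
                        break
                if ok:
                    opts.append(assign)
            if not opts:
                feasible = False
                break
            per_mol.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*per_mol):
            comp_map = {}
            for mi, (pm, assign) in enumerate(zip(pmols, combo)):
                for ci, target in enumerate(assign):
                    comp_map[(mi, ci)] = (mol_choice[mi], target)
            ok = True
            for e1, e2 in pattern.bond_pairs.values():
                a, ai = comp_map[e1]
                b, bi = comp_map[e2]
                bond = a.bonds[ai]
                if bond is None or bond[0] is not b or bond[1] != bi:
                    ok = False
                    break
            if ok:
                out.append(comp_map)
    return out


def _partition(molecules: Sequence[Molecule]) -> list[list[Molecule]]:
    remaining = {id(m): m for m in molecules}
    parts = []
    while remaining:
        seed = next(iter(remaining.values()))
        del remaining[id(seed)]
        comp = [seed]
        queue = deque([seed])
        while queue:
            cur = queue.popleft()
            for b in cur.bonds:
                if b is not None and id(b[0]) in remaining:
                    m = remaining.pop(id(b[0]))
                    comp.append(m)
                    queue.append(m)
        parts.append(comp)
    return parts


def _disconnects(molecules: Sequence[Molecule], a: Molecule, ai: int,
                 b: Molecule, bi: int) -> bool:
    """Would deleting the bond (a.ai - b.bi) leave a and b disconnected?"""
    seen = {id(a)}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        for ci, bond in enumerate(cur.bonds):
            if bond is None or (cur is a and ci == ai) or (cur is b and ci == bi):
                continue
            if bond[0] is b:
                return False
            if id(bond[0]) not in seen:
                seen.add(id(bond[0]))
                queue.append(bond[0])
    return True


def _mc(ref) -> tuple[int, int]:
    return (ref[1], ref[2])


def _center_comps(pattern: PatternGraph, center: tuple[int, int],
                  molecules: Sequence[Molecule]):
    """Distinct images of one center component, deduplicated."""
    seen = {}
    for m in _naive_matches(pattern, molecules):
        mol, ci = m[center]
        seen[(mol.uid, ci)] = (mol, ci)
    return list(seen.values())


def _pair_images(pattern: PatternGraph, c1: tuple[int, int], c2: tuple[int, int],
                 molecules: Sequence[Molecule]):
    """Distinct unordered images of a center pair, deduplicated."""
    seen = {}
    for m in _naive_matches(pattern, molecules):
        a, b = m[c1], m[c2]
        key = frozenset([(a[0].uid, a[1]), (b[0].uid, b[1])])
        seen[key] = (a, b)
    return list(seen.values())


def brute_force_rule_rate(rule: Rule, state) -> float:
    """k x (number of distinct reaction instances of ``rule`` in ``state``),
    by direct combinatorial enumeration."""
    k = rule.k
    if rule.rule_class is RuleClass.STATE_CHANGE:
        n = sum(len(_center_comps(rule.lhs[0], _mc(rule.centers[0]), sp.molecules))
                for sp in state.instances.values())
        return k * n
    if rule.rule_class is RuleClass.DISSOCIATION:
        n = 0
        for sp in state.instances.values():
            for (a, ai), (b, bi) in _pair_images(rule.lhs[0], _mc(rule.centers[0]),
                                                 _mc(rule.centers[1]), sp.molecules):
                products = 2 if _disconnects(sp.molecules, a, ai, b, bi) else 1
                if products == rule.n_products_required:
                    n += 1
        return k * n
    if rule.rule_class in (RuleClass.RING_MONO, RuleClass.RING_NONMONO):
        n = sum(len(_pair_images(rule.lhs[0], _mc(rule.centers[0]),
                                 _mc(rule.centers[1]), sp.molecules))
                for sp in state.instances.values())
        return k * n
    # association: pairs of centers from two distinct species instances
    centers1 = []
    centers2 = []
    for sp in state.instances.values():
        for mol, ci in _center_comps(rule.lhs[0], _mc(rule.centers[0]), sp.molecules):
            centers1.append((sp.uid, mol.uid, ci))
        for mol, ci in _center_comps(rule.lhs[1], _mc(rule.centers[1]), sp.molecules):
            centers2.append((sp.uid, mol.uid, ci))
    if rule.symmetry_factor == 0.5:
        events = {frozenset([c1, c2]) for c1 in centers1 for c2 in centers2
                  if c1[0] != c2[0]}
        n = len(events)
    else:
        n = sum(1 for c1 in centers1 for c2 in centers2 if c1[0] != c2[0])
    return k * n


# ---------------------------------------------------------------------------
# exhaustive network generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    reactants: tuple[int, ...]       # 1 or 2 species indices (pair sorted)
    products: tuple[int, ...]
    coeff: float                     # k x instances between single copies
    rule_name: str


@dataclass
class ReactionNetwork:
    labels: list[str]
    representatives: list[SpeciesInstance]
    reactions: list[Reaction]
    type_counts: list[dict[str, int]] = field(default_factory=list)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def dump(self) -> str:
        lines = []
        for r in self.reactions:
            lhs = " + ".join(self.labels[i] for i in r.reactants)
            rhs = " + ".join(self.labels[i] for i in r.products)
            lines.append(f"{lhs} -> {rhs} {r.coeff!r}  # {r.rule_name}")
        return "\n".join(lines)

    def observable_matrix(self, observables: Sequence[ObservableDef]) -> np.ndarray:
        mat = np.zeros((len(self.representatives), len(observables)))
        for si, rep in enumerate(self.representatives):
            for oi, obs in enumerate(observables):
                mat[si, oi] = species_observable_value(obs, rep)
        return mat


def _copy(mols: Sequence[Molecule], uids) -> list[Molecule]:
    clones = {id(m): Molecule(m.mtype, next(uids), states=list(m.states))
              for m in mols}
    for m in mols:
        for ci, b in enumerate(m.bonds):
            if b is not None:
                clones[id(m)].bonds[ci] = (clones[id(b[0])], b[1])
    return [clones[id(m)] for m in mols]


def generate_network(model, max_species: int = 100,
                     bound_by_copy_numbers: bool = False) -> ReactionNetwork:
    """Fixed-point closure: apply every rule to every discovered species
    (and species pair), canonicalize products, iterate until no new
    species appear or ``max_species`` is exceeded.

    With ``bound_by_copy_numbers`` products needing more molecules of some
    type than the seed block provides are dropped; under conservation such
    species are unreachable, so the truncated network is still the exact
    master-equation network for the given seeds (this is what makes, e.g.,
    small multivalent-aggregation networks finite).
    """
    uids = itertools.count()
    types = {mt.name: mt for mt in model.molecule_types}
    budget: Optional[dict[str, int]] = None
    if bound_by_copy_numbers:
        budget = {}
        for pattern, count in model.seed_species:
            for pm in pattern.molecules:
                budget[pm.name] = budget.get(pm.name, 0) + count

    labels: list[str] = []
    reps: list[SpeciesInstance] = []
    tcounts: list[dict[str, int]] = []
    index: dict[str, int] = {}
    queue: deque[int] = deque()
    reactions: list[Reaction] = []

    def type_count(mols: Sequence[Molecule]) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in mols:
            out[m.mtype.name] = out.get(m.mtype.name, 0) + 1
        return out

    def register(mols: list[Molecule]) -> Optional[int]:
        tc = type_count(mols)
        if budget is not None and any(tc[t] > budget.get(t, 0) for t in tc):
            return None
        sp = SpeciesInstance(mols, next(uids))
        label = canonical_label(sp)
        if label in index:
            return index[label]
        if len(labels) >= max_species:
            raise NetworkTooLargeError(
                f"network too large: more than {max_species} species implied by the rules")
        index[label] = len(labels)
        labels.append(label)
        reps.append(sp)
        tcounts.append(tc)
        queue.append(index[label])
        return index[label]

    for pattern, _count in model.seed_species:
        mols = instantiate_pattern(pattern, types, uids)
        for part in _partition(mols):
            if len(part) != len(mols):
                raise ValueError("seed species expression is not connected")
        register(mols)

    uni_rules = [r for r in model.rules if r.rule_class is not RuleClass.ASSOCIATION]
    assoc_rules = [r for r in model.rules if r.rule_class is RuleClass.ASSOCIATION]

    def add_grouped(reactants: tuple[int, ...], rule: Rule,
                    product_events: list[tuple[tuple[int, ...], int]]) -> None:
        grouped: dict[tuple[int, ...], int] = {}
        for products, n in product_events:
            grouped[products] = grouped.get(products, 0) + n
        for products, n in grouped.items():
            reactions.append(Reaction(reactants=reactants, products=products,
                                      coeff=rule.k * n, rule_name=rule.name))

    def apply_uni(rule: Rule, si: int) -> None:
        rep = reps[si]
        events: list[tuple[tuple[int, ...], int]] = []
        if rule.rule_class is RuleClass.STATE_CHANGE:
            instances = [ (c,) for c in _center_comps(rule.lhs[0], _mc(rule.centers[0]),
                                                      rep.molecules)]
        else:
            instances = _pair_images(rule.lhs[0], _mc(rule.centers[0]),
                                     _mc(rule.centers[1]), rep.molecules)
            if rule.rule_class is RuleClass.DISSOCIATION:
                want = rule.n_products_required == 2
                instances = [p for p in instances
                             if _disconnects(rep.molecules, p[0][0], p[0][1],
                                             p[1][0], p[1][1]) == want]
        for inst in instances:
            mols = _copy(rep.molecules, uids)
            pos = {m.uid: i for i, m in enumerate(rep.molecules)}
            if rule.rule_class is RuleClass.STATE_CHANGE:
                mol, ci = inst[0]
                mols[pos[mol.uid]].states[ci] = rule.new_state
            elif rule.rule_class is RuleClass.DISSOCIATION:
                (a, ai), (b, bi) = inst
                mols[pos[a.uid]].bonds[ai] = None
                mols[pos[b.uid]].bonds[bi] = None
            else:
                (a, ai), (b, bi) = inst
                ca, cb = mols[pos[a.uid]], mols[pos[b.uid]]
                ca.bonds[ai] = (cb, bi)
                cb.bonds[bi] = (ca, ai)
            prods = []
            for part in _partition(mols):
                pi = register(part)
                if pi is None:
                    prods = None
                    break
                prods.append(pi)
            if prods is not None:
                events.append((tuple(sorted(prods)), 1))
        add_grouped((si,), rule, events)

    def apply_pair(rule: Rule, si: int, sj: int) -> None:
        copy_a = _copy(reps[si].molecules, uids)
        copy_b = _copy(reps[sj].molecules, uids)
        c1a = _center_comps(rule.lhs[0], _mc(rule.centers[0]), copy_a)
        c2a = _center_comps(rule.lhs[1], _mc(rule.centers[1]), copy_a)
        c1b = _center_comps(rule.lhs[0], _mc(rule.centers[0]), copy_b)
        c2b = _center_comps(rule.lhs[1], _mc(rule.centers[1]), copy_b)
        raw = [(c1, c2) for c1 in c1a for c2 in c2b]
        raw += [(c1, c2) for c1 in c1b for c2 in c2a]
        if rule.symmetry_factor == 0.5:
            dedup = {}
            for c1, c2 in raw:
                key = frozenset([(c1[0].uid, c1[1]), (c2[0].uid, c2[1])])
                dedup[key] = (c1, c2)
            raw = list(dedup.values())
        pool = copy_a + copy_b
        pos = {m.uid: i for i, m in enumerate(pool)}
        events = []
        for (a, ai), (b, bi) in raw:
            mols = _copy(pool, uids)
            ca, cb = mols[pos[a.uid]], mols[pos[b.uid]]
            ca.bonds[ai] = (cb, bi)
            cb.bonds[bi] = (ca, ai)
            parts = _partition(mols)
            assert len(parts) == 1
            pi = register(parts[0])
            if pi is not None:
                events.append(((pi,), 1))
        add_grouped(tuple(sorted((si, sj))), rule, events)

    while queue:
        si = queue.popleft()
        for rule in uni_rules:
            apply_uni(rule, si)
        for rule in assoc_rules:
            for sj in range(si + 1):
                apply_pair(rule, si, sj)
    return ReactionNetwork(labels=labels, representatives=reps,
                           reactions=reactions, type_counts=tcounts)


def initial_counts(network: ReactionNetwork, model) -> np.ndarray:
    """Map the model's seed block onto the network's species axis."""
    uids = itertools.count()
    types = {mt.name: mt for mt in model.molecule_types}
    x = np.zeros(len(network.labels))
    for pattern, count in model.seed_species:
        label = canonical_label(
            SpeciesInstance(instantiate_pattern(pattern, types, uids), 0))
        x[network.index(label)] += count
    return x


# ---------------------------------------------------------------------------
# population-based simulation of the explicit network
# ---------------------------------------------------------------------------

def _reaction_arrays(network: ReactionNetwork):
    n_sp = len(network.labels)
    rows = []
    for r in network.reactions:
        stoich = np.zeros(n_sp)
        for i in r.reactants:
            stoich[i] -= 1
        for i in r.products:
            stoich[i] += 1
        rows.append(stoich)
    stoich = np.array(rows) if rows else np.zeros((0, n_sp))
    return stoich


def _propensities(network: ReactionNetwork, x: np.ndarray,
                  continuum: bool = False) -> np.ndarray:
    out = np.zeros(len(network.reactions))
    for ri, r in enumerate(network.reactions):
        if len(r.reactants) == 1:
            out[ri] = r.coeff * x[r.reactants[0]]
        else:
            i, j = r.reactants
            if i == j:
                out[ri] = r.coeff * (x[i] * x[i] / 2.0 if continuum
                                     else x[i] * (x[i] - 1) / 2.0)
            else:
                out[ri] = r.coeff * x[i] * x[j]
    return out


def direct_ssa(network: ReactionNetwork, init: np.ndarray, t_end: float,
               report_times: Sequence[float], rng: np.random.Generator,
               observables: Optional[Sequence[ObservableDef]] = None) -> Trajectory:
    """Gillespie's direct method on the explicit network."""
    stoich = _reaction_arrays(network)
    x = np.asarray(init, dtype=float).copy()
    times = np.asarray(report_times, dtype=float)
    mat = (network.observable_matrix(observables) if observables is not None
           else np.eye(len(network.labels)))
    names = ([o.name for o in observables] if observables is not None
             else list(network.labels))
    rows = []
    k = 0
    t = 0.0
    events = 0
    while True:
        props = _propensities(network, x)
        a0 = props.sum()
        if a0 <= 0:
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau > t_end:
            break
        while k < len(times) and times[k] < t + tau:
            rows.append(x @ mat)
            k += 1
        ri = int(np.searchsorted(np.cumsum(props), rng.random() * a0))
        ri = min(ri, len(props) - 1)
        x += stoich[ri]
        t += tau
        events += 1
    while k < len(times):
        rows.append(x @ mat)
        k += 1
    values = np.array(rows) if rows else np.zeros((0, mat.shape[1]))
    return Trajectory(times=times, values=values, names=names, event_count=events)


def integrate_ode(network: ReactionNetwork, init: np.ndarray,
                  report_times: Sequence[float],
                  observables: Optional[Sequence[ObservableDef]] = None,
                  rtol: float = 1e-8) -> Trajectory:
    """Deterministic mass-action kinetics of the explicit network."""
    stoich = _reaction_arrays(network)
    times = np.asarray(report_times, dtype=float)

    def f(_t, x):
        return _propensities(network, x, continuum=True) @ stoich

    sol = solve_ivp(f, (0.0, float(max(times[-1], 0.0)) if len(times) else 0.0),
                    np.asarray(init, dtype=float), t_eval=times,
                    method="LSODA", rtol=rtol, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    mat = (network.observable_matrix(observables) if observables is not None
           else np.eye(len(network.labels)))
    names = ([o.name for o in observables] if observables is not None
             else list(network.labels))
    return Trajectory(times=times, values=sol.y.T @ mat, names=names)
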