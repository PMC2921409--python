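"""Rule classification, rule-rate calculation, and event application.

A rule rewrites exactly one thing: one component's internal state, one
bond deleted, or one bond created.  Five classes follow from the rule's
shape, each with its own cumulative-rate formula (all mass action with
single-site rate constants):

* ``STATE_CHANGE``   r = k * sum_s v(l, s), v = distinct center images
* ``DISSOCIATION``   r = k * sum_s v(l, s), v = distinct bonded center
  pairs whose deletion yields the number of products the RHS demands
* ``ASSOCIATION``    r = f * k * (V1*V2 - sum_s v1(s)*v2(s)); only center
  pairs from two distinct species instances count (molecularity 2), and
  f = 1/2 when the two LHS patterns are identical (A + A rules)
* ``RING_MONO``      r = k * sum_s (distinct center pairs with both
  components in one molecule)
* ``RING_NONMONO``   r = k * sum_s (distinct center pairs with the two
  components in different molecules of the same species)

For the ring classes the pattern-automorphism degeneracy of symmetric
rules is removed by deduplicating unordered center-pair images, so no
explicit symmetry factor appears.

All center bookkeeping is integer-valued, so the incrementally maintained
rates (:class:`RuleActivity`) agree with de-novo recomputation exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graphs import (
    BOUND_ANY,
    UNBOUND,
    WILDCARD,
    Molecule,
    PatternGraph,
    SpeciesInstance,
    bond_splits_species,
    break_bond,
    center_images,
    make_bond,
    render_pattern,
    split_into_species,
)


class UnsupportedRuleError(ValueError):
    """The rule's transformation is not one of the five supported classes."""


class RuleClass(enum.Enum):
    STATE_CHANGE = "state_change"
    DISSOCIATION = "dissociation"
    ASSOCIATION = "association"
    RING_MONO = "ring_mono"
    RING_NONMONO = "ring_nonmono"


# a component reference inside the LHS: (pattern index, molecule index, comp index)
CompRef = tuple[int, int, int]


@dataclass(frozen=True)
class Rule:
    name: str
    lhs: tuple[PatternGraph, ...]
    rhs: tuple[PatternGraph, ...]
    k: float
    rule_class: RuleClass
    centers: tuple[CompRef, ...]
    new_state: Optional[str] = None        # STATE_CHANGE only
    n_products_required: int = 1           # DISSOCIATION: 1 or 2
    symmetry_factor: float = 1.0           # 1/2 for symmetric associations

    def __str__(self) -> str:
        lhs = " + ".join(render_pattern(p) for p in self.lhs)
        rhs = " + ".join(render_pattern(p) for p in self.rhs)
        return f"{self.name}: {lhs} -> {rhs}  k={self.k!r}"


def _flatten(patterns: Sequence[PatternGraph]):
    out = []
    for pi, p in enumerate(patterns):
        for mi, pm in enumerate(p.molecules):
            out.append((pi, mi, pm))
    return out


def build_rule(name: str, lhs: Sequence[PatternGraph], rhs: Sequence[PatternGraph],
               k: float) -> Rule:
    """Classify a parsed unidirectional rule and derive its transformation.

    The LHS and RHS must list the same molecules (same names, same listed
    components, in the same flattened order); they may differ in exactly
    one component state or exactly one bond.
    """
    if k < 0:
        raise ValueError(f"rule '{name}': negative rate constant {k}")
    if not 1 <= len(lhs) <= 2 or not 1 <= len(rhs) <= 2:
        raise UnsupportedRuleError(f"rule '{name}': only 1 or 2 patterns per side supported")
    fl, fr = _flatten(lhs), _flatten(rhs)
    if [m.name for _, _, m in fl] != [m.name for _, _, m in fr]:
        raise UnsupportedRuleError(
            f"rule '{name}': RHS molecule sequence inconsistent with LHS")
    state_diffs: list[tuple[int, CompRef, str]] = []
    unbind_ends: list[CompRef] = []
    bind_ends: list[tuple[CompRef, int]] = []
    for j, ((lpi, lmi, lm), (rpi, rmi, rm)) in enumerate(zip(fl, fr)):
        if [c.name for c in lm.components] != [c.name for c in rm.components]:
            raise UnsupportedRuleError(
                f"rule '{name}': molecule '{lm.name}' lists different components on the two sides")
        for ci, (lc, rc) in enumerate(zip(lm.components, rm.components)):
            ref: CompRef = (lpi, lmi, ci)
            if lc.state != rc.state:
                if lc.state is None or rc.state is None:
                    raise UnsupportedRuleError(
                        f"rule '{name}': state appears on only one side of '{lm.name}.{lc.name}'")
                state_diffs.append((j, ref, rc.state))
            lb, rb = lc.bond, rc.bond
            if lb == rb:
                continue
            if lb in (BOUND_ANY, WILDCARD) or rb in (BOUND_ANY, WILDCARD):
                raise UnsupportedRuleError(
                    f"rule '{name}': wildcard bond on '{lm.name}.{lc.name}' changes across the rule")
            if isinstance(lb, int) and rb is UNBOUND:
                unbind_ends.append(ref)
            elif lb is UNBOUND and isinstance(rb, int):
                bind_ends.append((ref, rb))
            else:
                raise UnsupportedRuleError(
                    f"rule '{name}': unsupported bond rewrite on '{lm.name}.{lc.name}'")

    n_edits = len(state_diffs) + (1 if unbind_ends else 0) + (1 if bind_ends else 0)
    if len(state_diffs) == 1 and not unbind_ends and not bind_ends:
        if len(lhs) != 1 or len(rhs) != 1:
            raise UnsupportedRuleError(f"rule '{name}': state change must be unimolecular")
        _, ref, new_state = state_diffs[0]
        return Rule(name, tuple(lhs), tuple(rhs), k, RuleClass.STATE_CHANGE,
                    centers=(ref,), new_state=new_state)
    if unbind_ends and not state_diffs and not bind_ends:
        if len(unbind_ends) != 2 or len(lhs) != 1:
            raise UnsupportedRuleError(f"rule '{name}': unsupported dissociation form")
        (p1, m1, c1), (p2, m2, c2) = unbind_ends
        b1 = lhs[p1].molecules[m1].components[c1].bond
        b2 = lhs[p2].molecules[m2].components[c2].bond
        if b1 != b2:
            raise UnsupportedRuleError(f"rule '{name}': deleted bond endpoints do not pair up")
        return Rule(name, tuple(lhs), tuple(rhs), k, RuleClass.DISSOCIATION,
                    centers=tuple(unbind_ends), n_products_required=len(rhs))
    if bind_ends and not state_diffs and not unbind_ends:
        if len(bind_ends) != 2 or len(rhs) != 1:
            raise UnsupportedRuleError(f"rule '{name}': unsupported association form")
        (ref1, bid1), (ref2, bid2) = bind_ends
        if bid1 != bid2:
            raise UnsupportedRuleError(f"rule '{name}': created bond endpoints do not pair up")
        if len(lhs) == 2:
            if ref1[0] == ref2[0]:
                raise UnsupportedRuleError(
                    f"rule '{name}': '+'-separated rule must bind across the two patterns")
            if ref1[0] == 1:
                ref1, ref2 = ref2, ref1
            sym = 0.5 if render_pattern(lhs[0]) == render_pattern(lhs[1]) else 1.0
            return Rule(name, tuple(lhs), tuple(rhs), k, RuleClass.ASSOCIATION,
                        centers=(ref1, ref2), symmetry_factor=sym)
        cls = RuleClass.RING_MONO if ref1[1] == ref2[1] else RuleClass.RING_NONMONO
        return Rule(name, tuple(lhs), tuple(rhs), k, cls, centers=(ref1, ref2))
    raise UnsupportedRuleError(
        f"rule '{name}': transformation is not exactly one state edit, bond deletion "
        f"or bond creation ({n_edits} edits found)")


# ---------------------------------------------------------------------------
# per-species reaction-instance enumeration
# ---------------------------------------------------------------------------

def _mc(ref: CompRef) -> tuple[int, int]:
    return (ref[1], ref[2])


def enumerate_instances(rule: Rule, sp: SpeciesInstance) -> list[tuple]:
    """Distinct reaction instances of a non-association rule wholly inside
    ``sp``: concrete center tuples in deterministic order."""
    if rule.rule_class is RuleClass.ASSOCIATION:
        raise ValueError("association instances span two species")
    if rule.rule_class is RuleClass.STATE_CHANGE:
        return center_images(rule.lhs[0], [_mc(rule.centers[0])], sp)
    pairs = center_images(rule.lhs[0], [_mc(rule.centers[0]), _mc(rule.centers[1])], sp)
    if rule.rule_class is RuleClass.DISSOCIATION:
        want_split = rule.n_products_required == 2
        return [p for p in pairs
                if bond_splits_species(sp, p[0][0], p[0][1]) == want_split]
    return pairs  # ring classes: mono/nonmono placement is forced by the pattern


def species_weight(rule: Rule, sp: SpeciesInstance) -> int:
    """v(l, s): the number of distinct reaction instances inside ``sp``."""
    return len(enumerate_instances(rule, sp))


def assoc_center_lists(rule: Rule, sp: SpeciesInstance):
    """Distinct center images of the two association patterns in ``sp``."""
    c1 = center_images(rule.lhs[0], [_mc(rule.centers[0])], sp)
    c2 = center_images(rule.lhs[1], [(rule.centers[1][1], rule.centers[1][2])], sp)
    return [c[0] for c in c1], [c[0] for c in c2]


# ---------------------------------------------------------------------------
# de-novo rule rates (used at initialization and as the consistency check)
# ---------------------------------------------------------------------------

def rate_state_change(rule: Rule, state) -> float:
    assert rule.rule_class is RuleClass.STATE_CHANGE
    return rule.k * sum(species_weight(rule, sp) for sp in state.instances.values())


def rate_dissociation(rule: Rule, state) -> float:
    assert rule.rule_class is RuleClass.DISSOCIATION
    return rule.k * sum(species_weight(rule, sp) for sp in state.instances.values())


def rate_association(rule: Rule, state) -> float:
    assert rule.rule_class is RuleClass.ASSOCIATION
    v1tot = v2tot = cross = 0
    for sp in state.instances.values():
        c1, c2 = assoc_center_lists(rule, sp)
        v1tot += len(c1)
        v2tot += len(c2)
        cross += len(c1) * len(c2)
    return rule.symmetry_factor * rule.k * (v1tot * v2tot - cross)


def rate_ring_mono(rule: Rule, state) -> float:
    assert rule.rule_class is RuleClass.RING_MONO
    return rule.k * sum(species_weight(rule, sp) for sp in state.instances.values())


def rate_ring_nonmono(rule: Rule, state) -> float:
    assert rule.rule_class is RuleClass.RING_NONMONO
    return rule.k * sum(species_weight(rule, sp) for sp in state.instances.values())


_RATE_FN = {
    RuleClass.STATE_CHANGE: rate_state_change,
    RuleClass.DISSOCIATION: rate_dissociation,
    RuleClass.ASSOCIATION: rate_association,
    RuleClass.RING_MONO: rate_ring_mono,
    RuleClass.RING_NONMONO: rate_ring_nonmono,
}


def rule_rate(rule: Rule, state) -> float:
    """De-novo cumulative rate of ``rule`` against the full system state."""
    return _RATE_FN[rule.rule_class](rule, state)


# ---------------------------------------------------------------------------
# incremental activity
# ---------------------------------------------------------------------------

@dataclass
class StateDelta:
    """Species instances removed and added by one reaction event.

    Molecule instances are conserved between the two sides.
    """

    removed: list[int] = field(default_factory=list)
    added: list[SpeciesInstance] = field(default_factory=list)


class RuleActivity:
    """Per-rule cumulative rates maintained incrementally.

    For each rule the per-species center counts are stored as integers;
    cumulative rates are recovered as ``k * (integer combinatorics)``, so
    the incremental values equal de-novo recomputation exactly.  After
    initialization rates are only ever updated through
    :meth:`apply_delta` — never recomputed from scratch.
    """

    def __init__(self, rules: Sequence[Rule]) -> None:
        self.rules = list(rules)
        self._w: list[dict[int, int]] = [{} for _ in self.rules]       # non-assoc
        self._v1: list[dict[int, int]] = [{} for _ in self.rules]      # assoc
        self._v2: list[dict[int, int]] = [{} for _ in self.rules]
        self._W = [0] * len(self.rules)
        self._V1 = [0] * len(self.rules)
        self._V2 = [0] * len(self.rules)
        self._S12 = [0] * len(self.rules)

    def initialize(self, state) -> None:
        for sp in state.instances.values():
            self.add_species(sp)

    def add_species(self, sp: SpeciesInstance) -> None:
        for i, rule in enumerate(self.rules):
            if rule.rule_class is RuleClass.ASSOCIATION:
                c1, c2 = assoc_center_lists(rule, sp)
                if c1:
                    self._v1[i][sp.uid] = len(c1)
                    self._V1[i] += len(c1)
                if c2:
                    self._v2[i][sp.uid] = len(c2)
                    self._V2[i] += len(c2)
                if c1 and c2:
                    self._S12[i] += len(c1) * len(c2)
            else:
                w = species_weight(rule, sp)
                if w:
                    self._w[i][sp.uid] = w
                    self._W[i] += w

    def remove_species(self, uid: int) -> None:
        for i, rule in enumerate(self.rules):
            if rule.rule_class is RuleClass.ASSOCIATION:
                v1 = self._v1[i].pop(uid, 0)
                v2 = self._v2[i].pop(uid, 0)
                self._V1[i] -= v1
                self._V2[i] -= v2
                self._S12[i] -= v1 * v2
            else:
                self._W[i] -= self._w[i].pop(uid, 0)
            if self._W[i] < 0 or self._V1[i] < 0 or self._V2[i] < 0 or self._S12[i] < 0:
                raise RuntimeError(f"negative activity for rule '{rule.name}' (bookkeeping bug)")

    def apply_delta(self, delta: StateDelta) -> None:
        for uid in delta.removed:
            self.remove_species(uid)
        for sp in delta.added:
            self.add_species(sp)

    def rate(self, i: int) -> float:
        rule = self.rules[i]
        if rule.rule_class is RuleClass.ASSOCIATION:
            pairs = self._V1[i] * self._V2[i] - self._S12[i]
            return rule.symmetry_factor * rule.k * pairs
        return rule.k * self._W[i]

    def rates(self) -> np.ndarray:
        return np.array([self.rate(i) for i in range(len(self.rules))])

    def r_tot(self) -> float:
        return float(self.rates().sum())

    # exposed for reactant selection
    def weights(self, i: int) -> dict[int, int]:
        return self._w[i]

    def assoc_counts(self, i: int):
        return self._v1[i], self._v2[i], self._V1[i], self._V2[i]


def update_activity(activity: RuleActivity, delta: StateDelta) -> RuleActivity:
    """Apply a state delta to the incrementally maintained rates."""
    activity.apply_delta(delta)
    return activity


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    """A concrete reaction instance chosen for execution."""

    species: tuple[SpeciesInstance, ...]
    centers: tuple[tuple[Molecule, int], ...]


def apply_rule(rule: Rule, selection: Selection, state) -> StateDelta:
    """Execute the rule's rewrite on the selected concrete reactants.

    Mutates the molecule instances in place (uids preserved), re-partitions
    the affected molecules into connected species instances, updates
    ``state.instances`` and returns the delta.
    """
    for sp in selection.species:
        if state.instances.get(sp.uid) is not sp:
            raise RuntimeError("stale selection: species no longer present (bookkeeping bug)")
    if rule.rule_class is RuleClass.STATE_CHANGE:
        mol, ci = selection.centers[0]
        mol.states[ci] = rule.new_state
    elif rule.rule_class is RuleClass.DISSOCIATION:
        (a, ai), (b, bi) = selection.centers
        if a.bonds[ai] is None or a.bonds[ai][0] is not b or a.bonds[ai][1] != bi:
            raise RuntimeError("stale selection: centers not bonded")
        break_bond(a, ai)
    else:  # ASSOCIATION and ring closures all create one bond
        (a, ai), (b, bi) = selection.centers
        make_bond(a, ai, b, bi)

    pool: list[Molecule] = []
    for sp in selection.species:
        pool.extend(sp.molecules)
    added = split_into_species(pool, uids=state.uid_source())
    removed = [sp.uid for sp in selection.species]
    if rule.rule_class is RuleClass.DISSOCIATION and len(added) != rule.n_products_required:
        raise RuntimeError("dissociation produced the wrong number of products")
    if rule.rule_class is RuleClass.ASSOCIATION and len(added) != 1:
        raise RuntimeError("association did not yield a single species")
    for uid in removed:
        del state.instances[uid]
    for sp in added:
        state.instances[sp.uid] = sp
    return StateDelta(removed=removed, added=added)
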