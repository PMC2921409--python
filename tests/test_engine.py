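"""Rule classification, the five rate formulas, and incremental activity.

Every rate contract is pinned against the independent brute-force
enumerator from the oracle module: rate == k x (instance count), exactly,
because all center bookkeeping is integer-valued.
"""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rulekmc.simulate as sim
from rulekmc.bngl import parse_model, parse_pattern, parse_reactant_side
from rulekmc.engine import (
    RuleClass,
    UnsupportedRuleError,
    build_rule,
    rule_rate,
)
from rulekmc.graphs import instantiate_pattern, split_into_species
from rulekmc.oracle import brute_force_rule_rate
from rulekmc.simulate import SystemState
from conftest import T_A, T_B, T_L, T_P, T_R, T_X, random_state
from rulekmc.graphs import ComponentDef, MoleculeTypeDef

TYPES = {
    "X": MoleculeTypeDef("X", (ComponentDef("y", ("0", "1")),)),
    "A": MoleculeTypeDef("A", (ComponentDef("a"), ComponentDef("b"),
                               ComponentDef("y", ("0", "1")))),
    "B": MoleculeTypeDef("B", (ComponentDef("a"),)),
    "M": MoleculeTypeDef("M", (ComponentDef("a"), ComponentDef("b"))),
    "P": MoleculeTypeDef("P", (ComponentDef("a"), ComponentDef("b"))),
    "L": MoleculeTypeDef("L", (ComponentDef("s"), ComponentDef("s"))),
    "R": MoleculeTypeDef("R", (ComponentDef("s"), ComponentDef("s"))),
}


def rule(text: str, k: float = 1.0, name: str = "r"):
    lhs_text, rhs_text = text.split("->")
    return build_rule(name, parse_reactant_side(lhs_text.strip()),
                      parse_reactant_side(rhs_text.strip()), k)


def state_of(*exprs: str) -> SystemState:
    state = SystemState()
    for expr in exprs:
        mols = instantiate_pattern(parse_pattern(expr), TYPES, state.mol_uid_source())
        for sp in split_into_species(mols, state.uid_source()):
            state.add(sp)
    return state


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,cls,extra", [
    ("X(y~0) -> X(y~1)", RuleClass.STATE_CHANGE, {"new_state": "1"}),
    ("A(b!1).B(a!1) -> A(b) + B(a)", RuleClass.DISSOCIATION, {"n_products_required": 2}),
    ("M(a!1).M(b!1) -> M(a).M(b)", RuleClass.DISSOCIATION, {"n_products_required": 1}),
    ("A(b) + B(a) -> A(b!1).B(a!1)", RuleClass.ASSOCIATION, {"symmetry_factor": 1.0}),
    ("A(a) + A(a) -> A(a!1).A(a!1)", RuleClass.ASSOCIATION, {"symmetry_factor": 0.5}),
    ("P(a,b) -> P(a!1,b!1)", RuleClass.RING_MONO, {}),
    ("L(s).R(s) -> L(s!1).R(s!1)", RuleClass.RING_NONMONO, {}),
])
def test_classification(text, cls, extra):
    r = rule(text)
    assert r.rule_class is cls
    for key, val in extra.items():
        assert getattr(r, key) == val


@pytest.mark.parametrize("text", [
    "X(y~0) -> X(y~1) + X(y~1)",             # state change cannot split
    "A(b,y~0) -> A(b!1,y~1).B(a!1)",         # molecule appears from nowhere
    "A(b) + B(a) -> A(b).B(a)",              # no transformation at all
    "A(b,y~0) -> A(b!1,y~1)",                # dangling new bond (and 2 edits)
    "M(a!1,b!2).M(a!2,b!1) -> M(a,b) + M(a,b)",  # two bonds deleted at once
])
def test_unsupported_rules_rejected(text):
    with pytest.raises((UnsupportedRuleError, ValueError)):
        rule(text)


def test_mixed_ring_and_molecularity_errors():
    with pytest.raises(UnsupportedRuleError):
        # '+'-separated rule whose new bond sits inside one pattern
        build_rule("bad", parse_reactant_side("P(a,b)+P(a,b)"),
                   parse_reactant_side("P(a!1,b!1).P(a,b)"), 1.0)


# ---------------------------------------------------------------------------
# rate formulas (frozen examples, each checked against the brute-force oracle)
# ---------------------------------------------------------------------------

def assert_rate(r, state, expected):
    assert rule_rate(r, state) == pytest.approx(expected)
    assert brute_force_rule_rate(r, state) == pytest.approx(expected)


def test_rate_state_change():
    r = rule("X(y~0) -> X(y~1)", k=2.0)
    assert_rate(r, state_of("X(y~0)", "X(y~0)", "X(y~0)"), 6.0)
    assert_rate(r, state_of("X(y~1)"), 0.0)


def test_rate_state_change_two_centers_one_species():
    # one species carrying two eligible centers: a molecule with two
    # identical modifiable sites, both unmodified
    model = parse_model("""
begin molecule types
  W(y~0~1,y~0~1)
end molecule types
begin species
  W(y~0,y~0) 1
end species
begin reaction rules
  flip: W(y~0) -> W(y~1) 1.0
end reaction rules
begin observables
  Molecules W0 W(y~0)
end observables
""")
    state, act, _ = sim.initialize(model)
    assert act.rates()[0] == pytest.approx(2.0)
    assert brute_force_rule_rate(model.rules[0], state) == pytest.approx(2.0)


def test_rate_dissociation_two_product():
    r = rule("A(b!1).B(a!1) -> A(b) + B(a)", k=1.0)
    st_ = state_of(*["A(a,b!1,y~0).B(a!1)"] * 5)
    assert_rate(r, st_, 5.0)


def test_rate_dissociation_ring_bond():
    two_prod = rule("M(a!1).M(b!1) -> M(a) + M(b)", k=1.0)
    one_prod = rule("M(a!1).M(b!1) -> M(a).M(b)", k=1.0)
    ring = state_of("M(a!1,b!3).M(a!3,b!2).M(a!2,b!1)")
    chain = state_of("M(a!1,b).M(a!2,b!1).M(a,b!2)")
    assert_rate(two_prod, ring, 0.0)    # every bond is in the ring
    assert_rate(one_prod, ring, 3.0)    # each of the 3 ring bonds opens in place
    assert_rate(two_prod, chain, 2.0)
    assert_rate(one_prod, chain, 0.0)


def test_rate_association():
    r = rule("A(b) + B(a) -> A(b!1).B(a!1)", k=0.1)
    st_ = state_of("A(a,b,y~0)", "A(a,b,y~0)", "B(a)", "B(a)", "B(a)")
    assert_rate(r, st_, 0.6)            # 2 x 3 pairs


def test_rate_association_symmetric():
    r = rule("A(a) + A(a) -> A(a!1).A(a!1)", k=1.0)
    st_ = state_of(*["A(a,b,y~0)"] * 4)
    assert_rate(r, st_, 6.0)            # 4*3/2 unordered pairs


def test_rate_association_molecularity_two_enforced():
    """A single chain matched by both patterns contributes nothing: the
    correction term cancels the first term entirely."""
    r = rule("M(a) + M(b) -> M(a!1).M(b!1)", k=1.0)
    st_ = state_of("M(a!1,b).M(a,b!1)")  # one species with a free a and a free b
    assert_rate(r, st_, 0.0)


def test_rate_ring_mono():
    r = rule("P(a,b) -> P(a!1,b!1)", k=1.0)
    assert_rate(r, state_of("P(a,b)", "P(a,b)", "P(a,b)", "P(a,b)"), 4.0)
    # a molecule whose a-site is occupied contributes nothing
    assert_rate(r, state_of("P(a!1,b).P(a,b!1)"), 0.0)


def test_rate_ring_mono_two_molecule_species():
    # species of two molecules, each with both ring sites free, joined
    # through a separate linker site
    model = parse_model("""
begin molecule types
  P(a,b,c)
end molecule types
begin species
  P(a,b,c!1).P(a,b,c!1) 1
end species
begin reaction rules
  fold: P(a,b) -> P(a!1,b!1) 1.0
end reaction rules
begin observables
  Molecules Open P(a,b)
end observables
""")
    state, act, _ = sim.initialize(model)
    assert act.rates()[0] == pytest.approx(2.0)
    assert brute_force_rule_rate(model.rules[0], state) == pytest.approx(2.0)


def test_rate_ring_nonmono():
    r = rule("L(s).R(s) -> L(s!1).R(s!1)", k=2.0)
    st_ = state_of("L(s!1,s).R(s!1,s)", "L(s!1,s).R(s!1,s)")
    assert_rate(r, st_, 4.0)            # two dimers, one closable pair each
    # both free sites on one molecule of the wrong shape: no instance
    assert_rate(r, state_of("R(s,s)"), 0.0)


# ---------------------------------------------------------------------------
# randomized oracle equivalence (exact, per class)
# ---------------------------------------------------------------------------

CLASS_CONFIGS = [
    ("X(y~0) -> X(y~1)", [T_X], False),
    ("L(s!1).R(s!1) -> L(s) + R(s)", [T_L, T_R], False),
    ("L(s!1).R(s!1) -> L(s).R(s)", [T_L, T_R], False),
    ("A(a) + B(a) -> A(a!1).B(a!1)", [T_A, T_B], False),
    ("A(a) + A(a) -> A(a!1).A(a!1)", [T_A], False),
    ("P(a,b) -> P(a!1,b!1)", [T_P], True),
    ("L(s).R(s) -> L(s!1).R(s!1)", [T_L, T_R], False),
]


@pytest.mark.parametrize("text,types,intra", CLASS_CONFIGS)
def test_oracle_equivalence_randomized(text, types, intra):
    """rate_* == k x brute-force instance count, exactly, on random states."""
    r = rule(text, k=0.37)
    rnd = random.Random(hash(text) & 0xFFFF)
    for _ in range(30):
        st_ = random_state(rnd, types, rnd.randrange(2, 25),
                           rnd.randrange(0, 20), allow_intramolecular=intra)
        assert rule_rate(r, st_) == brute_force_rule_rate(r, st_)


# ---------------------------------------------------------------------------
# event application and incremental updates
# ---------------------------------------------------------------------------

def _counts(state):
    out = {}
    for sp in state.instances.values():
        for m in sp.molecules:
            out[m.mtype.name] = out.get(m.mtype.name, 0) + 1
    return out


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_random_events_keep_activity_consistent(seed):
    """After any sequence of events the incrementally maintained rates equal
    de-novo recomputation, and molecule counts are conserved."""
    model = parse_model("""
begin parameters
  kon 0.3
  koff 1.0
end parameters
begin molecule types
  L(s,s)
  R(s,s)
end molecule types
begin species
  L(s,s) 8
  R(s,s) 6
end species
begin reaction rules
  bind: L(s) + R(s) -> L(s!1).R(s!1) kon
  close: L(s).R(s) -> L(s!1).R(s!1) kon
  open2: L(s!1).R(s!1) -> L(s) + R(s) koff
  open1: L(s!1).R(s!1) -> L(s).R(s) koff
end reaction rules
begin observables
  Molecules Bonds L(s!+)
end observables
""")
    state, act, tracker = sim.initialize(model)
    rng = np.random.default_rng(seed)
    before = _counts(state)
    for _ in range(60):
        if not sim.step(state, act, tracker, rng):
            break
        for i, r in enumerate(model.rules):
            de_novo = rule_rate(r, state)
            assert act.rate(i) == pytest.approx(de_novo, rel=1e-12, abs=1e-12)
        assert sim.eval_observable(model.observables[0], state) == tracker.values()[0]
    assert _counts(state) == before
    state.validate()


def test_apply_preserves_molecule_uids():
    model = parse_model("""
begin molecule types
  A(a)
end molecule types
begin species
  A(a) 2
end species
begin reaction rules
  dim: A(a) + A(a) -> A(a!1).A(a!1) 1.0
end reaction rules
begin observables
  Molecules Mono A(a)
end observables
""")
    state, act, tracker = sim.initialize(model)
    uids_before = {m.uid for sp in state.instances.values() for m in sp.molecules}
    rng = np.random.default_rng(0)
    assert sim.step(state, act, tracker, rng)
    (sp,) = state.instances.values()
    assert len(sp.molecules) == 2
    assert {m.uid for m in sp.molecules} == uids_before
    assert act.rates()[0] == 0.0
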