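"""Shared helpers: randomized small site-graph states for oracle tests.

All randomness is seeded; every helper builds states through the public
data model so structural invariants (mutual bonds, connectivity) hold by
construction.
"""

from __future__ import annotations

import random

import pytest

from rulekmc.graphs import (
    ComponentDef,
    Molecule,
    MoleculeTypeDef,
    make_bond,
    split_into_species,
)
from rulekmc.simulate import SystemState

# small type vocabulary used by the randomized rule-class states
T_X = MoleculeTypeDef("X", (ComponentDef("y", ("0", "1")), ComponentDef("z", ("0", "1"))))
T_L = MoleculeTypeDef("L", (ComponentDef("s"), ComponentDef("s")))
T_R = MoleculeTypeDef("R", (ComponentDef("s"), ComponentDef("s")))
T_P = MoleculeTypeDef("P", (ComponentDef("a"), ComponentDef("b")))
T_A = MoleculeTypeDef("A", (ComponentDef("a"),))
T_B = MoleculeTypeDef("B", (ComponentDef("a"),))


def random_state(rnd: random.Random, types, n_mols: int, n_bond_attempts: int,
                 allow_intramolecular: bool = True) -> SystemState:
    """A random particle state: molecules with random internal states and
    random bonds (possibly rings, possibly intramolecular)."""
    state = SystemState()
    mol_uids = state.mol_uid_source()
    mols: list[Molecule] = []
    for _ in range(n_mols):
        mt = rnd.choice(types)
        mol = Molecule(mt, next(mol_uids))
        for ci, cd in enumerate(mt.components):
            if cd.states:
                mol.states[ci] = rnd.choice(cd.states)
        mols.append(mol)
    for _ in range(n_bond_attempts):
        free = [(m, ci) for m in mols for ci in range(len(m.mtype.components))
                if m.bonds[ci] is None]
        if len(free) < 2:
            break
        (a, ai), (b, bi) = rnd.sample(free, 2)
        if a is b and not allow_intramolecular:
            continue
        make_bond(a, ai, b, bi)
    for sp in split_into_species(mols, state.uid_source()):
        state.add(sp)
    return state


@pytest.fixture
def rnd() -> random.Random:
    return random.Random(20240917)
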