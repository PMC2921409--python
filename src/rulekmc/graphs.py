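"""Site-graph data model and matching machinery.

Chemical species are represented as *site graphs*: molecules carry named
components (binding sites / modifiable residues), components carry an
optional internal state and at most one bond to another component.  A
connected site graph of concrete molecules is a :class:`SpeciesInstance`
— one tracked particle copy of a chemical species.

Patterns (:class:`PatternGraph`) are partial site graphs used by rules and
observables; they recognise species by subgraph embedding.  The matcher
(:func:`find_matches`) returns *all* injections, including those that
differ only by permutations of chemically indistinguishable components;
degeneracy is removed downstream by deduplicating reaction-center images.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nx_iso

# Bond requirement sentinels for pattern components.  A listed component
# with no "!" suffix is required to be UNBOUND; "!+" requires a bond to
# anything; "!?" places no constraint; an integer is an explicit bond id
# pairing two components within one pattern.
UNBOUND = "unbound"
BOUND_ANY = "bound-any"
WILDCARD = "wildcard"


# ---------------------------------------------------------------------------
# type declarations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentDef:
    """A declared component of a molecule type.

    ``states`` is empty for components that carry no internal state.
    Components with identical name and identical allowed states are
    chemically indistinguishable and may repeat within one molecule type.
    """

    name: str
    states: tuple[str, ...] = ()


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    components: tuple[ComponentDef, ...] = ()


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternComponent:
    name: str
    state: Optional[str] = None          # None = any state
    bond: object = UNBOUND               # UNBOUND | BOUND_ANY | WILDCARD | int


@dataclass(frozen=True)
class PatternMolecule:
    name: str
    components: tuple[PatternComponent, ...] = ()


@dataclass(frozen=True)
class PatternGraph:
    """One LHS/RHS pattern: molecules joined by "." into a single graph.

    Dotted molecules need not be bond-connected; the "." grouping itself
    demands that all of them embed into the *same* species instance.
    """

    molecules: tuple[PatternMolecule, ...]

    def __post_init__(self) -> None:
        ends: dict[int, list[tuple[int, int]]] = {}
        for mi, pm in enumerate(self.molecules):
            for ci, pc in enumerate(pm.components):
                if isinstance(pc.bond, int):
                    ends.setdefault(pc.bond, []).append((mi, ci))
        for bid, pair in ends.items():
            if len(pair) != 2:
                raise ValueError(f"bond index !{bid} does not pair up in pattern {render_pattern(self)}")
        object.__setattr__(self, "_bond_pairs", {b: (p[0], p[1]) for b, p in ends.items()})

    @property
    def bond_pairs(self) -> dict[int, tuple[tuple[int, int], tuple[int, int]]]:
        return self._bond_pairs  # type: ignore[attr-defined]


def render_pattern(pattern: PatternGraph) -> str:
    parts = []
    for pm in pattern.molecules:
        comps = []
        for pc in pm.components:
            s = pc.name
            if pc.state is not None:
                s += f"~{pc.state}"
            if isinstance(pc.bond, int):
                s += f"!{pc.bond}"
            elif pc.bond is BOUND_ANY:
                s += "!+"
            elif pc.bond is WILDCARD:
                s += "!?"
            comps.append(s)
        parts.append(f"{pm.name}({','.join(comps)})")
    return ".".join(parts)


# ---------------------------------------------------------------------------
# concrete instances
# ---------------------------------------------------------------------------

class Molecule:
    """One concrete molecule: per-component internal state and bond partner.

    Component identity is positional (index into the type's declared
    components), so two same-named sites are distinguishable as particles
    but chemically indistinguishable in all counts.
    """

    __slots__ = ("mtype", "states", "bonds", "uid")

    def __init__(self, mtype: MoleculeTypeDef, uid: int,
                 states: Optional[list[Optional[str]]] = None) -> None:
        self.mtype = mtype
        self.uid = uid
        if states is None:
            states = [cd.states[0] if cd.states else None for cd in mtype.components]
        self.states: list[Optional[str]] = states
        # bond partner per component: (Molecule, comp_index) or None
        self.bonds: list[Optional[tuple["Molecule", int]]] = [None] * len(mtype.components)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Molecule {self.mtype.name}#{self.uid}>"


class SpeciesInstance:
    """A connected site graph of molecules: one particle copy of a species."""

    __slots__ = ("molecules", "uid")

    def __init__(self, molecules: list[Molecule], uid: int) -> None:
        self.molecules = molecules
        self.uid = uid

    def n_bonds(self) -> int:
        n = 0
        for m in self.molecules:
            n += sum(1 for b in m.bonds if b is not None)
        return n // 2

    def __len__(self) -> int:
        return len(self.molecules)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Species #{self.uid} {render_species(self)}>"


def make_bond(a: Molecule, ai: int, b: Molecule, bi: int) -> None:
    if a.bonds[ai] is not None or b.bonds[bi] is not None:
        raise ValueError("component already bound")
    if a is b and ai == bi:
        raise ValueError("component cannot bind itself")
    a.bonds[ai] = (b, bi)
    b.bonds[bi] = (a, ai)


def break_bond(a: Molecule, ai: int) -> None:
    partner = a.bonds[ai]
    if partner is None:
        raise ValueError("component not bound")
    b, bi = partner
    a.bonds[ai] = None
    b.bonds[bi] = None


def instantiate_pattern(pattern: PatternGraph,
                        types: dict[str, MoleculeTypeDef],
                        uids: Iterator[int]) -> list[Molecule]:
    """Build concrete molecules from a fully specified species expression.

    The expression must list every declared component of each molecule
    exactly once, give explicit states for stateful components, and use
    only explicit integer bonds (no wildcards).
    """
    mols: list[Molecule] = []
    comp_map: dict[tuple[int, int], tuple[Molecule, int]] = {}
    for mi, pm in enumerate(pattern.molecules):
        if pm.name not in types:
            raise ValueError(f"undeclared molecule type '{pm.name}'")
        mt = types[pm.name]
        mol = Molecule(mt, next(uids), states=[None] * len(mt.components))
        used: set[int] = set()
        for ci, pc in enumerate(pm.components):
            if pc.bond in (BOUND_ANY, WILDCARD):
                raise ValueError(f"wildcard bond in seed species {render_pattern(pattern)}")
            target = None
            for ti, cd in enumerate(mt.components):
                if ti in used or cd.name != pc.name:
                    continue
                target = ti
                break
            if target is None:
                raise ValueError(f"component '{pc.name}' not available on molecule type '{pm.name}'")
            used.add(target)
            cd = mt.components[target]
            if cd.states:
                if pc.state is None:
                    raise ValueError(
                        f"seed species must give a state for component '{pm.name}.{pc.name}'")
                if pc.state not in cd.states:
                    raise ValueError(
                        f"state '~{pc.state}' not declared for component '{pm.name}.{pc.name}'")
                mol.states[target] = pc.state
            elif pc.state is not None:
                raise ValueError(f"component '{pm.name}.{pc.name}' carries no internal state")
            comp_map[(mi, ci)] = (mol, target)
        if len(used) != len(mt.components):
            raise ValueError(
                f"seed species must list all components of '{pm.name}' exactly once")
        mols.append(mol)
    for bid, (end1, end2) in pattern.bond_pairs.items():
        (m1, c1), (m2, c2) = comp_map[end1], comp_map[end2]
        make_bond(m1, c1, m2, c2)
    return mols


def copy_molecules(molecules: Sequence[Molecule], uids: Iterator[int]) -> list[Molecule]:
    """Deep-copy a set of molecules, preserving bonds among them."""
    clones = {id(m): Molecule(m.mtype, next(uids), states=list(m.states)) for m in molecules}
    for m in molecules:
        cm = clones[id(m)]
        for ci, b in enumerate(m.bonds):
            if b is not None:
                partner, pi = b
                if id(partner) not in clones:
                    raise ValueError("bond leaves the copied molecule set")
                cm.bonds[ci] = (clones[id(partner)], pi)
    return [clones[id(m)] for m in molecules]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class Match:
    """An injection of a pattern into a species instance.

    ``mols[i]`` is the image of pattern molecule ``i``; ``comps[(i, ci)]``
    is the component index (on ``mols[i]``) of pattern component ``ci``.
    """

    mols: tuple[Molecule, ...]
    comps: dict[tuple[int, int], int] = field(default_factory=dict)

    def comp_image(self, ref: tuple[int, int]) -> tuple[Molecule, int]:
        return self.mols[ref[0]], self.comps[ref]


def _comp_compatible(pc: PatternComponent, mol: Molecule, ci: int) -> bool:
    cd = mol.mtype.components[ci]
    if cd.name != pc.name:
        return False
    if pc.state is not None and mol.states[ci] != pc.state:
        return False
    bond = mol.bonds[ci]
    if pc.bond is UNBOUND:
        return bond is None
    if pc.bond is BOUND_ANY or isinstance(pc.bond, int):
        return bond is not None
    return True  # WILDCARD


def _molecule_order(pattern: PatternGraph) -> list[int]:
    """Order pattern molecules so each one is, where possible, bond-connected
    to an earlier one (lets the matcher follow bonds instead of scanning)."""
    n = len(pattern.molecules)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for (e1, e2) in pattern.bond_pairs.values():
        adj[e1[0]].add(e2[0])
        adj[e2[0]].add(e1[0])
    order: list[int] = []
    seen: set[int] = set()
    for start in range(n):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            order.append(cur)
            for nb in sorted(adj[cur]):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
    return order


def find_matches(pattern: PatternGraph, species: SpeciesInstance) -> list[Match]:
    """Return every injection of ``pattern`` into ``species``.

    Symmetric embeddings (pattern automorphisms) are counted as distinct,
    matching the "distinct mappings (injections)" semantics; callers that
    need reaction centers or images deduplicate downstream.
    """
    order = _molecule_order(pattern)
    matches: list[Match] = []
    mol_images: dict[int, Molecule] = {}
    comp_images: dict[tuple[int, int], int] = {}
    used_mols: set[int] = set()

    def bond_partner_ref(mi: int, ci: int) -> Optional[tuple[int, int]]:
        pc = pattern.molecules[mi].components[ci]
        if isinstance(pc.bond, int):
            e1, e2 = pattern.bond_pairs[pc.bond]
            return e2 if e1 == (mi, ci) else e1
        return None

    def assign_comps(mi: int, mol: Molecule, todo: list[int],
                     used_comps: set[int]) -> Iterator[None]:
        if not todo:
            yield None
            return
        ci = todo[0]
        pc = pattern.molecules[mi].components[ci]
        for target in range(len(mol.mtype.components)):
            if target in used_comps or not _comp_compatible(pc, mol, target):
                continue
            # explicit-bond consistency with already-assigned partner
            if isinstance(pc.bond, int):
                pref = bond_partner_ref(mi, ci)
                if pref in comp_images and pref[0] in mol_images:
                    partner = mol.bonds[target]
                    if partner is None:
                        continue
                    want = (mol_images[pref[0]], comp_images[pref])
                    if partner[0] is not want[0] or partner[1] != want[1]:
                        continue
            comp_images[(mi, ci)] = target
            used_comps.add(target)
            yield from assign_comps(mi, mol, todo[1:], used_comps)
            used_comps.discard(target)
            del comp_images[(mi, ci)]

    def place(pos: int) -> None:
        if pos == len(order):
            matches.append(Match(
                mols=tuple(mol_images[i] for i in range(len(pattern.molecules))),
                comps=dict(comp_images)))
            return
        mi = order[pos]
        pm = pattern.molecules[mi]
        # candidates: follow a bond from an already-placed molecule if possible
        candidates: Optional[list[Molecule]] = None
        for ci, pc in enumerate(pm.components):
            if not isinstance(pc.bond, int):
                continue
            pref = bond_partner_ref(mi, ci)
            if pref is not None and pref in comp_images:
                pmol = mol_images[pref[0]]
                partner = pmol.bonds[comp_images[pref]]
                candidates = [] if partner is None else [partner[0]]
                break
        if candidates is None:
            candidates = [m for m in species.molecules if m.mtype.name == pm.name]
        for mol in candidates:
            if mol.mtype.name != pm.name or id(mol) in used_mols:
                continue
            mol_images[mi] = mol
            used_mols.add(id(mol))
            for _ in assign_comps(mi, mol, list(range(len(pm.components))), set()):
                place(pos + 1)
            used_mols.discard(id(mol))
            del mol_images[mi]

    place(0)
    # final verification of every explicit pattern bond (defensive; partner
    # checks above already prune all but deferred orderings)
    verified = []
    for m in matches:
        ok = True
        for e1, e2 in pattern.bond_pairs.values():
            a, ai = m.comp_image(e1)
            b, bi = m.comp_image(e2)
            if a.bonds[ai] is None or a.bonds[ai][0] is not b or a.bonds[ai][1] != bi:
                ok = False
                break
        if ok:
            verified.append(m)
    return verified


def count_reaction_centers(pattern: PatternGraph,
                           centers: Sequence[tuple[int, int]],
                           species: SpeciesInstance) -> int:
    """Number of *distinct* reaction-center images of ``pattern`` in ``species``.

    Distinct center images, not match count: a contextual constraint that
    can be satisfied several ways around one center contributes one.
    """
    return len(center_images(pattern, centers, species))


def center_images(pattern: PatternGraph,
                  centers: Sequence[tuple[int, int]],
                  species: SpeciesInstance) -> list[tuple[tuple[int, int], ...]]:
    """Distinct images of the center components, as sorted (mol_uid-keyed)
    tuples of (molecule, comp_index) pairs, in deterministic order."""
    seen: dict[tuple, tuple] = {}
    for m in find_matches(pattern, species):
        img = tuple(sorted(((mol.uid, ci) for mol, ci in
                            (m.comp_image(c) for c in centers))))
        if img not in seen:
            seen[img] = tuple(m.comp_image(c) for c in centers)
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def split_into_species(molecules: Sequence[Molecule],
                       uids: Optional[Iterator[int]] = None) -> list[SpeciesInstance]:
    """Partition molecules into connected components via bonds.

    Restores the connectivity invariant after a bond edit.  Output order
    and within-species molecule order are deterministic (BFS from the
    lowest-uid molecule of each component).
    """
    if uids is None:
        uids = itertools.count()
    by_id = {id(m): m for m in molecules}
    for m in molecules:
        for b in m.bonds:
            if b is not None:
                partner, pi = b
                if id(partner) not in by_id:
                    raise ValueError("bond reaches outside the given molecule set")
                back = partner.bonds[pi]
                if back is None or back[0] is not m:
                    raise ValueError("non-mutual bond")
    remaining = {id(m) for m in molecules}
    out: list[SpeciesInstance] = []
    for m in sorted(molecules, key=lambda x: x.uid):
        if id(m) not in remaining:
            continue
        comp: list[Molecule] = []
        queue = [m]
        remaining.discard(id(m))
        while queue:
            cur = queue.pop(0)
            comp.append(cur)
            for b in cur.bonds:
                if b is not None and id(b[0]) in remaining:
                    remaining.discard(id(b[0]))
                    queue.append(b[0])
        out.append(SpeciesInstance(comp, next(uids)))
    return out


def bond_splits_species(species: SpeciesInstance, a: Molecule, ai: int) -> bool:
    """True iff deleting the bond at (a, ai) disconnects the species.

    Tree shortcut: with n molecules and n-1 bonds every bond is a bridge.
    """
    b, bi = a.bonds[ai]
    if a is b:
        return False
    nb = species.n_bonds()
    if nb == len(species.molecules) - 1:
        return True
    # BFS from a avoiding the bond; if b is reached the bond is in a ring
    seen = {id(a)}
    queue = [a]
    while queue:
        cur = queue.pop()
        for ci, bond in enumerate(cur.bonds):
            if bond is None or (cur is a and ci == ai) or (cur is b and ci == bi):
                continue
            nxt = bond[0]
            if nxt is b:
                return False
            if id(nxt) not in seen:
                seen.add(id(nxt))
                queue.append(nxt)
    return True


# ---------------------------------------------------------------------------
# isomorphism and canonical labels
# ---------------------------------------------------------------------------

def to_networkx(species: SpeciesInstance) -> nx.Graph:
    g = nx.Graph()
    for m in species.molecules:
        g.add_node(("m", m.uid), kind="mol", label=m.mtype.name, state="")
        for ci, cd in enumerate(m.mtype.components):
            g.add_node(("c", m.uid, ci), kind="comp", label=cd.name,
                       state=m.states[ci] or "")
            g.add_edge(("m", m.uid), ("c", m.uid, ci), etype="part")
    for m in species.molecules:
        for ci, b in enumerate(m.bonds):
            if b is not None:
                partner, pi = b
                g.add_edge(("c", m.uid, ci), ("c", partner.uid, pi), etype="bond")
    return g


def species_isomorphic(a: SpeciesInstance, b: SpeciesInstance) -> bool:
    """True iff a and b represent the same chemical species (same multiset of
    molecules, internal states and bond topology, up to relabeling)."""
    if len(a.molecules) != len(b.molecules) or a.n_bonds() != b.n_bonds():
        return False
    nm = nx_iso.categorical_node_match(["kind", "label", "state"], [None, None, None])
    em = nx_iso.categorical_edge_match("etype", None)
    return nx.is_isomorphic(to_networkx(a), to_networkx(b), node_match=nm, edge_match=em)


def _render_ordered(mols: list[Molecule]) -> str:
    pos = {id(m): i for i, m in enumerate(mols)}
    bond_ids: dict[frozenset, int] = {}
    next_id = 1
    parts = []
    for m in mols:
        def key(ci: int) -> tuple:
            b = m.bonds[ci]
            cd = m.mtype.components[ci]
            if b is None:
                return (cd.name, m.states[ci] or "", 1, 0, 0)
            bk = frozenset([(m.uid, ci), (b[0].uid, b[1])])
            assigned = bond_ids.get(bk, 10 ** 9)
            return (cd.name, m.states[ci] or "", 0, pos[id(b[0])], assigned)

        comps = []
        for ci in sorted(range(len(m.mtype.components)), key=key):
            b = m.bonds[ci]
            cd = m.mtype.components[ci]
            s = cd.name
            if m.states[ci] is not None:
                s += f"~{m.states[ci]}"
            if b is not None:
                bk = frozenset([(m.uid, ci), (b[0].uid, b[1])])
                if bk not in bond_ids:
                    bond_ids[bk] = next_id
                    next_id += 1
                s += f"!{bond_ids[bk]}"
            comps.append(s)
        parts.append(f"{m.mtype.name}({','.join(comps)})")
    return ".".join(parts)


def render_species(species: SpeciesInstance) -> str:
    """Debug serialization in BNGL species syntax (storage order)."""
    return _render_ordered(list(species.molecules))


def _refine_colors(species: SpeciesInstance) -> dict[int, int]:
    """Iterative neighborhood refinement; returns molecule uid -> color rank."""
    colors: dict[int, tuple] = {}
    for m in species.molecules:
        sig = tuple(sorted((cd.name, m.states[ci] or "", m.bonds[ci] is not None)
                           for ci, cd in enumerate(m.mtype.components)))
        colors[m.uid] = (m.mtype.name, sig)
    for _ in range(len(species.molecules)):
        new: dict[int, tuple] = {}
        for m in species.molecules:
            nbrs = []
            for ci, b in enumerate(m.bonds):
                if b is not None:
                    partner, pi = b
                    nbrs.append((m.mtype.components[ci].name,
                                 partner.mtype.components[pi].name,
                                 colors[partner.uid]))
            new[m.uid] = (colors[m.uid], tuple(sorted(nbrs)))
        old_classes = len(set(colors.values()))
        colors = new
        if len(set(colors.values())) == old_classes:
            break
    final = {c: i for i, c in enumerate(sorted(set(colors.values())))}
    return {uid: final[c] for uid, c in colors.items()}


_PERM_LIMIT = 2_000_000


def canonical_label(species: SpeciesInstance) -> str:
    """A string label with canonical_label(a) == canonical_label(b) iff
    species_isomorphic(a, b); stable across runs.

    Molecules are first partitioned by iterative neighborhood refinement;
    the label is the lexicographically minimal rendering over orderings
    that permute molecules only within refinement classes.
    """
    ranks = _refine_colors(species)
    groups: dict[int, list[Molecule]] = {}
    for m in species.molecules:
        groups.setdefault(ranks[m.uid], []).append(m)
    total = 1
    for g in groups.values():
        for i in range(2, len(g) + 1):
            total *= i
        if total > _PERM_LIMIT:
            raise ValueError("species too symmetric for canonical labeling at this size")
    best: Optional[str] = None
    ordered_groups = [sorted(groups[r], key=lambda m: m.uid) for r in sorted(groups)]
    for perm_parts in itertools.product(*(itertools.permutations(g) for g in ordered_groups)):
        mols = [m for part in perm_parts for m in part]
        s = _render_ordered(mols)
        if best is None or s < best:
            best = s
    assert best is not None
    return best
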