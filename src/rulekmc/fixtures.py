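"""Programmatic builders for benchmark models.

Every builder assembles BNGL-subset source text and parses it through the
regular front end, so the models exercised in tests are exactly the
models a user would load from a file.

The builders cover the standard network-free benchmark family:

* multisite phosphorylation (2^n-species network from 2n rules),
* TLBR — trivalent ligand, bivalent receptor aggregation with acyclic
  aggregates and a sol-gel (percolation) transition controlled by
  beta = N_R * k_plus2 / k_off,
* a stiff two-reaction model with rate constants separated by a factor phi,
* symmetric dimerization (A + A with a 1/2 statistical factor).
"""

from __future__ import annotations

from dataclasses import dataclass

from .bngl import ModelSpec, parse_model
from .simulate import SystemState


@dataclass
class TLBRParams:
    """Trivalent-ligand / bivalent-receptor parameters.

    ``k_plus1`` is the single-site capture rate of a ligand free in
    solution, ``k_plus2`` the crosslinking rate of an already surface-bound
    ligand, ``k_off`` the per-bond dissociation rate (all in 1/s with the
    volume folded into the bimolecular constants).  The dimensionless
    crosslinking parameter ``beta = N_R * k_plus2 / k_off`` controls the
    equilibrium extent of receptor aggregation; the defaults sit well below
    the sol-gel transition.
    """

    N_L: int = 50
    N_R: int = 30
    k_plus1: float = 0.1
    k_plus2: float = 0.001
    k_off: float = 0.1

    @property
    def beta(self) -> float:
        return self.N_R * self.k_plus2 / self.k_off

    @classmethod
    def from_beta(cls, beta: float, N_L: int = 50, N_R: int = 30,
                  k_plus1: float = 0.1, k_off: float = 0.1) -> "TLBRParams":
        return cls(N_L=N_L, N_R=N_R, k_plus1=k_plus1,
                   k_plus2=beta * k_off / N_R, k_off=k_off)


def make_tlbr(params: TLBRParams | None = None, t_end: float = 50.0,
              n_report: int = 50) -> ModelSpec:
    """TLBR model: trivalent ligand L(s,s,s), bivalent receptor R(s,s).

    Free-ligand capture and crosslinking are both '+'-separated
    association rules (molecularity 2), and dissociation demands two
    products, so cyclic aggregates can neither form nor break — aggregates
    stay acyclic by construction.
    """
    p = params or TLBRParams()
    text = f"""
begin model
begin parameters
  N_L {p.N_L}
  N_R {p.N_R}
  kp1 {p.k_plus1!r}
  kp2 {p.k_plus2!r}
  koff {p.k_off!r}
end parameters
begin molecule types
  L(s,s,s)
  R(s,s)
end molecule types
begin species
  L(s,s,s) N_L
  R(s,s) N_R
end species
begin reaction rules
  capture: L(s,s,s) + R(s) -> L(s!1,s,s).R(s!1) kp1
  crosslink: L(s,s!+) + R(s) -> L(s!1,s!+).R(s!1) kp2
  unbind: L(s!1).R(s!1) -> L(s) + R(s) koff
end reaction rules
begin observables
  Molecules FreeL L(s,s,s)
  Molecules LRbonds R(s!+)
end observables
end model
simulate_rm({{t_end=>{t_end!r},n_steps=>{n_report}}});
"""
    return parse_model(text)


def make_multisite_phos(n_sites: int = 2, n_substrate: int = 100,
                        k_p: float = 1.0, k_d: float = 1.0,
                        t_end: float = 2.0, n_report: int = 10) -> ModelSpec:
    """One substrate with ``n_sites`` independent two-state sites and
    per-site phosphorylation/dephosphorylation state-change rules; the
    implied network has 2^n_sites species."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    comps = ",".join(f"s{i}~0~1" for i in range(1, n_sites + 1))
    seed = ",".join(f"s{i}~0" for i in range(1, n_sites + 1))
    rules = []
    obs = []
    for i in range(1, n_sites + 1):
        rules.append(f"  p{i}: S(s{i}~0) -> S(s{i}~1) kp")
        rules.append(f"  d{i}: S(s{i}~1) -> S(s{i}~0) kd")
        obs.append(f"  Molecules P{i} S(s{i}~1)")
    full = ",".join(f"s{i}~1" for i in range(1, n_sites + 1))
    obs.append(f"  Molecules Full S({full})")
    text = (
        "begin parameters\n"
        f"  n0 {n_substrate}\n  kp {k_p!r}\n  kd {k_d!r}\n"
        "end parameters\n"
        "begin molecule types\n"
        f"  S({comps})\n"
        "end molecule types\n"
        "begin species\n"
        f"  S({seed}) n0\n"
        "end species\n"
        "begin reaction rules\n" + "\n".join(rules) + "\n"
        "end reaction rules\n"
        "begin observables\n" + "\n".join(obs) + "\n"
        "end observables\n"
        f"simulate_rm({{t_end=>{t_end!r},n_steps=>{n_report}}});\n"
    )
    return parse_model(text)


def make_stiff(phi: float = 1e3, n0: int = 1000, k: float = 1.0,
               t_end: float = 10.0, n_report: int = 10) -> ModelSpec:
    """Two first-order state-change reactions on separate molecule types
    whose rate constants differ by the factor ``phi``."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    text = f"""
begin parameters
  n0 {n0}
  k {k!r}
  phi {phi!r}
end parameters
begin molecule types
  A(s~0~1)
  B(s~0~1)
end molecule types
begin species
  A(s~0) n0
  B(s~0) n0
end species
begin reaction rules
  fast: A(s~0) -> A(s~1) phi*k
  slow: B(s~0) -> B(s~1) k
end reaction rules
begin observables
  Molecules Afast A(s~1)
  Molecules Bslow B(s~1)
end observables
simulate_rm({{t_end=>{t_end!r},n_steps=>{n_report}}});
"""
    return parse_model(text)


def make_dimerization(k_plus: float = 0.1, k_minus: float = 1.0, n0: int = 20,
                      t_end: float = 5.0, n_report: int = 10) -> ModelSpec:
    """Symmetric A + A association (statistical factor 1/2) with two-product
    dissociation: initial association rate k_plus * n0 * (n0 - 1) / 2."""
    if n0 < 2:
        raise ValueError("n0 must be >= 2")
    text = f"""
begin parameters
  n0 {n0}
  kp {k_plus!r}
  km {k_minus!r}
end parameters
begin molecule types
  A(a)
end molecule types
begin species
  A(a) n0
end species
begin reaction rules
  dim: A(a) + A(a) -> A(a!1).A(a!1) kp
  undim: A(a!1).A(a!1) -> A(a) + A(a) km
end reaction rules
begin observables
  Molecules FreeA A(a)
  Species Dimer A(a!1).A(a!1)
end observables
simulate_rm({{t_end=>{t_end!r},n_steps=>{n_report}}});
"""
    return parse_model(text)


def make_decay(k: float = 1.0, n0: int = 100, t_end: float = 3.0,
               n_report: int = 10) -> ModelSpec:
    """Irreversible one-site state flip X(y~0) -> X(y~1): the mean of the
    unflipped count follows n0 * exp(-k t) exactly."""
    text = f"""
begin parameters
  n0 {n0}
  k {k!r}
end parameters
begin molecule types
  X(y~0~1)
end molecule types
begin species
  X(y~0) n0
end species
begin reaction rules
  decay: X(y~0) -> X(y~1) k
end reaction rules
begin observables
  Molecules X0 X(y~0)
  Molecules X1 X(y~1)
end observables
simulate_rm({{t_end=>{t_end!r},n_steps=>{n_report}}});
"""
    return parse_model(text)


def largest_aggregate_fraction(state: SystemState, molecule_name: str) -> float:
    """Fraction of all ``molecule_name`` molecules held by the single
    largest species instance (the percolation / sol-gel order parameter)."""
    total = 0
    largest = 0
    for sp in state.instances.values():
        n = sum(1 for m in sp.molecules if m.mtype.name == molecule_name)
        total += n
        largest = max(largest, n)
    if total == 0:
        raise ValueError(f"no molecules named '{molecule_name}' in the state")
    return largest / total
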