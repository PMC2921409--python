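"""Rejection-free, network-free kinetic Monte Carlo loop.

Every step executes exactly one reaction event: the waiting time is drawn
from Exponential(r_tot), a rule is selected by linear scan in proportion
to its cumulative rate, reactants are selected in proportion to their
distinct reaction-center counts, and the graph rewrite is applied.  Rule
rates and observable match numbers are maintained incrementally; the only
de-novo computation of a run happens at initialization.

Random deviates are consumed in a fixed order per event — waiting time,
rule, reactant(s), center(s) — so a fixed seed reproduces a trajectory
bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import (
    Rule,
    RuleActivity,
    RuleClass,
    Selection,
    StateDelta,
    apply_rule,
    assoc_center_lists,
    enumerate_instances,
)
from .graphs import (
    PatternGraph,
    SpeciesInstance,
    find_matches,
    instantiate_pattern,
    split_into_species,
)


class SystemState:
    """The complete component state of the system: every tracked species
    instance, the current time, and the event count."""

    def __init__(self, volume: float = 1.0) -> None:
        self.instances: dict[int, SpeciesInstance] = {}
        self.t = 0.0
        self.volume = volume
        self.event_count = 0
        self._next_sp_uid = 0
        self._next_mol_uid = 0

    def uid_source(self):
        while True:
            uid = self._next_sp_uid
            self._next_sp_uid += 1
            yield uid

    def mol_uid_source(self):
        while True:
            uid = self._next_mol_uid
            self._next_mol_uid += 1
            yield uid

    def add(self, sp: SpeciesInstance) -> None:
        self.instances[sp.uid] = sp

    def molecule_count(self, name: Optional[str] = None) -> int:
        n = 0
        for sp in self.instances.values():
            for m in sp.molecules:
                if name is None or m.mtype.name == name:
                    n += 1
        return n

    def validate(self) -> None:
        """Structural invariants: mutual bonds, connectivity, unique uids."""
        for uid, sp in self.instances.items():
            if sp.uid != uid:
                raise AssertionError("uid map inconsistent")
            parts = split_into_species(sp.molecules)
            if len(parts) != 1:
                raise AssertionError("species instance not connected")


@dataclass(frozen=True)
class ObservableDef:
    """A named pattern whose match number is reported over time.

    ``Molecules`` counts distinct images of the pattern across all species
    instances; ``Species`` counts the instances containing at least one
    image.
    """

    name: str
    obs_type: str                      # "Molecules" | "Species"
    patterns: tuple[PatternGraph, ...]

    def __post_init__(self) -> None:
        if self.obs_type not in ("Molecules", "Species"):
            raise ValueError(f"unknown observable type '{self.obs_type}'")


def _pattern_value(pattern: PatternGraph, sp: SpeciesInstance, count_images: bool) -> int:
    ms = find_matches(pattern, sp)
    if not count_images:
        return 1 if ms else 0
    images = set()
    for m in ms:
        images.add(frozenset((m.mols[mi].uid, tci) for (mi, _ci), tci in m.comps.items())
                   | frozenset(("mol", mol.uid) for mol in m.mols))
    return len(images)


def species_observable_value(obs: ObservableDef, sp: SpeciesInstance) -> int:
    return sum(_pattern_value(p, sp, obs.obs_type == "Molecules") for p in obs.patterns)


def eval_observable(obs: ObservableDef, state: SystemState) -> int:
    """Match number of ``obs`` against the full system state (Eq.-3 style
    de-novo evaluation; the tracker below maintains it incrementally)."""
    return sum(species_observable_value(obs, sp) for sp in state.instances.values())


class ObservableTracker:
    """Incrementally maintained observable match numbers."""

    def __init__(self, observables: Sequence[ObservableDef]) -> None:
        self.observables = list(observables)
        self._contrib: list[dict[int, int]] = [{} for _ in self.observables]
        self.totals: list[int] = [0] * len(self.observables)

    def initialize(self, state: SystemState) -> None:
        for sp in state.instances.values():
            self.add_species(sp)

    def add_species(self, sp: SpeciesInstance) -> None:
        for i, obs in enumerate(self.observables):
            v = species_observable_value(obs, sp)
            if v:
                self._contrib[i][sp.uid] = v
                self.totals[i] += v

    def remove_species(self, uid: int) -> None:
        for i in range(len(self.observables)):
            self.totals[i] -= self._contrib[i].pop(uid, 0)

    def apply_delta(self, delta: StateDelta) -> None:
        for uid in delta.removed:
            self.remove_species(uid)
        for sp in delta.added:
            self.add_species(sp)

    def values(self) -> tuple[int, ...]:
        return tuple(self.totals)


@dataclass
class SimulationConfig:
    t_end: float
    seed: int = 0
    n_report: int = 20
    report_times: Optional[Sequence[float]] = None
    max_events: Optional[int] = None

    def resolved_report_times(self) -> np.ndarray:
        if self.report_times is not None:
            times = np.asarray(self.report_times, dtype=float)
        else:
            times = np.linspace(0.0, self.t_end, self.n_report + 1)
        if np.any(np.diff(times) < 0) or (len(times) and
                                          (times[0] < 0 or times[-1] > self.t_end)):
            raise ValueError("report times must be sorted within [0, t_end]")
        return times


@dataclass
class Trajectory:
    times: np.ndarray
    values: np.ndarray                 # one row per report time
    names: list[str]
    event_count: int = 0
    truncated: bool = False            # max_events reached before t_end
    final_state: Optional[SystemState] = None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(model) -> tuple[SystemState, RuleActivity, ObservableTracker]:
    """Instantiate seed species as individual particle copies and compute
    every rule rate and observable match number de novo (the only de-novo
    pass of a run)."""
    state = SystemState()
    types = {mt.name: mt for mt in model.molecule_types}
    for pattern, count in model.seed_species:
        for _ in range(count):
            mols = instantiate_pattern(pattern, types, state.mol_uid_source())
            parts = split_into_species(mols, uids=state.uid_source())
            if len(parts) != 1:
                raise ValueError(
                    f"seed species expression is not a connected species graph")
            state.add(parts[0])
    activity = RuleActivity(model.rules)
    activity.initialize(state)
    tracker = ObservableTracker(model.observables)
    tracker.initialize(state)
    return state, activity, tracker


# ---------------------------------------------------------------------------
# elementary sampling operations
# ---------------------------------------------------------------------------

def sample_tau(r_tot: float, u: float) -> float:
    """Waiting time to the next event: Exponential(r_tot) via inversion."""
    if r_tot <= 0:
        raise ValueError("r_tot must be positive; no further events possible")
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    return math.log(1.0 / u) / r_tot


def select_rule(rates: Sequence[float], u: float) -> int:
    """Smallest index whose cumulative rate reaches u * r_tot (linear scan;
    zero-rate rules are never selected)."""
    total = float(np.sum(rates))
    if total <= 0:
        raise ValueError("all rule rates are zero")
    threshold = u * total
    cum = 0.0
    last_positive = -1
    for i, r in enumerate(rates):
        if r > 0:
            cum += r
            last_positive = i
            if cum >= threshold:
                return i
    return last_positive  # guard against float round-off at u -> 1


def _pick_weighted(pairs, total: int, u: float):
    """Pick a key from (key, integer weight) pairs with prob weight/total."""
    threshold = u * total
    cum = 0
    last = None
    for key, w in pairs:
        if w > 0:
            cum += w
            last = key
            if cum > threshold:
                return key
    if last is None:
        raise RuntimeError("inconsistent activity: no positive weight (bookkeeping bug)")
    return last


def select_reactants(rule: Rule, activity: RuleActivity, state: SystemState,
                     rng: np.random.Generator) -> Selection:
    """Select species instance(s) in proportion to distinct reaction-center
    counts, then center(s) uniformly.

    Association samples directly from the corrected pair distribution
    (instance pairs within one species excluded); there is no
    reject-and-redraw.
    """
    i = activity.rules.index(rule)
    if rule.rule_class is RuleClass.ASSOCIATION:
        v1, v2, V1, V2 = activity.assoc_counts(i)
        pairs1 = [(uid, w * (V2 - v2.get(uid, 0))) for uid, w in v1.items()]
        total1 = sum(w for _, w in pairs1)
        uid1 = _pick_weighted(pairs1, total1, rng.random())
        pairs2 = [(uid, w) for uid, w in v2.items() if uid != uid1]
        uid2 = _pick_weighted(pairs2, V2 - v2.get(uid1, 0), rng.random())
        sp1, sp2 = state.instances[uid1], state.instances[uid2]
        c1 = assoc_center_lists(rule, sp1)[0]
        c2 = assoc_center_lists(rule, sp2)[1]
        j1 = min(int(rng.random() * len(c1)), len(c1) - 1)
        j2 = min(int(rng.random() * len(c2)), len(c2) - 1)
        return Selection(species=(sp1, sp2), centers=(c1[j1], c2[j2]))
    weights = activity.weights(i)
    total = sum(weights.values())
    uid = _pick_weighted(weights.items(), total, rng.random())
    sp = state.instances[uid]
    instances = enumerate_instances(rule, sp)
    if not instances:
        raise RuntimeError("inconsistent activity: eligible count with no instances")
    j = min(int(rng.random() * len(instances)), len(instances) - 1)
    return Selection(species=(sp,), centers=instances[j])


# ---------------------------------------------------------------------------
# stepping and trajectories
# ---------------------------------------------------------------------------

def step(state: SystemState, activity: RuleActivity, tracker: ObservableTracker,
         rng: np.random.Generator) -> bool:
    """Execute exactly one reaction event (rejection-free).

    Returns False without consuming deviates when no event is possible.
    """
    rates = activity.rates()
    r_tot = float(rates.sum())
    if r_tot <= 0:
        return False
    u = rng.random()
    while u <= 0.0:
        u = rng.random()
    tau = sample_tau(r_tot, u)
    i = select_rule(rates, rng.random())
    rule = activity.rules[i]
    sel = select_reactants(rule, activity, state, rng)
    delta = apply_rule(rule, sel, state)
    activity.apply_delta(delta)
    tracker.apply_delta(delta)
    state.t += tau
    state.event_count += 1
    return True


def run(model, config: SimulationConfig) -> Trajectory:
    """Simulate ``model`` to ``config.t_end``, reporting observables on the
    requested grid.

    The value reported at a report time is the state at the last event
    time at or before it (the jump process is right-continuous and
    piecewise constant between events).
    """
    rng = np.random.default_rng(config.seed)
    state, activity, tracker = initialize(model)
    times = config.resolved_report_times()
    names = [o.name for o in tracker.observables]
    rows: list[tuple[int, ...]] = []
    k = 0
    truncated = False
    while True:
        rates = activity.rates()
        r_tot = float(rates.sum())
        if r_tot <= 0:
            break
        u = rng.random()
        while u <= 0.0:
            u = rng.random()
        tau = sample_tau(r_tot, u)
        t_next = state.t + tau
        if t_next > config.t_end:
            state.t = config.t_end
            break
        while k < len(times) and times[k] < t_next:
            rows.append(tracker.values())
            k += 1
        i = select_rule(rates, rng.random())
        rule = activity.rules[i]
        sel = select_reactants(rule, activity, state, rng)
        delta = apply_rule(rule, sel, state)
        activity.apply_delta(delta)
        tracker.apply_delta(delta)
        state.t = t_next
        state.event_count += 1
        if config.max_events is not None and state.event_count >= config.max_events:
            truncated = state.t < config.t_end
            break
    while k < len(times):
        rows.append(tracker.values())
        k += 1
    values = np.array(rows, dtype=float) if rows else np.zeros((0, len(names)))
    return Trajectory(times=times, values=values, names=names,
                      event_count=state.event_count, truncated=truncated,
                      final_state=state)
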