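"""The KMC loop: waiting times, selection, trajectories, observables."""

import math

import numpy as np
import pytest

import rulekmc.simulate as sim
from rulekmc.bngl import parse_model
from rulekmc.fixtures import make_decay, make_dimerization
from rulekmc.simulate import (
    SimulationConfig,
    eval_observable,
    initialize,
    run,
    sample_tau,
    select_rule,
)


def test_sample_tau_closed_form():
    assert sample_tau(2.0, math.exp(-2.0)) == pytest.approx(1.0)
    assert sample_tau(5.0, 1.0 - 1e-12) == pytest.approx(0.0, abs=1e-11)
    with pytest.raises(ValueError):
        sample_tau(0.0, 0.5)
    with pytest.raises(ValueError):
        sample_tau(1.0, 0.0)


def test_sample_tau_distribution_mean():
    rng = np.random.default_rng(11)
    n = 10 ** 5
    taus = np.array([sample_tau(5.0, u) for u in 1.0 - rng.random(n)])
    se = taus.std(ddof=1) / math.sqrt(n)
    assert abs(taus.mean() - 0.2) < 3 * se


def test_select_rule_arithmetic():
    # cumulative(1)=0.25 < 0.5 <= 1.0 -> second rule
    assert select_rule([1.0, 3.0], 0.5) == 1
    assert select_rule([1.0, 3.0], 0.2) == 0
    assert select_rule([0.0, 4.0], 1e-12) == 1          # zero-rate rule skipped
    assert select_rule([0.0, 4.0, 0.0], 0.999) == 1
    with pytest.raises(ValueError):
        select_rule([0.0, 0.0], 0.5)


def test_select_rule_frequencies():
    rng = np.random.default_rng(3)
    n = 10 ** 5
    picks = np.array([select_rule([1.0, 3.0], u) for u in rng.random(n)])
    p = picks.mean()
    se = math.sqrt(0.75 * 0.25 / n)
    assert abs(p - 0.75) < 3 * se


def test_select_reactants_proportional_to_centers():
    """Two species with 1 and 2 eligible centers: the first is chosen with
    probability 1/3."""
    model = parse_model("""
begin molecule types
  W(y~0~1,y~0~1)
end molecule types
begin species
  W(y~0,y~1) 1
  W(y~0,y~0) 1
end species
begin reaction rules
  flip: W(y~0) -> W(y~1) 1.0
end reaction rules
begin observables
  Molecules W0 W(y~0)
end observables
""")
    state, act, _ = initialize(model)
    rng = np.random.default_rng(17)
    rule = model.rules[0]
    uid_single = next(uid for uid, w in act.weights(0).items() if w == 1)
    n = 4000
    hits = sum(sim.select_reactants(rule, act, state, rng).species[0].uid == uid_single
               for _ in range(n))
    se = math.sqrt((1 / 3) * (2 / 3) / n)
    assert abs(hits / n - 1 / 3) < 3.5 * se


def test_single_eligible_center_deterministic():
    model = make_decay(n0=1)
    state, act, tracker = initialize(model)
    sel = sim.select_reactants(model.rules[0], act, state, np.random.default_rng(0))
    assert len(sel.centers) == 1
    assert sim.step(state, act, tracker, np.random.default_rng(0))
    assert not sim.step(state, act, tracker, np.random.default_rng(0))


def test_eval_observable_semantics():
    model = parse_model("""
begin molecule types
  A(a)
end molecule types
begin species
  A(a!1).A(a!1) 1
  A(a) 3
end species
begin reaction rules
  dim: A(a) + A(a) -> A(a!1).A(a!1) 0.0
end reaction rules
begin observables
  Molecules Atot A()
  Species Asp A()
  Molecules Free A(a)
end observables
""")
    state, _, tracker = initialize(model)
    vals = dict(zip([o.name for o in model.observables], tracker.values()))
    assert vals == {"Atot": 5, "Asp": 4, "Free": 3}
    for obs in model.observables:
        assert eval_observable(obs, state) == vals[obs.name]


def test_symmetric_pattern_counts_images_not_injections():
    """A pattern with two identical free sites has 2 injections per matching
    molecule but only 1 image: the match number counts images."""
    model = parse_model("""
begin molecule types
  R(s,s)
end molecule types
begin species
  R(s,s) 4
end species
begin reaction rules
end reaction rules
begin observables
  Molecules FreeR R(s,s)
end observables
""")
    _, _, tracker = initialize(model)
    assert tracker.values() == (4,)


def test_empty_seed_all_rates_zero():
    model = parse_model("""
begin molecule types
  X(y~0~1)
end molecule types
begin species
  X(y~0) 0
end species
begin reaction rules
  decay: X(y~0) -> X(y~1) 1.0
end reaction rules
begin observables
  Molecules X0 X(y~0)
end observables
""")
    state, act, tracker = initialize(model)
    assert act.r_tot() == 0.0
    traj = run(model, SimulationConfig(t_end=1.0, seed=1, n_report=4))
    assert np.all(traj.values == 0.0) and traj.event_count == 0


def test_rejection_free_event_count():
    """Every step is a real event: an irreversible n0-molecule decay executes
    exactly n0 events and then stops."""
    model = make_decay(n0=40, k=50.0)
    traj = run(model, SimulationConfig(t_end=1e3, seed=5, n_report=3))
    assert traj.event_count == 40
    assert traj.final_state.event_count == 40
    assert traj.values[-1].tolist() == [0.0, 40.0]


def test_decay_mean_matches_analytic():
    n0, k, t_obs = 50, 1.0, 1.0
    model = make_decay(n0=n0, k=k)
    finals = []
    for seed in range(200):
        traj = run(model, SimulationConfig(t_end=t_obs, seed=seed,
                                           report_times=[t_obs]))
        finals.append(traj.values[-1, 0])
    finals = np.array(finals)
    expected = n0 * math.exp(-k * t_obs)
    sem = finals.std(ddof=1) / math.sqrt(len(finals))
    assert abs(finals.mean() - expected) < 3 * sem


def test_determinism_same_seed():
    model = make_dimerization()
    cfg = SimulationConfig(t_end=3.0, seed=123, n_report=12)
    a = run(model, cfg)
    b = run(model, cfg)
    assert np.array_equal(a.values, b.values)
    assert a.event_count == b.event_count
    c = run(model, SimulationConfig(t_end=3.0, seed=124, n_report=12))
    assert not np.array_equal(a.values, c.values) or a.event_count != c.event_count


def test_report_grid_and_max_events():
    model = make_dimerization(n0=30)
    cfg = SimulationConfig(t_end=2.0, seed=9, n_report=8, max_events=5)
    traj = run(model, cfg)
    assert traj.truncated
    assert traj.event_count == 5
    assert len(traj.times) == 9
    assert traj.values.shape == (9, 2)
    with pytest.raises(ValueError):
        SimulationConfig(t_end=1.0, report_times=[0.5, 2.0]).resolved_report_times()
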