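import numpy as np
import pytest

from signalsim.agents import (
    BuildFlags,
    ItemPopulation,
    Receiver,
    Signaler,
    all_builds,
    forage,
    item_population_step,
    receiver_step,
    signaler_step,
)
from signalsim.engine import SimConfig, WorldState, initialize
from signalsim.world import Arena, Point, torus_distance

ARENA = Arena(500.0, 500.0)


def make_pop(xs, ys, ages=None, capacity=None, max_age=100, p=0.1, kind="food"):
    xs = np.asarray(xs, dtype=float)
    ages = np.zeros(len(xs), dtype=int) if ages is None else np.asarray(ages)
    return ItemPopulation(
        kind, ARENA, xs, np.asarray(ys, dtype=float), ages,
        capacity=len(xs) if capacity is None else capacity,
        max_age=max_age, reproduce_prob=p, neighborhood=10.0,
    )


def make_world(cfg, signalers=(), receivers=(), food=None, display=None):
    food = food if food is not None else make_pop([], [])
    return WorldState(ARENA, list(signalers), list(receivers), food, display)


def test_all_builds_enumerates_eight_unique_combinations():
    builds = all_builds()
    assert len(builds) == len(set(builds)) == 8


# ---- item population dynamics -----------------------------------------


def test_items_at_capacity_produce_no_births(rng):
    pop = make_pop(np.arange(10.0) * 30, np.arange(10.0) * 30, capacity=10, p=1.0)
    item_population_step(pop, rng)
    assert pop.size == 10 and pop.n_alive == 10


def test_item_reaching_max_age_dies(rng):
    pop = make_pop([100.0], [100.0], ages=[99], max_age=100, p=0.0)
    item_population_step(pop, rng)
    assert pop.size == 0 and pop.n_alive == 0


def test_item_births_match_binomial_expectation():
    # 1000 items, ample capacity, p=0.1: mean births over 200 trials within
    # 3 standard errors of 100
    births = []
    rng = np.random.default_rng(99)
    for _ in range(200):
        xy = rng.random((1000, 2)) * 500
        pop = make_pop(xy[:, 0], xy[:, 1], capacity=10_000, p=0.1)
        item_population_step(pop, rng)
        births.append(pop.size - 1000)
    se = np.sqrt(1000 * 0.1 * 0.9 / 200)
    assert abs(np.mean(births) - 100.0) < 3 * se


def test_item_population_never_exceeds_capacity(rng):
    xy = rng.random((50, 2)) * 500
    pop = make_pop(xy[:, 0], xy[:, 1], ages=rng.integers(0, 101, 50),
                   capacity=55, p=0.5)
    for _ in range(50):
        item_population_step(pop, rng)
        assert pop.n_alive <= 55


def test_newborns_enter_at_age_zero(rng):
    pop = make_pop([10.0] * 20, [10.0] * 20, ages=[50] * 20, capacity=100, p=1.0)
    item_population_step(pop, rng)
    assert pop.size == 40
    assert sorted(set(pop.age.tolist())) == [0, 51]


# ---- foraging ----------------------------------------------------------


def _cfg(**kw):
    # unit-step behavioral tests pin the energy scale to whole units
    defaults = dict(n_signalers=1, n_receivers=1, n_food_init=0, n_display_init=0,
                    step_cost=1.0, food_energy=50.0)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_forage_consumes_nearest_item(rng):
    cfg = _cfg(food_energy=50.0)
    food = make_pop([103.0, 108.0], [100.0, 100.0], p=0.0)  # distances 3 and 8
    w = make_world(cfg, food=food)
    agent = Signaler(0, Point(1, 1), 100.0, 100.0, energy=10.0)
    assert forage(agent, w, cfg, rng)
    assert agent.energy == 60.0
    assert (agent.x, agent.y) == (103.0, 100.0)
    assert food.n_alive == 1 and not food.alive[0] and food.alive[1]


def test_forage_at_exact_radius_is_inclusive(rng):
    cfg = _cfg()
    food = make_pop([110.0], [100.0], p=0.0)
    w = make_world(cfg, food=food)
    agent = Signaler(0, Point(1, 1), 100.0, 100.0, energy=10.0)
    assert forage(agent, w, cfg, rng)


def test_forage_without_food_moves_exactly_one_step(rng):
    cfg = _cfg(move_step=10.0)
    w = make_world(cfg)
    agent = Signaler(0, Point(1, 1), 100.0, 100.0, energy=10.0)
    assert not forage(agent, w, cfg, rng)
    assert torus_distance((agent.x, agent.y), (100.0, 100.0), ARENA) == pytest.approx(10.0)


# ---- signaler behavior -------------------------------------------------


def test_signaler_displays_at_home_when_energy_allows(rng):
    cfg = _cfg(energy_threshold=500.0, step_cost=1.0)
    w = make_world(cfg)
    s = Signaler(0, Point(50.0, 60.0), 200.0, 300.0, energy=600.0)
    signaler_step(s, w, BuildFlags(), cfg, rng)
    assert s.displaying and s.display_effort == 1
    assert (s.x, s.y) == (50.0, 60.0)
    assert s.energy == 599.0


def test_signaler_without_display_item_logs_lost_opportunity(rng):
    cfg = _cfg(energy_threshold=500.0)
    w = make_world(cfg, display=make_pop([], [], kind="display"))
    s = Signaler(0, Point(50.0, 60.0), 200.0, 300.0, energy=600.0)
    signaler_step(s, w, BuildFlags(items_needed=True), cfg, rng)
    assert not s.displaying and s.display_effort == 0
    assert w.lost_opportunities == 1
    assert (s.x, s.y) != (200.0, 300.0)  # moved randomly to keep searching


def test_signaler_with_display_item_consumes_it_and_displays(rng):
    cfg = _cfg(energy_threshold=500.0)
    disp = make_pop([205.0], [300.0], p=0.0, kind="display")
    w = make_world(cfg, display=disp)
    s = Signaler(0, Point(50.0, 60.0), 200.0, 300.0, energy=600.0)
    signaler_step(s, w, BuildFlags(items_needed=True), cfg, rng)
    assert s.displaying and s.display_effort == 1
    assert disp.n_alive == 0
    assert (s.x, s.y) == (50.0, 60.0)
    assert w.lost_opportunities == 0


def test_hungry_signaler_forages_instead_of_displaying(rng):
    cfg = _cfg(energy_threshold=500.0, food_energy=50.0, step_cost=1.0)
    food = make_pop([105.0], [100.0], p=0.0)
    w = make_world(cfg, food=food)
    s = Signaler(0, Point(50.0, 60.0), 100.0, 100.0, energy=100.0)
    signaler_step(s, w, BuildFlags(), cfg, rng)
    assert not s.displaying and s.display_effort == 0
    assert s.energy == 149.0  # +food_energy - step_cost
    assert food.n_alive == 0


def test_signaler_energy_floors_at_zero(rng):
    cfg = _cfg(energy_threshold=500.0, step_cost=5.0)
    w = make_world(cfg)
    s = Signaler(0, Point(1, 1), 0.0, 0.0, energy=2.0)
    signaler_step(s, w, BuildFlags(), cfg, rng)
    assert s.energy == 0.0


# ---- receiver behavior -------------------------------------------------


def _receiver(n_signalers=3, energy=600.0, tour=None):
    return Receiver(
        10.0, 10.0, energy,
        estimates=np.zeros(n_signalers),
        tour=None if tour is None else np.asarray(tour),
    )


def _displaying_signaler(i, effort=0):
    home = Point(50.0 * (i + 1), 60.0)
    s = Signaler(i, home, home.x, home.y, energy=600.0,
                 display_effort=effort, displaying=True)
    return s


def test_lek_realtime_counts_each_displaying_signaler(rng):
    cfg = _cfg(n_signalers=3)
    sigs = [_displaying_signaler(i, effort=5) for i in range(3)]
    sigs[1].displaying = False
    r = _receiver()
    w = make_world(cfg, signalers=sigs, receivers=[r])
    receiver_step(r, w, BuildFlags(realtime_only=True), cfg, rng)
    assert r.estimates.tolist() == [1.0, 0.0, 1.0]
    assert (r.x, r.y) == tuple(ARENA.center)


def test_lek_cumulative_reads_display_record(rng):
    cfg = _cfg(n_signalers=3)
    sigs = [_displaying_signaler(i, effort=10 * (i + 1)) for i in range(3)]
    r = _receiver()
    w = make_world(cfg, signalers=sigs, receivers=[r])
    receiver_step(r, w, BuildFlags(), cfg, rng)
    assert r.estimates.tolist() == [10.0, 20.0, 30.0]


def test_sequential_cumulative_reads_current_territory_then_advances(rng):
    cfg = _cfg(n_signalers=3)
    sigs = [_displaying_signaler(i, effort=37) for i in range(3)]
    r = _receiver(tour=[2, 0, 1])
    w = make_world(cfg, signalers=sigs, receivers=[r])
    receiver_step(r, w, BuildFlags(sequential_assessment=True), cfg, rng)
    assert r.estimates.tolist() == [0.0, 0.0, 37.0]
    assert r.tour_pos == 1
    assert (r.x, r.y) == tuple(sigs[2].home)


def test_sequential_visit_to_absent_signaler_updates_nothing(rng):
    cfg = _cfg(n_signalers=3)
    sigs = [_displaying_signaler(i) for i in range(3)]
    sigs[2].displaying = False  # off foraging
    r = _receiver(tour=[2, 0, 1])
    w = make_world(cfg, signalers=sigs, receivers=[r])
    receiver_step(r, w, BuildFlags(sequential_assessment=True), cfg, rng)
    assert r.estimates.tolist() == [0.0, 0.0, 0.0]
    assert r.tour_pos == 1  # the tour still advances


def test_hungry_receiver_forages_and_does_not_observe(rng):
    cfg = _cfg(n_signalers=3, food_energy=50.0)
    sigs = [_displaying_signaler(i) for i in range(3)]
    food = make_pop([12.0], [10.0], p=0.0)
    r = _receiver(energy=100.0)
    w = make_world(cfg, signalers=sigs, receivers=[r], food=food)
    receiver_step(r, w, BuildFlags(), cfg, rng)
    assert r.estimates.tolist() == [0.0, 0.0, 0.0]
    assert r.energy == 149.0


# ---- run-level invariants ---------------------------------------------


def test_cumulative_estimates_never_exceed_current_effort(small_config):
    from signalsim.engine import run

    res = run(small_config.replace(flags=BuildFlags(items_needed=True)))
    assert np.all(res.estimates <= res.true_efforts[None, :])
    assert np.all(res.estimates >= 0)


def test_lost_opportunities_only_with_items_needed(small_config):
    from signalsim.engine import run

    res = run(small_config)  # items not needed
    assert res.lost_opportunities == 0
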