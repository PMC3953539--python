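"""Run configuration, world initialization, and the scheduler.

A run advances a fixed world for ``n_steps`` discrete time steps. Within a
step a single uniformly random permutation is drawn over *all* entities --
signalers, receivers, food items, and (in item-needed builds) display items
-- and each entity executes its behavior at its slot, so no agent class has
a systematic ordering advantage. A signaler's display flag is set by its own
action (true iff that action was a display) and persists until its next
action, so whether a receiver registers a given display never depends on the
draw of the within-step ordering; a signaler that switches to foraging
clears its flag at that action and is never registered while searching for
food.

Randomness is organized as named substreams spawned from the single run
seed (placement, energies, scheduling, item births, movement headings,
receiver tours), so individual components can be frozen or replayed in
tests without disturbing the others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .agents import (
    BuildFlags,
    ItemPopulation,
    Receiver,
    Signaler,
    receiver_step,
    signaler_step,
)
from .world import Arena, Point

_STREAMS = ("placement", "energies", "scheduling", "births", "headings", "tours")


class ConfigError(ValueError):
    """An invalid run configuration; the message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of one run.

    Energy is in arbitrary units; lengths are in arena length units. The
    defaults reproduce the standard study conditions: a 500x500 toroid, 20
    signalers with unique home territories, 20 receivers, 1440 time steps,
    perception neighborhood 10, display threshold 500, initial energies
    drawn uniformly on the integers 0..1000, and 10% capacity-gated item
    reproduction with item ages initialized uniformly on 0..100.

    ``step_cost``, ``food_energy`` and ``move_step`` are free parameters of
    the energy budget (see docs/methods.md for their calibration): by
    default each time step costs 0.35 energy units -- so the 0..1000
    initial-energy heterogeneity persists across a full 1440-step run --
    a food item is worth 1 energy unit (roughly three further steps), and
    an undirected search move covers one neighborhood radius.
    """

    n_signalers: int = 20
    n_receivers: int = 20
    arena_side: float = 500.0
    n_steps: int = 1440
    neighborhood: float = 10.0
    energy_threshold: float = 500.0
    init_energy_max: int = 1000
    n_food_init: int = 2500
    n_display_init: int = 2500
    reproduce_prob: float = 0.10
    max_age: int = 100
    step_cost: float = 0.35
    food_energy: float = 1.0
    move_step: float = 10.0
    food_capacity: Optional[int] = None  # defaults to n_food_init
    display_capacity: Optional[int] = None  # defaults to n_display_init
    flags: BuildFlags = field(default_factory=BuildFlags)
    seed: int = 0
    # explicit initial-energy overrides for controlled experiments; when
    # given they replace the random 0..init_energy_max draw
    signaler_energies: Optional[tuple[float, ...]] = None
    receiver_energies: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        for name in ("n_signalers", "n_receivers", "n_steps"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("n_food_init", "n_display_init", "init_energy_max", "max_age"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0.0 <= self.reproduce_prob <= 1.0):
            raise ConfigError("reproduce_prob must lie in [0, 1]")
        for name in ("arena_side", "step_cost", "move_step"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.arena_side <= 0:
            raise ConfigError("arena_side must be positive")
        if self.neighborhood < 0:
            raise ConfigError("neighborhood must be non-negative")
        for name in ("signaler_energies", "receiver_energies"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, tuple(float(v) for v in val))
                n = self.n_signalers if name == "signaler_energies" else self.n_receivers
                if len(getattr(self, name)) != n:
                    raise ConfigError(f"{name} must have one entry per agent")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = dataclasses.asdict(self.flags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        flags = d.pop("flags", {})
        if not isinstance(flags, BuildFlags):
            flags = BuildFlags(**flags)
        return cls(flags=flags, **d)


def home_grid(n: int, arena: Arena) -> list[Point]:
    """Evenly spaced home territories on a near-square grid (row-major).

    20 territories on the default square arena land on a 5x4 grid, so every
    signaler has a unique, collision-free home location.
    """
    cols = max(1, math.ceil(math.sqrt(n)))
    rows = max(1, math.ceil(n / cols))
    pts = []
    for k in range(n):
        i, j = k % cols, k // cols
        pts.append(
            Point((i + 0.5) * arena.width / cols, (j + 0.5) * arena.height / rows)
        )
    return pts


class WorldState:
    """The full mutable state of one run."""

    def __init__(
        self,
        arena: Arena,
        signalers: list[Signaler],
        receivers: list[Receiver],
        food: ItemPopulation,
        display_items: Optional[ItemPopulation],
    ) -> None:
        self.arena = arena
        self.signalers = signalers
        self.receivers = receivers
        self.food = food
        self.display_items = display_items
        self.t = 0
        self.lost_opportunities = 0


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def initialize(config: SimConfig) -> tuple[WorldState, dict[str, np.random.Generator]]:
    """Build the t=0 world: random placement, random integer energies.

    Mobile agents land uniformly at random; initial energies are integer
    draws on ``[0, init_energy_max]``; items get integer ages on ``[0, 100]``.
    In builds that do not require display items the display-item population
    is not instantiated at all.
    """
    rngs = _rng_streams(config.seed)
    arena = Arena(config.arena_side, config.arena_side)
    place, energies = rngs["placement"], rngs["energies"]

    homes = home_grid(config.n_signalers, arena)
    sig_xy = place.random((config.n_signalers, 2)) * config.arena_side
    sig_e = energies.integers(0, config.init_energy_max + 1, size=config.n_signalers)
    if config.signaler_energies is not None:
        sig_e = np.asarray(config.signaler_energies)
    signalers = [
        Signaler(i, homes[i], float(sig_xy[i, 0]), float(sig_xy[i, 1]), float(sig_e[i]))
        for i in range(config.n_signalers)
    ]

    rec_xy = place.random((config.n_receivers, 2)) * config.arena_side
    rec_e = energies.integers(0, config.init_energy_max + 1, size=config.n_receivers)
    if config.receiver_energies is not None:
        rec_e = np.asarray(config.receiver_energies)
    receivers = []
    for i in range(config.n_receivers):
        tour = None
        if config.flags.sequential_assessment:
            tour = rngs["tours"].permutation(config.n_signalers)
        receivers.append(
            Receiver(
                float(rec_xy[i, 0]),
                float(rec_xy[i, 1]),
                float(rec_e[i]),
                estimates=np.zeros(config.n_signalers, dtype=np.float64),
                tour=tour,
            )
        )

    def make_pop(kind: str, n: int, capacity: Optional[int]) -> ItemPopulation:
        xy = place.random((n, 2)) * config.arena_side
        ages = place.integers(0, 101, size=n)
        return ItemPopulation(
            kind,
            arena,
            xy[:, 0],
            xy[:, 1],
            ages,
            capacity=n if capacity is None else capacity,
            max_age=config.max_age,
            reproduce_prob=config.reproduce_prob,
            neighborhood=config.neighborhood,
        )

    food = make_pop("food", config.n_food_init, config.food_capacity)
    display = (
        make_pop("display", config.n_display_init, config.display_capacity)
        if config.flags.items_needed
        else None
    )
    return WorldState(arena, signalers, receivers, food, display), rngs


def step(
    world: WorldState,
    config: SimConfig,
    rngs: dict[str, np.random.Generator],
) -> None:
    """Advance the world by one time step under random entity ordering."""
    ns, nr = len(world.signalers), len(world.receivers)
    n_mobile = ns + nr
    world.food.begin_step()
    nf = world.food.size
    nd = 0
    if world.display_items is not None:
        world.display_items.begin_step()
        nd = world.display_items.size

    perm = rngs["scheduling"].permutation(n_mobile + nf + nd)
    u_f = rngs["births"].random(nf)
    u_d = rngs["births"].random(nd) if nd else np.empty(0)

    from ._kernels import scan_item_segment  # local alias for the hot loop

    mobile_pos = np.flatnonzero(perm < n_mobile)
    heads = rngs["headings"]
    births_rng = rngs["births"]
    disp = world.display_items

    def run_items(a: int, b: int) -> None:
        if a >= b:
            return
        seg = perm[a:b]
        if disp is not None:
            pf, bf, pd, bd = scan_item_segment(
                seg, n_mobile, nf,
                world.food.age, world.food.alive, u_f,
                world.food.n_alive, world.food.capacity,
                world.food.max_age, world.food.reproduce_prob,
                disp.age, disp.alive, u_d,
                disp.n_alive, disp.capacity, disp.max_age, disp.reproduce_prob,
            )
        else:
            pf, bf, pd, bd = scan_item_segment(
                seg, n_mobile, nf,
                world.food.age, world.food.alive, u_f,
                world.food.n_alive, world.food.capacity,
                world.food.max_age, world.food.reproduce_prob,
                _EMPTY_I8, _EMPTY_B, _EMPTY_F8, 0, 0, 0, 0.0,
            )
        world.food.n_alive = int(pf)
        if bf:
            locs = births_rng.random((bf, 2)) * config.arena_side
            world.food.add_newborns(locs[:, 0], locs[:, 1])
        if disp is not None:
            disp.n_alive = int(pd)
            if bd:
                locs = births_rng.random((bd, 2)) * config.arena_side
                disp.add_newborns(locs[:, 0], locs[:, 1])

    prev = 0
    for pos in mobile_pos:
        run_items(prev, int(pos))
        v = int(perm[pos])
        if v < ns:
            signaler_step(world.signalers[v], world, config.flags, config, heads)
        else:
            receiver_step(world.receivers[v - ns], world, config.flags, config, heads)
        prev = int(pos) + 1
    run_items(prev, perm.size)

    world.food.end_step()
    if disp is not None:
        disp.end_step()
    world.t += 1


_EMPTY_I8 = np.empty(0, dtype=np.int64)
_EMPTY_F8 = np.empty(0, dtype=np.float64)
_EMPTY_B = np.empty(0, dtype=np.bool_)


@dataclass
class RunResult:
    """Final outcome of one run: the rating table plus run metadata.

    ``true_efforts[i]`` is signaler ``i``'s cumulative display-step count;
    ``estimates[r, i]`` is receiver ``r``'s final estimate for signaler
    ``i``. Serialized as a CSV with one row per signaler and columns
    ``true_effort, receiver_00, ...`` (the n x (n_receivers + 1) table),
    plus a JSON sidecar with the configuration echo.
    """

    true_efforts: np.ndarray
    estimates: np.ndarray
    lost_opportunities: int
    config: SimConfig
    seed: int

    def rating_table(self) -> np.ndarray:
        """Judges-by-signalers score matrix: true efforts, then receivers."""
        return np.vstack([self.true_efforts[None, :].astype(float), self.estimates])

    def to_frame(self):
        import pandas as pd

        cols = {"true_effort": self.true_efforts}
        for r in range(self.estimates.shape[0]):
            cols[f"receiver_{r:02d}"] = self.estimates[r]
        return pd.DataFrame(cols)

    def save(self, directory: str | Path, stem: str = "run") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}_ratings.csv", index=False)
        meta = {
            "seed": int(self.seed),
            "lost_opportunities": int(self.lost_opportunities),
            "config": self.config.to_dict(),
        }
        (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def run(config: SimConfig) -> RunResult:
    """Initialize a world and advance it through all time steps."""
    world, rngs = initialize(config)
    for _ in range(config.n_steps):
        step(world, config, rngs)
    return RunResult(
        true_efforts=np.array([s.display_effort for s in world.signalers], dtype=np.int64),
        estimates=np.vstack([r.estimates for r in world.receivers])
        if world.receivers
        else np.zeros((0, config.n_signalers)),
        lost_opportunities=world.lost_opportunities,
        config=config,
        seed=config.seed,
    )
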