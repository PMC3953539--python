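"""Agent state and per-step behavior for the four agent kinds.

Signalers advertise a generic display trait whenever their energy reserves
allow it (optionally only after securing an external display item); receivers
build per-signaler estimates of display effort under one of two assessment
regimes (lek vs. sequential territory visits) and one of two observation
regimes (real-time counting vs. reading a cumulative record). Food and
display items are non-mobile resources with age-limited lifespans and
capacity-gated reproduction.

Behavioral rules shared by mobile agents:

* An agent below the energy threshold forages: it consumes the nearest food
  item within its perception neighborhood (moving onto it), or moves one
  step along a uniform-random heading when no food is perceptible.
* Every agent pays the same energy cost per time step whether it displays,
  observes, or forages; energy is floored at zero and agents never die.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from . import _kernels
from .world import Arena, Point, grid_geometry, neighbor_cell_table, torus_distance

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimConfig, WorldState

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class BuildFlags:
    """The three binary design axes spanning the eight model builds.

    items_needed
        Signalers must secure an external display item (e.g. a twig) before
        they can display.
    sequential_assessment
        Receivers visit one signaler territory per time step instead of
        observing every displaying signaler at once (lek).
    realtime_only
        Receivers count displays as they happen (+1 per witnessed display
        step) instead of reading the signaler's cumulative display record.
    """

    items_needed: bool = False
    sequential_assessment: bool = False
    realtime_only: bool = False


def all_builds() -> list[BuildFlags]:
    """The eight factorial combinations, in lexicographic flag order."""
    return [
        BuildFlags(bool(i), bool(s), bool(r))
        for i in (0, 1)
        for s in (0, 1)
        for r in (0, 1)
    ]


@dataclass
class Signaler:
    id: int
    home: Point
    x: float
    y: float
    energy: float
    display_effort: int = 0
    displaying: bool = False

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class Receiver:
    x: float
    y: float
    energy: float
    estimates: np.ndarray  # one non-negative entry per signaler id
    tour: Optional[np.ndarray] = None  # territory visit order (sequential builds)
    tour_pos: int = 0

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class ResourceItem:
    """Boundary representation of a single food or display item."""

    kind: str  # "food" | "display"
    location: Point
    age: int = 0


class ItemPopulation:
    """A resource-item population stored as flat arrays with a grid index.

    Per time step the engine calls :meth:`begin_step` (rebuild the spatial
    index over the items alive at the step boundary), then advances scheduled
    slices via :meth:`scan_segment` interleaved with mobile-agent actions
    (which may :meth:`consume` items), and finally :meth:`end_step` (drop the
    dead, append the step's newborns at age 0). Newborns are placed uniformly
    at random, become visible to agents acting later in the same step, and
    count toward carrying capacity immediately, but do not act until the next
    step.
    """

    def __init__(
        self,
        kind: str,
        arena: Arena,
        xs: np.ndarray,
        ys: np.ndarray,
        ages: np.ndarray,
        capacity: int,
        max_age: int,
        reproduce_prob: float,
        neighborhood: float,
    ) -> None:
        self.kind = kind
        self.arena = arena
        self.x = np.asarray(xs, dtype=np.float64)
        self.y = np.asarray(ys, dtype=np.float64)
        self.age = np.asarray(ages, dtype=np.int64)
        self.alive = np.ones(self.x.size, dtype=np.bool_)
        self.capacity = int(capacity)
        self.max_age = int(max_age)
        self.reproduce_prob = float(reproduce_prob)
        self.n_alive = int(self.x.size)
        # newborn buffers for the step in progress (amortized growth)
        self._new_x = np.empty(64, dtype=np.float64)
        self._new_y = np.empty(64, dtype=np.float64)
        self._new_alive = np.empty(64, dtype=np.bool_)
        self._n_new = 0
        # spatial index geometry is fixed for the run
        nx, ny, cw, ch = grid_geometry(arena, neighborhood)
        self._nx, self._ny, self._cw, self._ch = nx, ny, cw, ch
        self._neighbor_cells = neighbor_cell_table(nx, ny)
        self._sorted_idx = np.empty(0, dtype=np.int64)
        self._cell_starts = np.zeros(nx * ny + 1, dtype=np.int64)
        self.begin_step()

    # -- step lifecycle -------------------------------------------------

    @property
    def size(self) -> int:
        """Number of scheduler slots this population occupies this step."""
        return int(self.x.size)

    def begin_step(self) -> None:
        cx = np.minimum((self.x / self._cw).astype(np.int64), self._nx - 1)
        cy = np.minimum((self.y / self._ch).astype(np.int64), self._ny - 1)
        cid = cx * self._ny + cy
        self._sorted_idx, self._cell_starts = _kernels.grid_sort(
            cid, self._nx * self._ny
        )

    def scan_segment(self, seg_idx: np.ndarray, u: np.ndarray) -> int:
        """Advance the items whose indices appear in ``seg_idx`` (in order).

        ``u`` holds one uniform draw per item index for this step. Returns
        the number of births; the caller supplies newborn locations via
        :meth:`add_newborns`.
        """
        pop, births, _, _ = _kernels.scan_item_segment(
            seg_idx,
            0,
            self.size,
            self.age,
            self.alive,
            u,
            self.n_alive,
            self.capacity,
            self.max_age,
            self.reproduce_prob,
            _EMPTY_I8,
            _EMPTY_B,
            _EMPTY_F8,
            0,
            0,
            0,
            0.0,
        )
        self.n_alive = int(pop)
        return int(births)

    def add_newborns(self, xs: np.ndarray, ys: np.ndarray) -> None:
        k = len(xs)
        need = self._n_new + k
        if need > self._new_x.size:
            cap = max(need, 2 * self._new_x.size)
            for name in ("_new_x", "_new_y", "_new_alive"):
                buf = getattr(self, name)
                grown = np.empty(cap, dtype=buf.dtype)
                grown[: self._n_new] = buf[: self._n_new]
                setattr(self, name, grown)
        self._new_x[self._n_new : need] = xs
        self._new_y[self._n_new : need] = ys
        self._new_alive[self._n_new : need] = True
        self._n_new = need

    def end_step(self) -> None:
        keep = self.alive
        pend_keep = self._new_alive[: self._n_new].copy()
        self.x = np.concatenate([self.x[keep], self._new_x[: self._n_new][pend_keep]])
        self.y = np.concatenate([self.y[keep], self._new_y[: self._n_new][pend_keep]])
        self.age = np.concatenate(
            [self.age[keep], np.zeros(int(pend_keep.sum()), dtype=np.int64)]
        )
        self.alive = np.ones(self.x.size, dtype=np.bool_)
        self._n_new = 0
        assert self.x.size == self.n_alive

    # -- queries and consumption ---------------------------------------

    def nearest_within(self, px: float, py: float, radius: float) -> Optional[int]:
        """Index of the nearest live item within ``radius`` (inclusive).

        Ties break to the lowest index; newborn items sort after the main
        array. Returns ``None`` when nothing is in range.
        """
        c = min(int(px / self._cw), self._nx - 1) * self._ny + min(
            int(py / self._ch), self._ny - 1
        )
        best, best_d2 = _kernels.nearest_in_grid(
            px,
            py,
            self.x,
            self.y,
            self.alive,
            self._sorted_idx,
            self._cell_starts,
            self._neighbor_cells[c],
            radius,
            self.arena.width,
            self.arena.height,
        )
        n_new = self._n_new
        if n_new:
            nb, nb_d2 = _kernels.nearest_in_arrays(
                px,
                py,
                self._new_x,
                self._new_y,
                self._new_alive,
                n_new,
                radius,
                self.arena.width,
                self.arena.height,
            )
            if nb >= 0 and (best < 0 or nb_d2 < best_d2):
                return self.size + nb
        return None if best < 0 else int(best)

    def location_of(self, idx: int) -> Point:
        if idx >= self.size:
            k = idx - self.size
            return Point(float(self._new_x[k]), float(self._new_y[k]))
        return Point(float(self.x[idx]), float(self.y[idx]))

    def consume(self, idx: int) -> None:
        """Remove one item from the landscape (exactly once)."""
        if idx >= self.size:
            k = idx - self.size
            if not self._new_alive[k]:
                raise ValueError("item already consumed")
            self._new_alive[k] = False
        else:
            if not self.alive[idx]:
                raise ValueError("item already consumed")
            self.alive[idx] = False
        self.n_alive -= 1

    # -- conversion helpers (tests, I/O) --------------------------------

    def to_items(self) -> list[ResourceItem]:
        return [
            ResourceItem(self.kind, Point(float(x), float(y)), int(a))
            for x, y, a, ok in zip(self.x, self.y, self.age, self.alive)
            if ok
        ]


_EMPTY_I8 = np.empty(0, dtype=np.int64)
_EMPTY_F8 = np.empty(0, dtype=np.float64)
_EMPTY_B = np.empty(0, dtype=np.bool_)


def item_population_step(
    pop: ItemPopulation,
    rng: np.random.Generator,
    order: Optional[np.ndarray] = None,
) -> None:
    """Advance a whole item population by one time step.

    Equivalent to scheduling every item of ``pop`` consecutively (in
    ``order``, defaulting to storage order): each item ages, dies on reaching
    the maximum age, and otherwise reproduces with the population's birth
    probability while the population is below carrying capacity. Newborns
    land uniformly at random and enter at age 0.
    """
    pop.begin_step()
    if order is None:
        order = np.arange(pop.size, dtype=np.int64)
    u = rng.random(pop.size)
    births = pop.scan_segment(np.asarray(order, dtype=np.int64), u)
    if births:
        locs = rng.random((births, 2))
        pop.add_newborns(locs[:, 0] * pop.arena.width, locs[:, 1] * pop.arena.height)
    pop.end_step()


# -- mobile-agent behaviors ---------------------------------------------


def random_move(agent, cfg: "SimConfig", arena: Arena, rng: np.random.Generator) -> None:
    """Move ``move_step`` units along a uniform-random heading (wrapped)."""
    theta = rng.random() * TWO_PI
    agent.x = (agent.x + cfg.move_step * math.cos(theta)) % arena.width
    agent.y = (agent.y + cfg.move_step * math.sin(theta)) % arena.height


def forage(agent, world: "WorldState", cfg: "SimConfig", rng: np.random.Generator) -> bool:
    """Search the neighborhood for food; eat the nearest item or move randomly.

    On success the agent moves onto the item, the item leaves the landscape,
    and the agent gains ``food_energy``. Returns True when food was eaten.
    """
    hit = world.food.nearest_within(agent.x, agent.y, cfg.neighborhood)
    if hit is None:
        random_move(agent, cfg, world.arena, rng)
        return False
    agent.x, agent.y = world.food.location_of(hit)
    world.food.consume(hit)
    agent.energy += cfg.food_energy
    return True


def signaler_step(
    s: Signaler,
    world: "WorldState",
    flags: BuildFlags,
    cfg: "SimConfig",
    rng: np.random.Generator,
) -> None:
    """One signaler action.

    With sufficient energy the signaler displays at its home territory
    (display is dichotomous; surplus energy does not change it). In
    item-needed builds the display first requires a display item within the
    perception neighborhood; the item is consumed, and failing to find one
    is logged as a lost signaling opportunity. Below the threshold the
    signaler forages instead. Display costs the same energy as any other
    time step.
    """
    if s.energy >= cfg.energy_threshold:
        can_display = True
        if flags.items_needed:
            hit = world.display_items.nearest_within(s.x, s.y, cfg.neighborhood)
            if hit is None:
                can_display = False
                world.lost_opportunities += 1
                random_move(s, cfg, world.arena, rng)
        if can_display:
            if flags.items_needed:
                world.display_items.consume(hit)
            s.x, s.y = s.home
            s.display_effort += 1
        s.displaying = can_display
    else:
        s.displaying = False
        forage(s, world, cfg, rng)
    s.energy = max(0.0, s.energy - cfg.step_cost)


def _observe(r: Receiver, s: Signaler, realtime_only: bool) -> None:
    if realtime_only:
        r.estimates[s.id] += 1
    else:
        r.estimates[s.id] = s.display_effort


def receiver_step(
    r: Receiver,
    world: "WorldState",
    flags: BuildFlags,
    cfg: "SimConfig",
    rng: np.random.Generator,
) -> None:
    """One receiver action.

    With sufficient energy the receiver observes: under the lek regime it
    moves to the arena center and registers every signaler whose display
    flag is set (i.e. whose most recent action was a display -- foragers are
    never registered); under sequential assessment it inspects the single
    territory at its current tour position, registers the resident only if
    that signaler is displaying on its territory, and then moves on to the
    next territory on its circuit. Real-time observation increments the
    estimate by one per witnessed
    display; cumulative observation copies the signaler's current display
    record. Below the threshold the receiver forages and observes nothing.
    """
    if r.energy < cfg.energy_threshold:
        forage(r, world, cfg, rng)
    elif flags.sequential_assessment:
        s = world.signalers[int(r.tour[r.tour_pos])]
        r.x, r.y = s.home
        if s.displaying and torus_distance(s.location, s.home, world.arena) <= cfg.neighborhood:
            _observe(r, s, flags.realtime_only)
        r.tour_pos = (r.tour_pos + 1) % len(r.tour)
    else:
        r.x, r.y = world.arena.center
        for s in world.signalers:
            if s.displaying:
                _observe(r, s, flags.realtime_only)
    r.energy = max(0.0, r.energy - cfg.step_cost)
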