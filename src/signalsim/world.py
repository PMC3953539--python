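"""Continuous toroidal arena: wrapping, distances, placement, neighborhoods.

The simulation arena is a rectangular region with periodic (wraparound)
boundaries, so every location is topologically equivalent and there are no
edge effects on foraging or display. Coordinates are continuous floats; the
model does not use a lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class Point(NamedTuple):
    """A location in the arena, wrapped into ``[0, side)`` on both axes."""

    x: float
    y: float


@dataclass(frozen=True)
class Arena:
    """Toroidal rectangle of ``width`` x ``height`` length units."""

    width: float = 500.0
    height: float = 500.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")

    @property
    def center(self) -> Point:
        return Point(self.width / 2.0, self.height / 2.0)

    def wrap(self, x: float, y: float) -> Point:
        """Wrap arbitrary coordinates into the arena. Idempotent."""
        return Point(x % self.width, y % self.height)

    def wrap_point(self, p: Point | tuple[float, float]) -> Point:
        return self.wrap(p[0], p[1])


def torus_distance(a: Sequence[float], b: Sequence[float], arena: Arena) -> float:
    """Euclidean distance between two points under wraparound boundaries.

    Symmetric, and never larger than ``sqrt((w/2)**2 + (h/2)**2)``.
    """
    dx = abs(a[0] - b[0]) % arena.width
    dy = abs(a[1] - b[1]) % arena.height
    if dx > arena.width / 2.0:
        dx = arena.width - dx
    if dy > arena.height / 2.0:
        dy = arena.height - dy
    return float(np.hypot(dx, dy))


def torus_distance_sq_arrays(
    px: float,
    py: float,
    xs: np.ndarray,
    ys: np.ndarray,
    arena: Arena,
) -> np.ndarray:
    """Squared toroidal distances from one point to arrays of coordinates."""
    dx = np.abs(xs - px) % arena.width
    dy = np.abs(ys - py) % arena.height
    np.minimum(dx, arena.width - dx, out=dx)
    np.minimum(dy, arena.height - dy, out=dy)
    return dx * dx + dy * dy


def neighbors_within(
    items: Iterable,
    center: Sequence[float],
    radius: float,
    arena: Arena,
) -> list:
    """All entities whose location lies within ``radius`` of ``center``.

    The boundary is inclusive (distance <= radius). Entities must expose a
    ``location`` attribute (anything indexable as ``(x, y)``). Order follows
    the input order. This is the exact linear-scan contract; the engine uses
    an equivalent grid-binned index internally.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    out = []
    for it in items:
        if torus_distance(it.location, center, arena) <= radius:
            out.append(it)
    return out


def random_point(rng: np.random.Generator, arena: Arena) -> Point:
    """Uniform random location in the arena."""
    return Point(
        float(rng.random() * arena.width),
        float(rng.random() * arena.height),
    )


def grid_geometry(arena: Arena, radius: float) -> tuple[int, int, float, float]:
    """Choose uniform-grid bin counts so each bin is at least ``radius`` wide.

    Returns ``(nx, ny, cell_w, cell_h)``. With bins no smaller than the query
    radius, every radius-limited neighborhood is covered by the 3x3 block of
    bins around the query point.
    """
    if radius <= 0:
        nx = ny = 1
    else:
        nx = max(1, int(arena.width // radius))
        ny = max(1, int(arena.height // radius))
    return nx, ny, arena.width / nx, arena.height / ny


def neighbor_cell_table(nx: int, ny: int) -> np.ndarray:
    """For every grid cell, the (wrapped) ids of its 3x3 block of cells.

    With fewer than 3 cells along an axis the block collapses to the distinct
    wrapped cells, so no cell is visited twice in a query.
    """
    width = min(3, nx) * min(3, ny)
    table = np.empty((nx * ny, width), dtype=np.int64)
    for cx in range(nx):
        xs = sorted({(cx + o) % nx for o in (-1, 0, 1)})
        for cy in range(ny):
            ys = sorted({(cy + o) % ny for o in (-1, 0, 1)})
            table[cx * ny + cy, :] = [gx * ny + gy for gx in xs for gy in ys]
    return table
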