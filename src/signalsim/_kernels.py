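"""Numba hot loops for the per-step schedule.

Two inner loops dominate a run: advancing the resource-item populations in
scheduled order (aging, death, capacity-gated birth) and nearest-item
neighborhood queries against the uniform-grid spatial index. Both are exact
counterparts of the plain-Python contracts in :mod:`signalsim.agents` and
:mod:`signalsim.world`; the test suite checks the equivalence.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def scan_item_segment(
    seg: np.ndarray,
    n_mobile: int,
    n_food: int,
    age_f: np.ndarray,
    alive_f: np.ndarray,
    u_f: np.ndarray,
    pop_f: int,
    cap_f: int,
    max_age_f: int,
    p_f: float,
    age_d: np.ndarray,
    alive_d: np.ndarray,
    u_d: np.ndarray,
    pop_d: int,
    cap_d: int,
    max_age_d: int,
    p_d: float,
):
    """Advance every item whose scheduler slot falls in ``seg``.

    ``seg`` is a slice of the per-step permutation over all entities; values
    below ``n_mobile`` (mobile agents) are skipped, values in
    ``[n_mobile, n_mobile + n_food)`` index food items, the rest index
    display items. Each live item ages by one; an item reaching its maximum
    age dies; otherwise it gives birth with probability ``p`` while its
    population is below carrying capacity. Items consumed earlier in the
    step (``alive`` already False) do not act. Newborns are only counted
    here -- the caller places them -- but they raise the population
    immediately, so they gate later births in the same step.

    Returns ``(pop_f, births_f, pop_d, births_d)``.
    """
    births_f = 0
    births_d = 0
    for k in range(seg.size):
        v = seg[k]
        if v < n_mobile:
            continue
        i = v - n_mobile
        if i < n_food:
            if alive_f[i]:
                age_f[i] += 1
                if age_f[i] >= max_age_f:
                    alive_f[i] = False
                    pop_f -= 1
                elif pop_f < cap_f and u_f[i] < p_f:
                    births_f += 1
                    pop_f += 1
        else:
            j = i - n_food
            if alive_d[j]:
                age_d[j] += 1
                if age_d[j] >= max_age_d:
                    alive_d[j] = False
                    pop_d -= 1
                elif pop_d < cap_d and u_d[j] < p_d:
                    births_d += 1
                    pop_d += 1
    return pop_f, births_f, pop_d, births_d


@njit(cache=True)
def grid_sort(cid: np.ndarray, n_cells: int):
    """Stable counting sort of item indices by grid-cell id.

    Returns ``(sorted_idx, cell_starts)`` with ``cell_starts`` of length
    ``n_cells + 1``; equivalent to a stable argsort of ``cid`` plus
    searchsorted boundaries, in O(n).
    """
    counts = np.zeros(n_cells + 1, dtype=np.int64)
    for i in range(cid.size):
        counts[cid[i] + 1] += 1
    starts = np.cumsum(counts)
    pos = starts[:-1].copy()
    sorted_idx = np.empty(cid.size, dtype=np.int64)
    for i in range(cid.size):
        c = cid[i]
        sorted_idx[pos[c]] = i
        pos[c] += 1
    return sorted_idx, starts


@njit(cache=True)
def nearest_in_grid(
    px: float,
    py: float,
    xs: np.ndarray,
    ys: np.ndarray,
    alive: np.ndarray,
    sorted_idx: np.ndarray,
    cell_starts: np.ndarray,
    cells: np.ndarray,
    radius: float,
    width: float,
    height: float,
):
    """Nearest live item within ``radius`` among the grid cells ``cells``.

    Boundary inclusive; ties at equal distance go to the lowest item index.
    Returns ``(index, distance_sq)`` with ``index = -1`` when nothing is in
    range.
    """
    best = -1
    best_d2 = radius * radius
    for t in range(cells.size):
        c = cells[t]
        for k in range(cell_starts[c], cell_starts[c + 1]):
            i = sorted_idx[k]
            if not alive[i]:
                continue
            dx = abs(xs[i] - px)
            if dx > width - dx:
                dx = width - dx
            dy = abs(ys[i] - py)
            if dy > height - dy:
                dy = height - dy
            d2 = dx * dx + dy * dy
            if d2 < best_d2 or (d2 == best_d2 and (best == -1 or i < best)):
                best = i
                best_d2 = d2
    return best, best_d2


@njit(cache=True)
def nearest_in_arrays(
    px: float,
    py: float,
    xs: np.ndarray,
    ys: np.ndarray,
    alive: np.ndarray,
    n: int,
    radius: float,
    width: float,
    height: float,
):
    """Linear-scan variant of :func:`nearest_in_grid` over ``xs[:n]``."""
    best = -1
    best_d2 = radius * radius
    for i in range(n):
        if not alive[i]:
            continue
        dx = abs(xs[i] - px)
        if dx > width - dx:
            dx = width - dx
        dy = abs(ys[i] - py)
        if dy > height - dy:
            dy = height - dy
        d2 = dx * dx + dy * dy
        if d2 < best_d2 or (d2 == best_d2 and (best == -1 or i < best)):
            best = i
            best_d2 = d2
    return best, best_d2
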