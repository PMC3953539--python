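"""Full-factorial simulation sweeps over builds and resource levels.

A sweep runs every requested build at every food level (and, for builds
that require display items, every display-item level) for a number of
replicate seeds, computing the per-run concordance W and the lost-signaling-
opportunity count. Per-run seeds are derived deterministically from the
master seed and the cell/replicate coordinates, so runs are independent and
the sweep is reproducible run-by-run regardless of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import BuildFlags, all_builds
from .engine import RunResult, SimConfig, run
from .metrics import run_concordance

DEFAULT_FOOD_LEVELS = (250, 1000, 2500, 5000, 10000, 25000)
DEFAULT_DISPLAY_LEVELS = (250, 2500, 25000)

SWEEP_COLUMNS = [
    "items_needed",
    "sequential_assessment",
    "realtime_only",
    "food_level",
    "display_level",
    "replicate",
    "seed",
    "W",
    "lost_opportunities",
]


@dataclass(frozen=True)
class SweepSpec:
    """Definition of one factorial experiment.

    ``display_levels`` applies only to builds with ``items_needed``; builds
    without display items contribute one cell per food level (recorded with
    ``display_level = 0``).
    """

    food_levels: Sequence[int] = DEFAULT_FOOD_LEVELS
    display_levels: Sequence[int] = DEFAULT_DISPLAY_LEVELS
    builds: Sequence[BuildFlags] = field(default_factory=all_builds)
    replicates: int = 10
    base_config: SimConfig = field(default_factory=SimConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v <= 0 for v in self.food_levels) or any(
            v <= 0 for v in self.display_levels
        ):
            raise ValueError("all resource levels must be positive")

    def cells(self) -> list[tuple[BuildFlags, int, int]]:
        """All (build, food_level, display_level) cells, in sweep order."""
        out = []
        for build in self.builds:
            for food in self.food_levels:
                if build.items_needed:
                    for disp in self.display_levels:
                        out.append((build, int(food), int(disp)))
                else:
                    out.append((build, int(food), 0))
        return out


def run_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic, collision-free per-run seed (31-bit)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def cell_config(spec: SweepSpec, build: BuildFlags, food: int, disp: int, seed: int) -> SimConfig:
    return spec.base_config.replace(
        flags=build,
        n_food_init=int(food),
        n_display_init=int(disp) if build.items_needed else 0,
        seed=seed,
    )


def factorial_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Execute the sweep and return the tidy result table.

    One row per run: the three build flags (0/1), resource levels, replicate
    index, per-run seed, Kendall's W, and the lost-opportunity count.
    """
    rows = []
    cells = spec.cells()
    for ci, (build, food, disp) in enumerate(cells):
        for rep in range(spec.replicates):
            seed = run_seed(spec.master_seed, ci, rep)
            cfg = cell_config(spec, build, food, disp, seed)
            try:
                result = run(cfg)
            except Exception as exc:  # pragma: no cover - abort with cell identity
                raise RuntimeError(
                    f"run failed in cell {ci} "
                    f"(build={build}, food={food}, display={disp}, replicate={rep})"
                ) from exc
            rows.append(
                {
                    "items_needed": int(build.items_needed),
                    "sequential_assessment": int(build.sequential_assessment),
                    "realtime_only": int(build.realtime_only),
                    "food_level": food,
                    "display_level": disp,
                    "replicate": rep,
                    "seed": seed,
                    "W": run_concordance(result),
                    "lost_opportunities": result.lost_opportunities,
                }
            )
        if progress:
            print(f"cell {ci + 1}/{len(cells)} done", flush=True)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def lost_opportunity_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e.m. lost opportunities by (food_level, display_level).

    Only item-needed runs carry the counter; with none present the result is
    an explicit empty table (same columns, zero rows). Single-run cells
    report a zero-width s.e.m.
    """
    sub = table[table["items_needed"] == 1]
    if sub.empty:
        return pd.DataFrame(columns=["food_level", "display_level", "mean", "sem", "n"])
    g = sub.groupby(["food_level", "display_level"])["lost_opportunities"]
    out = g.agg(mean="mean", sem=lambda v: v.sem(ddof=1) if len(v) > 1 else 0.0, n="count")
    return out.reset_index()


def save_sweep(
    table: pd.DataFrame, spec: SweepSpec, directory: str | Path, stem: str = "sweep"
) -> None:
    """Write the tidy table as CSV plus a JSON manifest of the spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.to_csv(directory / f"{stem}.csv", index=False)
    manifest = {
        "master_seed": int(spec.master_seed),
        "replicates": int(spec.replicates),
        "food_levels": [int(v) for v in spec.food_levels],
        "display_levels": [int(v) for v in spec.display_levels],
        "builds": [
            {
                "items_needed": b.items_needed,
                "sequential_assessment": b.sequential_assessment,
                "realtime_only": b.realtime_only,
            }
            for b in spec.builds
        ],
        "base_config": spec.base_config.to_dict(),
    }
    (directory / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))
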