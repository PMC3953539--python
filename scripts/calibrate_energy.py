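"""Calibrate the two free energy-budget parameters.

The energy budget leaves two parameters without a stated value: the energy
gained per food item (``food_energy``) and the per-step cost (``step_cost``,
the natural unit). This script sweeps candidate values over a reduced
factorial design, fits the W-on-design-factors GLM for each candidate, and
prints the three binary-factor coefficients and the realtime effect size,
so a default can be chosen on the published effect structure (items and
sequential moderately negative, realtime weakly negative).

Usage::

    python scripts/calibrate_energy.py [--food-energy 20 100 500]
        [--step-cost 1] [--replicates 2] [--seed 11]
"""

import argparse

from signalsim.analysis import fit_glm
from signalsim.engine import SimConfig
from signalsim.experiments import SweepSpec, factorial_sweep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--food-energy", nargs="+", type=float, default=[20.0, 100.0, 500.0])
    ap.add_argument("--step-cost", nargs="+", type=float, default=[1.0])
    ap.add_argument("--replicates", type=int, default=2)
    ap.add_argument("--food-levels", nargs="+", type=int, default=[250, 2500, 25000])
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    header = (
        f"{'step_cost':>9} {'food_energy':>11} {'items':>8} {'sequential':>10} "
        f"{'realtime':>8} {'rt_eta2':>8} {'food':>8} {'intercept':>9}"
    )
    print(header)
    for sc in args.step_cost:
        for fe in args.food_energy:
            base = SimConfig(step_cost=sc, food_energy=fe)
            spec = SweepSpec(
                food_levels=tuple(args.food_levels),
                display_levels=(2500,),
                replicates=args.replicates,
                base_config=base,
                master_seed=args.seed,
            )
            table = factorial_sweep(spec)
            fit = fit_glm(table)
            print(
                f"{sc:9.2f} {fe:11.1f} "
                f"{fit.coef('items_needed'):8.3f} "
                f"{fit.coef('sequential_assessment'):10.3f} "
                f"{fit.coef('realtime_only'):8.3f} "
                f"{fit.partial_eta_sq('realtime_only'):8.4f} "
                f"{fit.coef('food'):8.3f} "
                f"{fit.coef('Intercept'):9.3f}",
                flush=True,
            )


if __name__ == "__main__":
    main()
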