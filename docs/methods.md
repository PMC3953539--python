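# Model and methods

## The model

`signalsim` is a spatially explicit, individual-based model of animal
signaling systems. Twenty **signalers** hold fixed, unique home territories
on a 500×500 continuous toroid (no lattice; wraparound boundaries remove
edge effects) and advertise a single generic display trait. Twenty
**receivers** assess them. **Food items** and, where required, **display
items** are point resources with age-limited lifespans and capacity-gated
reproduction. A run lasts 1,440 discrete time steps (one month of 15-minute
steps at 12-hour days); within each step a single uniformly random
permutation over *all* entities fixes the action order, so no class of
agent is systematically advantaged.

Every mobile agent runs the same energy budget: an energy reserve
(initialized as a uniform integer draw on 0–1000), a threshold of 500 below
which the agent must forage, a fixed per-step cost paid in display,
observation and search alike, and a fixed gain per food item eaten. An
agent below threshold eats the nearest food item within its perception
neighborhood (radius 10) or moves one step (10 units) along a random
heading. Agents never die; energy floors at zero.

Signalers with sufficient energy display at their home territory; display
is dichotomous and costs no more than any other step. The three build
axes — the factorial design of the experiment — are:

* **items needed**: display additionally requires securing an external
  display item (a twig, say) from within the neighborhood; the item is
  consumed by the display. A step in which a signaler has the energy but
  cannot find an item increments the global **lost-opportunity** counter.
* **sequential assessment**: receivers inspect one territory per step on a
  private shuffled circuit (best-of-n sampling), advancing to the next
  territory each step, instead of observing every displaying signaler at
  once from the arena center (the lek). (A variant in which the receiver
  stays on a territory while its resident keeps displaying was tried and
  rejected; see the calibration section.)
* **real-time only**: receivers increment a per-signaler tally by one for
  each display they witness, instead of reading the signaler's cumulative
  display record (a bower, nest, or morphological structure) in a single
  observation.

A signaler's *display flag* is set by its own action — true when that
action was a display, false otherwise — and persists until its next action.
Receivers register only flag-true signalers, so foragers are never counted,
and whether an individual display is witnessed does not depend on the luck
of the within-step ordering. (Clearing flags at the start of each step was
tried and rejected: it makes every real-time count a ~50% binomial sample
of the true effort, which drowns the design factors in scheduler noise.)

There is no learning, no adaptation, no reproduction of mobile agents, and
no direct interaction between individuals; all competition is indirect,
through the shared resource pools. Receivers are assumed to have perfect
memory and perfect identification of signalers.

## Scoring a run

A run yields a 20×21 rating table: each signaler's true display-step count
plus each receiver's 20-entry estimate vector. Agreement is scored with
tie-corrected Kendall's coefficient of concordance over the m = 21 judges,

W = 12·S / (m²(n³−n) − m·ΣTⱼ),

with mid-ranks within judges, S the variance of rank sums over the n = 20
signalers, and Tⱼ = Σ(t³−t) over judge j's tie groups. The tie correction
is essential: receivers that never secured enough food rank all signalers
identically at zero, which breaks ordinary rank correlations but leaves W
defined. A fully degenerate table (every judge all-tied) returns W = 0
with a warning rather than an error so that large sweeps never abort.
A mean per-receiver Spearman correlation against the true record is
provided as a secondary diagnostic only.

## The experiment and its analysis

`factorial_sweep` crosses the 8 builds with food abundances
{250, 1000, 2500, 5000, 10000, 25000} (display items at 2500 where a build
needs them; the 250–25000 range is also available as a display-item axis)
and replicates each cell with per-run seeds derived from
`SeedSequence(master_seed, spawn_key=(cell, replicate))`, so results do not
depend on execution order. Per-run W values are fitted by OLS on an
intercept, the food fraction (food level divided by the largest level
swept, keeping the predictor on the unit scale of W; raw-count coding is a
flag), and the three 0/1 build factors, in that fixed order. Effect sizes
are partial eta squared, SS_factor/(SS_factor+SS_error), from sequential
(Type-I) sums of squares in the same order by default (Type-III is an
option). p-values are reported but are not the point: with simulated data
significance is a function of the number of runs, so interpretation rests
on coefficients and effect sizes.

## Calibrating the free energy parameters

The energy budget has two parameters with no canonical value: the per-step
cost and the per-item food gain. They were calibrated (script:
`scripts/calibrate_energy.py`) against the qualitative effect structure the
experiment is meant to exhibit — ranking accuracy rising with food toward
an asymptote, a moderate penalty for needing display items, a moderate
penalty for sequential assessment, and only a weak penalty for real-time
observation — with these findings:

* **Per-step cost sets how long initial-energy heterogeneity survives.**
  The 0–1000 initial draw is the model's engine of inter-individual
  variation. At a cost of 1/step the endowment is spent within ~500 steps,
  true efforts converge to a common steady-state display rate, and all
  observation regimes degrade into ranking noise. A cost of 0.35/step makes
  the endowment transient span the full 1,440-step run, so true efforts
  stay well separated under every build.
* **Food gain relative to cost sets the foraging interruption rate.** A
  gain near 3× the step cost yields display/observation duty cycles around
  70% at saturating food — high enough that receivers witness most
  displays, low enough that food abundance still modulates accuracy and
  display-item demand stays near the item population's reproductive
  capacity rather than stripping it bare.

The shipped defaults are `step_cost = 0.35` and `food_energy = 1.0`
(`move_step` stays at one neighborhood radius, coupling the motion and
perception scales). Under these defaults the fitted coefficients are
approximately −0.16 for items-needed and −0.10 for sequential assessment.
The real-time penalty, while correctly negative, remains larger in this
implementation (≈ −0.19, partial eta squared ≈ 0.26) than the near-null
effect the design aims for: with symmetric home territories and a shared landscape, no
parameterization found keeps per-receiver miss patterns uncorrelated with
per-signaler display phases at saturating food, so real-time counts carry
irreducible pair-level bias. This is documented as a known limitation
rather than hidden by retuning the statistic.

## What the generator does and does not emulate

Runs are fully synthetic: the model *is* the data generator, and the test
suite exercises it at reduced replication (typically 3 replicates per cell
rather than 10) and with smaller worlds and shorter runs in unit tests.
Passing tests therefore demonstrate internal consistency of the model and
statistics under the stated conditions — they say nothing about any real
signaling system, where memory is imperfect, signals are multimodal, and
receivers' sampling rules are richer than the two regimes modeled.

## Numerical and design choices

* Neighborhood boundaries are inclusive (distance ≤ radius), making a
  radius of 0 meaningful; nearest-item ties break to the lowest item index.
* The spatial index is a uniform grid with bins at least one query radius
  wide; its results are contractually identical to a linear scan (tested).
* Item reproduction is evaluated in scheduled order with the population
  counter updated as deaths, births and consumption occur, so capacity can
  never be exceeded mid-step; newborns enter at age 0, are visible (and
  edible) immediately, and first act on the following step.
* Items whose age reaches the maximum (100, matching the 0–100 initial age
  draw) die at their action; an item initialized at the maximum age dies at
  its first action.
* One master seed spawns six named substreams (placement, energies,
  scheduling, births, headings, tours), so tests can freeze components
  independently; identical configuration and seed give bit-identical runs.
* Travel to home, territory or arena center is instantaneous; modeling
  travel time would introduce parameters with no stated values.
* Home territories sit on an evenly spaced 5×4 grid; receiver circuits are
  independent uniform shuffles of the 20 territories.
* Hungry receivers do not advance their circuit while foraging.
* Coefficients of the GLM's binary factors are insensitive to the food
  coding in this near-balanced design; the intercept and food coefficient
  are coding-dependent and should be compared across analyses only under
  the same coding.

## Known limitations

* The real-time observation penalty is overestimated relative to the
  target effect structure (see calibration section). The same mechanism
  breaks the rising-with-food accuracy curve in the two builds that
  combine real-time observation with display items: at high food nearly
  every signaler is energy-rich, display-item demand (one item per display
  step, 20 signalers) far exceeds the item population's reproductive
  output, realized efforts become a near-homogeneous item lottery, and
  real-time counts of those sporadic displays lose rank information as
  food grows. Mean W rises with food in the other six builds.
* Partial eta squared uses Type-I sums of squares by default; in this
  nearly balanced design Type-III values are close but not identical.
* The model is not a general foraging model: energy has no ceiling, agents
  cannot die, and food competition is purely exploitative.
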