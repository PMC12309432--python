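# Methods

## Model overview

`foragesim` implements a discrete-time, spatially explicit individual-based
model of predator foraging modes. A single *active predator* searches a
two-dimensional arena for prey; a *sit-and-wait (ambush) predator* may be
present as a stationary competitor. Prey come in two kinds of equal initial
abundance: *mobile* prey, which move exactly like the active predator, and
*sedentary* prey, which never move. The model isolates **encounter
dynamics**: capture abilities are identical across prey types, so any
deviation of the active predator's capture mix from 50:50 reflects spatial
and movement mechanics alone, not differences in detectability or handling.

### Space and time

The arena is a grid of `width × height` unit cells (default 51 × 51).
Agent positions are continuous; the grid matters only for interactions,
with a position belonging to cell `(⌊x⌋, ⌊y⌋)` (half-open unit cells).
Boundaries are a torus by default (coordinates reduced modulo the arena
size, heading unchanged); a reflecting variant mirrors the offending
coordinate at the wall and negates the normal velocity component, for
boundary-sensitivity analyses. Time advances in discrete steps; "speed × 2"
treatments give a mover two unit sub-steps per time step rather than one
longer jump, so no cell is tunneled through and capture can be checked
after every sub-step.

### Movement

Movers perform correlated random walks. Per unit move the heading changes
by an angle drawn from Uniform(−θ, +θ) and the agent advances `step_length`
(default 1 cell). The turn half-width θ takes one of two values:
**directional** movement, θ = 10°, which yields strongly persistent,
space-covering paths; and **nondirectional** movement, θ = 120°, nearly
uncorrelated and locally diffusive. The active predator runs in one of
three modes: fixed directional, fixed nondirectional, or **area-restricted
search (ARS)** — directional by default, switching to nondirectional for
`ars_duration` = 20 time steps after an encounter with sedentary prey, the
timer resetting (not accumulating) on each new encounter. ARS concentrates
search effort where sedentary prey were just found, which pays off exactly
when that prey is spatially clumped.

The timer's contract: the turn limit used throughout time step *t* is 120°
iff the timer is positive on entry to *t*. Within the scheduler the timer
is updated once per step after the predator's moves — reset to the full
duration if any check that step encountered sedentary prey, otherwise
decremented — so a single trigger yields exactly 20 subsequent
nondirectional steps. A trigger during step *t* therefore changes behavior
from step *t*+1 on; both of a double-speed predator's sub-steps within one
time step use the same turn limit. By default the trigger is the
*encounter* (cell co-occupancy with a live sedentary prey) regardless of
capture success; `ars_trigger: on_capture` restricts it to actual captures,
which differs only under uncertain capture.

### Capture

A capture check examines one predator's current cell: every live prey in
the cell undergoes an independent Bernoulli(`capture_probability`) trial
(probability 1.0 by default, 0.5 in uncertain-capture treatments).
Captured prey are removed immediately and credited to the capturing
predator's ledger; prey that survive a trial stay in place and are simply
eligible at the next check. Two or more co-located prey are all taken in
the same check. Checks follow movement: after each mobile-prey sub-step
and after each active-predator sub-step, the active predator's cell is
checked; the ambush predator's cell is checked exactly once per time step,
after the movement phases. Ambush predators capture mobile prey only —
sedentary prey can never enter their cell, and initialization co-location
is deliberately inert. When both predators occupy the same cell, each
captured mobile prey is credited by a fair coin flip; the survival trial
precedes the winner draw, so "50% capture" means the same thing whether or
not the capture is contested.

### Reappearance

When enabled, each time step makes one independent Bernoulli(0.10) draw
per prey type. A successful mobile draw adds one mobile prey at a uniform
position with a uniform heading; it starts moving the next time step. A
successful sedentary draw places one new sedentary prey uniformly within a
Moore-neighbor cell (8-neighborhood, adjacent across the torus seam) of a
uniformly chosen surviving sedentary prey, preserving the clumped pattern;
if no sedentary prey survive, the draw is a recorded non-event.

### Scheduling and termination

Each time step executes, in order: mobile-prey sub-steps (check after
each), active-predator sub-steps (check after each), the ambush check, the
ARS timer update, reappearance, and the stop condition. A run terminates
when the active predator's total captures reach `stop_threshold` (default
200, i.e. half the initial 400 prey); because the stop condition is
evaluated once per step, multi-capture steps can overshoot the threshold by
a few captures. A `max_steps` cap (10⁶) guards misconfigured scenarios and
is reported as a distinct termination reason, never raised.

## Parameters

| parameter | default | meaning |
|---|---|---|
| arena width × height | 51 × 51 cells | torus by default; `reflect` available |
| n_mobile, n_sedentary | 200, 200 | initial prey abundances |
| clumped pattern | 8 patches × 25 prey, radius 5 | patch centers uniform; prey uniform on the disc, torus metric |
| directional / nondirectional max turn | 10° / 120° | half-width of the uniform turn distribution |
| step_length | 1 cell | per unit move |
| speed multipliers | 1 (2 in ×2 treatments) | unit sub-steps per time step |
| ars_duration | 20 steps | nondirectional bout length; reset on re-encounter |
| capture_probability | 1.0 (0.5 in treatments) | per predator–prey trial |
| contested_active_share | 0.5 | active predator's chance at a contested prey |
| reappearance probability | 0.10 per type per step | at most one new item per type per step |
| stop_threshold | 200 captures | by the active predator |
| replicates | 50 per scenario | seeds `base_seed … base_seed+49` |
| bootstrap | 10,000 resamples, 95% CI | order statistics 250 / 9,750 |

All of these are fields of `ScenarioSpec` and can be overridden from Python
(`apply_overrides`) or a YAML/JSON config (`load_config`), which is how the
boundary-handling, arena-size, ±20%-parameter and stop-condition
sensitivity analyses are expressed.

## Statistics

The per-run statistic is p = mobile / (mobile + sedentary) over the active
predator's captures (defined for every completed run, since a threshold
run has ≥ 200 captures). An experiment's summary is the sample mean of the
50 per-run proportions with a percentile bootstrap CI: 10,000 resamples of
size 50 drawn with replacement, the resample means sorted, and the CI read
at the 1-based ranks ⌈0.025·B⌉ and ⌈0.975·B⌉. The bootstrap RNG stream is
independent of the simulation streams, so summaries can be recomputed
without touching the runs. Two treatments are declared different when
their CIs do not overlap (closed intervals; shared endpoints overlap).
This decision rule is conservative relative to a formal test, and no other
inference is performed.

## Randomness and reproducibility

Each replicate uses one `numpy` PCG64 generator seeded with `base_seed +
replicate_index`; every stochastic element (placement, turns, capture
trials, contested draws, reappearance) consumes this single stream in a
fixed documented order, so `run_simulation(scenario, seed)` is a pure
function and whole experiments are bit-reproducible and order-independent
across replicates. For vectorization the prey arrays advance dead slots
along with live ones (a fixed-shape operation per step); dead positions
are inert because every interaction filters on the alive mask.

## Design choices where the description was open

- **Turn distribution**: "turns up to θ" is read as the symmetric uniform
  on (−θ, θ), the standard correlated-random-walk choice; triangular or
  wrapped-normal kernels would also be consistent with the phrase but add a
  parameter the description does not name.
- **Initial headings** are uniform on [0°, 360°), matching the uniform
  random positions.
- **Repeat trials under uncertain capture**: co-occupancy is re-evaluated
  at every check, so a sedentary prey that survived a 50% trial faces
  another trial at the next check while the predator lingers in its cell.
  The alternative (one trial per visit) was considered and measurably
  overshoots the uncertain-capture conditions' published proportions,
  while the re-trial reading sits slightly below them; the literal
  every-check reading is kept.
- **Stop comparator**: termination at ≥ 200 captures (the named figure);
  the threshold is configurable for stop-condition sensitivity analyses.
- **Contested captures** resolve survival first, predator identity second.
- **Ambush diet** is mobile prey only (see Capture above).
- **Sedentary reappearance anchor**: Moore neighborhood of a surviving
  sedentary prey, torus-adjacent; skipped silently when none survive.
- **Patch geometry**: clump centers may overlap and discs wrap across the
  torus seam; distances use the torus metric.

## What the simulation shows — and what it cannot

Runs of the default conditions reproduce the model's qualitative findings:
equal catchability notwithstanding, the active predator captures mostly
mobile prey under a random sedentary pattern, and shifts toward sedentary
prey under clumped patterns searched with ARS and under ambush
competition. These are statements about the model world: a homogeneous
arena, memoryless prey that never respond to predators, no energetics,
no births or deaths, and identical per-encounter capture probabilities for
both prey types. Real systems violate all of these to varying degrees, so
passing reproduction tests validates the implementation of this encounter
mechanism, not the field accuracy of its predictions.

## Problem sizes used in the test suite

Unit and property tests run on reduced worlds (11×11 arenas, tens of prey,
stop thresholds of a few captures) chosen so each test isolates one
mechanism deterministically. The reproduction tests and
`scripts/acceptance.py` run the reported conditions at the study's own
scale — 50 replicates of full 51×51, 200+200-prey runs per condition —
because the published quantities are 50-replicate means; a full 11-condition
regeneration takes about a minute and a half on one CPU. Monte-Carlo
frequency checks (capture rates, contested splits, bootstrap coverage) use
10³–10⁵ draws with fixed seeds, sized so their tolerances are several
standard errors wide.
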