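"""Individual-based predator–prey world on a bounded 2-D arena.

The model places one actively searching predator (optionally alongside one
stationary ambush predator) in a cell-gridded arena containing mobile and
sedentary prey. Movers follow correlated random walks: each unit move turns
by a bounded uniform angle and advances one step length. Capture happens by
cell co-occupancy. The active predator may use area-restricted search (ARS),
switching from directional travel (small max turn) to tortuous search (large
max turn) for a fixed number of time steps after encountering sedentary prey.

Positions are continuous; the cell grid only mediates capture. The default
arena is a 51×51 torus (wrapped boundaries); mirrored (reflecting) walls are
available as a variant.

Internally the prey populations are stored as flat numpy arrays so that a
whole time step costs a handful of vectorized operations; dead prey keep
their array slots and are excluded from every interaction via an alive mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ACTIVE_PREDATOR",
    "AMBUSH_PREDATOR",
    "MOBILE_PREY",
    "SEDENTARY_PREY",
    "ArenaConfig",
    "MovementParams",
    "ARSParams",
    "CaptureParams",
    "ReappearanceParams",
    "AgentState",
    "ActivePredatorState",
    "SimulationState",
    "CaptureEvent",
    "RunResult",
    "wrap_position",
    "reflect_position",
    "cell_index",
    "sample_turn",
    "advance_agent",
    "init_sedentary_random",
    "init_sedentary_clumped",
    "init_state",
    "resolve_cell_captures",
    "resolve_contested",
    "trigger_ars",
    "tick_ars",
    "reappearance_step",
    "simulation_step",
    "run_simulation",
]

ACTIVE_PREDATOR = "active_predator"
AMBUSH_PREDATOR = "ambush_predator"
MOBILE_PREY = "mobile_prey"
SEDENTARY_PREY = "sedentary_prey"

_MOVERS = (ACTIVE_PREDATOR, MOBILE_PREY)

#: Moore-neighborhood cell offsets, fixed order (used by sedentary reappearance).
MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and boundary handling.

    ``wrap`` gives a torus: movers exiting one edge re-enter from the
    opposite edge with heading unchanged. ``reflect`` mirrors the mover back
    into the arena and negates the velocity component normal to the wall.
    """

    width: int = 51
    height: int = 51
    boundary_mode: str = "wrap"

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("arena must be at least 3x3 cells")
        if self.boundary_mode not in ("wrap", "reflect"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass(frozen=True)
class MovementParams:
    """Correlated-random-walk parameters shared by all movers.

    Max turns are half-widths in degrees of the symmetric uniform turning
    distribution. Speed multipliers are integer sub-steps per time step
    (2 means "twice as fast": two unit moves, each followed by a capture
    check).
    """

    directional_max_turn: float = 10.0
    nondirectional_max_turn: float = 120.0
    step_length: float = 1.0
    speed_multiplier_active: int = 1
    speed_multiplier_mobile: int = 1

    def __post_init__(self) -> None:
        for mt in (self.directional_max_turn, self.nondirectional_max_turn):
            if not 0.0 <= mt <= 180.0:
                raise ValueError("max turn must be in [0, 180] degrees")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        for m in (self.speed_multiplier_active, self.speed_multiplier_mobile):
            if m not in (1, 2):
                raise ValueError("speed multipliers must be 1 or 2")


@dataclass(frozen=True)
class ARSParams:
    """Area-restricted search: nondirectional turning for ``duration`` time
    steps after a sedentary-prey trigger; a new trigger resets the count.

    ``trigger`` is ``on_encounter`` (cell co-occupancy with a live sedentary
    prey, regardless of capture success) or ``on_capture`` (only an actual
    capture re-arms the timer); the two differ only under uncertain capture.
    """

    enabled: bool = False
    duration: int = 20
    trigger: str = "on_encounter"

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("ARS duration must be >= 0")
        if self.trigger not in ("on_encounter", "on_capture"):
            raise ValueError(f"unknown ARS trigger {self.trigger!r}")


@dataclass(frozen=True)
class CaptureParams:
    capture_probability: float = 1.0
    #: probability the active predator is credited with a prey captured while
    #: both predators share its cell
    contested_active_share: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.capture_probability <= 1.0:
            raise ValueError("capture_probability must be in (0, 1]")
        if not 0.0 <= self.contested_active_share <= 1.0:
            raise ValueError("contested_active_share must be in [0, 1]")


@dataclass(frozen=True)
class ReappearanceParams:
    """Per time step, one independent Bernoulli draw per prey type decides
    whether a single new prey item of that type appears."""

    enabled: bool = False
    per_type_probability: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_type_probability <= 1.0:
            raise ValueError("per_type_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    x: float
    y: float
    heading: float
    kind: str
    alive: bool = True


@dataclass
class ActivePredatorState(AgentState):
    """Active predator with search mode and capture ledger.

    ``mode`` is one of ``fixed_directional``, ``fixed_nondirectional``,
    ``ars``. ``ars_timer`` counts the time steps of nondirectional search
    remaining; the max turn used during a time step is the nondirectional
    limit iff the timer is positive on entry to that step.
    """

    kind: str = ACTIVE_PREDATOR
    mode: str = "fixed_directional"
    ars_timer: int = 0
    captured_mobile: int = 0
    captured_sedentary: int = 0

    @property
    def captured_total(self) -> int:
        return self.captured_mobile + self.captured_sedentary


@dataclass(frozen=True)
class CaptureEvent:
    prey_kind: str
    prey_index: int
    predator_kind: str


@dataclass(frozen=True)
class RunResult:
    """Outcome of a single replicate run."""

    scenario_id: str
    seed: int
    captured_mobile_active: int
    captured_sedentary_active: int
    captured_mobile_ambush: int
    reappeared_mobile: int
    reappeared_sedentary: int
    duration_steps: int
    termination: str  # "threshold_reached" | "max_steps"


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def wrap_position(p: tuple[float, float], arena: ArenaConfig) -> tuple[float, float]:
    """Reduce a coordinate pair onto the torus (modulo arena dimensions)."""
    # float modulo of a tiny negative can round up to the modulus itself;
    # fold that back to 0 so the half-open containment invariant holds
    x = p[0] % arena.width
    y = p[1] % arena.height
    return (x if x < arena.width else 0.0, y if y < arena.height else 0.0)


def _norm_deg(h: float) -> float:
    h %= 360.0
    return h if h < 360.0 else 0.0


def _reflect_axis(v: float, size: float) -> tuple[float, bool]:
    """Mirror ``v`` into [0, size); returns (value, axis-was-flipped)."""
    flipped = False
    while v < 0.0 or v >= size:
        v = -v if v < 0.0 else 2.0 * size - v
        flipped = not flipped
        if v == size:  # exact-wall landing after mirroring
            v = np.nextafter(size, 0.0)
    return v, flipped


def reflect_position(
    p: tuple[float, float], heading: float, arena: ArenaConfig
) -> tuple[tuple[float, float], float]:
    """Mirror an out-of-bounds position back into the arena.

    The velocity component normal to each crossed wall is negated: a
    vertical-wall bounce maps heading ``h`` to ``180 - h``, a horizontal-wall
    bounce maps it to ``-h`` (degrees, 0° = +x, counterclockwise).
    """
    x, flip_x = _reflect_axis(p[0], float(arena.width))
    y, flip_y = _reflect_axis(p[1], float(arena.height))
    h = heading
    if flip_x:
        h = 180.0 - h
    if flip_y:
        h = -h
    return (x, y), _norm_deg(h)


def cell_index(p: tuple[float, float]) -> tuple[int, int]:
    """Grid cell containing a continuous position (half-open unit cells)."""
    return (int(math.floor(p[0])), int(math.floor(p[1])))


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

def sample_turn(rng: np.random.Generator, max_turn: float) -> float:
    """One turning angle, Uniform(−max_turn, +max_turn) degrees."""
    if not 0.0 <= max_turn <= 180.0:
        raise ValueError("max_turn must be in [0, 180]")
    return float(rng.uniform(-max_turn, max_turn))


def advance_agent(
    agent: AgentState,
    max_turn: float,
    step_length: float,
    arena: ArenaConfig,
    rng: np.random.Generator,
) -> AgentState:
    """One unit move of a mover: turn, then advance ``step_length`` cells.

    Returns a new agent; boundary handling follows ``arena.boundary_mode``.
    """
    if agent.kind not in _MOVERS:
        raise ValueError(f"{agent.kind} does not move")
    if not agent.alive:
        raise ValueError("cannot advance a dead agent")
    h = _norm_deg(agent.heading + sample_turn(rng, max_turn))
    rad = math.radians(h)
    x = agent.x + step_length * math.cos(rad)
    y = agent.y + step_length * math.sin(rad)
    if arena.boundary_mode == "wrap":
        x, y = wrap_position((x, y), arena)
    else:
        (x, y), h = reflect_position((x, y), h, arena)
    return replace(agent, x=x, y=y, heading=h)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_sedentary_random(
    n: int, arena: ArenaConfig, rng: np.random.Generator
) -> np.ndarray:
    """``n`` i.i.d. uniform positions over the continuous arena, shape (n, 2)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out = np.empty((n, 2))
    out[:, 0] = rng.uniform(0.0, arena.width, n)
    out[:, 1] = rng.uniform(0.0, arena.height, n)
    return out


def init_sedentary_clumped(
    n_patches: int,
    per_patch: int,
    radius: float,
    arena: ArenaConfig,
    rng: np.random.Generator,
    return_centers: bool = False,
):
    """Clumped placement: uniform patch centers, prey uniform on the disc of
    ``radius`` cells around each center, wrapped onto the torus.

    Defaults used by the clumped scenarios are 8 patches × 25 prey within a
    5-cell radius. Returns positions with shape (n_patches * per_patch, 2);
    with ``return_centers`` also the (n_patches, 2) centers.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    centers = np.empty((n_patches, 2))
    centers[:, 0] = rng.uniform(0.0, arena.width, n_patches)
    centers[:, 1] = rng.uniform(0.0, arena.height, n_patches)
    pts = np.empty((n_patches * per_patch, 2))
    for i in range(n_patches):
        r = radius * np.sqrt(rng.uniform(0.0, 1.0, per_patch))
        theta = rng.uniform(0.0, 2.0 * np.pi, per_patch)
        block = pts[i * per_patch : (i + 1) * per_patch]
        block[:, 0] = (centers[i, 0] + r * np.cos(theta)) % arena.width
        block[:, 1] = (centers[i, 1] + r * np.sin(theta)) % arena.height
    if return_centers:
        return pts, centers
    return pts


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------

class SimulationState:
    """Mutable world state of one replicate.

    Prey live in parallel flat arrays (positions, headings, alive mask);
    captured prey keep their slots with ``alive = False``. All randomness
    flows through the single ``rng`` stream, so a state evolves
    deterministically from its seed.
    """

    def __init__(
        self,
        arena: ArenaConfig,
        movement: MovementParams,
        ars: ARSParams,
        capture: CaptureParams,
        reappearance: ReappearanceParams,
        active: ActivePredatorState,
        ambush: Optional[AgentState],
        mobile_xy: np.ndarray,
        mobile_heading: np.ndarray,
        sedentary_xy: np.ndarray,
        mobile_max_turn: float,
        rng: np.random.Generator,
        stop_threshold: int = 200,
        max_steps: int = 1_000_000,
        scenario_id: str = "",
        seed: Optional[int] = None,
    ) -> None:
        self.arena = arena
        self.movement = movement
        self.ars = ars
        self.capture = capture
        self.reappearance = reappearance
        self.active = active
        self.ambush = ambush
        self.mobile_x = np.ascontiguousarray(mobile_xy[:, 0], dtype=float)
        self.mobile_y = np.ascontiguousarray(mobile_xy[:, 1], dtype=float)
        self.mobile_heading = np.asarray(mobile_heading, dtype=float) % 360.0
        self.mobile_alive = np.ones(len(self.mobile_x), dtype=bool)
        self.sedentary_x = np.ascontiguousarray(sedentary_xy[:, 0], dtype=float)
        self.sedentary_y = np.ascontiguousarray(sedentary_xy[:, 1], dtype=float)
        self.sedentary_alive = np.ones(len(self.sedentary_x), dtype=bool)
        self.mobile_max_turn = float(mobile_max_turn)
        self.rng = rng
        self.stop_threshold = int(stop_threshold)
        self.max_steps = int(max_steps)
        self.scenario_id = scenario_id
        self.seed = seed
        self.t = 0
        self.termination: Optional[str] = None
        self.n_mobile_init = len(self.mobile_x)
        self.n_sedentary_init = len(self.sedentary_x)
        self.reappeared_mobile = 0
        self.reappeared_sedentary = 0
        self.captured_mobile_ambush = 0

    # -- bookkeeping -------------------------------------------------------

    @property
    def terminated(self) -> bool:
        return self.termination is not None

    def conservation_ok(self) -> bool:
        """Per-type ledger identity: initial + reappeared = alive + captured."""
        mob = (
            self.n_mobile_init + self.reappeared_mobile
            == int(self.mobile_alive.sum())
            + self.active.captured_mobile
            + self.captured_mobile_ambush
        )
        sed = (
            self.n_sedentary_init + self.reappeared_sedentary
            == int(self.sedentary_alive.sum()) + self.active.captured_sedentary
        )
        return mob and sed

    def positions_in_bounds(self) -> bool:
        w, h = self.arena.width, self.arena.height
        agents_ok = 0.0 <= self.active.x < w and 0.0 <= self.active.y < h
        if self.ambush is not None:
            agents_ok = agents_ok and 0.0 <= self.ambush.x < w and 0.0 <= self.ambush.y < h
        m = self.mobile_alive
        s = self.sedentary_alive
        return bool(
            agents_ok
            and np.all((self.mobile_x[m] >= 0) & (self.mobile_x[m] < w))
            and np.all((self.mobile_y[m] >= 0) & (self.mobile_y[m] < h))
            and np.all((self.sedentary_x[s] >= 0) & (self.sedentary_x[s] < w))
            and np.all((self.sedentary_y[s] >= 0) & (self.sedentary_y[s] < h))
        )

    def result(self) -> RunResult:
        if self.termination is None:
            raise RuntimeError("simulation has not terminated")
        return RunResult(
            scenario_id=self.scenario_id,
            seed=self.seed if self.seed is not None else -1,
            captured_mobile_active=self.active.captured_mobile,
            captured_sedentary_active=self.active.captured_sedentary,
            captured_mobile_ambush=self.captured_mobile_ambush,
            reappeared_mobile=self.reappeared_mobile,
            reappeared_sedentary=self.reappeared_sedentary,
            duration_steps=self.t,
            termination=self.termination,
        )

    # -- prey-array growth -------------------------------------------------

    def _append_mobile(self, x: float, y: float, heading: float) -> None:
        self.mobile_x = np.append(self.mobile_x, x)
        self.mobile_y = np.append(self.mobile_y, y)
        self.mobile_heading = np.append(self.mobile_heading, heading % 360.0)
        self.mobile_alive = np.append(self.mobile_alive, True)

    def _append_sedentary(self, x: float, y: float) -> None:
        self.sedentary_x = np.append(self.sedentary_x, x)
        self.sedentary_y = np.append(self.sedentary_y, y)
        self.sedentary_alive = np.append(self.sedentary_alive, True)


def init_state(scenario, seed: int) -> SimulationState:
    """Build the initial world for one replicate of a scenario.

    Placement order (one seeded stream): sedentary prey per the scenario's
    spatial pattern, mobile prey uniform, active predator, then the ambush
    predator if present. All mover headings are i.i.d. uniform on [0, 360).
    """
    scenario.validate()
    arena = scenario.arena
    rng = np.random.default_rng(seed)
    if scenario.spatial_pattern == "clumped":
        sed = init_sedentary_clumped(
            scenario.n_patches, scenario.per_patch, scenario.patch_radius, arena, rng
        )
    else:
        sed = init_sedentary_random(scenario.n_sedentary, arena, rng)
    mob = np.empty((scenario.n_mobile, 2))
    mob[:, 0] = rng.uniform(0.0, arena.width, scenario.n_mobile)
    mob[:, 1] = rng.uniform(0.0, arena.height, scenario.n_mobile)
    mob_heading = rng.uniform(0.0, 360.0, scenario.n_mobile)
    active = ActivePredatorState(
        x=float(rng.uniform(0.0, arena.width)),
        y=float(rng.uniform(0.0, arena.height)),
        heading=float(rng.uniform(0.0, 360.0)),
        kind=ACTIVE_PREDATOR,
        mode=scenario.predator_mode(),
    )
    ambush = None
    if scenario.ambush_present:
        ambush = AgentState(
            x=float(rng.uniform(0.0, arena.width)),
            y=float(rng.uniform(0.0, arena.height)),
            heading=0.0,
            kind=AMBUSH_PREDATOR,
        )
    return SimulationState(
        arena=arena,
        movement=scenario.movement_params(),
        ars=scenario.ars_params(),
        capture=scenario.capture_params(),
        reappearance=scenario.reappearance_params(),
        active=active,
        ambush=ambush,
        mobile_xy=mob,
        mobile_heading=mob_heading,
        sedentary_xy=sed,
        mobile_max_turn=scenario.mobile_max_turn(),
        rng=rng,
        stop_threshold=scenario.stop_threshold,
        max_steps=scenario.max_steps,
        scenario_id=scenario.scenario_id,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ARS bookkeeping
# ---------------------------------------------------------------------------

def trigger_ars(predator: ActivePredatorState, ars: ARSParams) -> ActivePredatorState:
    """Re-arm the ARS timer to its full duration (a new encounter resets the
    count rather than extending it). No-op for fixed-directionality modes."""
    if predator.mode != "ars":
        return predator
    return replace(predator, ars_timer=ars.duration)


def tick_ars(predator: ActivePredatorState) -> ActivePredatorState:
    """End-of-step timer decrement (floored at zero). The turn limit used by
    the next time step's movement reflects the post-decrement timer."""
    return replace(predator, ars_timer=max(0, predator.ars_timer - 1))


def _active_max_turn(state: SimulationState) -> float:
    a = state.active
    mv = state.movement
    if a.mode == "fixed_nondirectional":
        return mv.nondirectional_max_turn
    if a.mode == "ars" and a.ars_timer > 0:
        return mv.nondirectional_max_turn
    return mv.directional_max_turn


# ---------------------------------------------------------------------------
# Capture resolution
# ---------------------------------------------------------------------------

def resolve_contested(state: SimulationState) -> str:
    """Fair draw deciding which of two co-located predators is credited with
    a prey that has just been captured."""
    if state.rng.random() < state.capture.contested_active_share:
        return ACTIVE_PREDATOR
    return AMBUSH_PREDATOR


def resolve_cell_captures(
    state: SimulationState, predator: AgentState
) -> tuple[list[CaptureEvent], bool]:
    """One capture check over ``predator``'s current cell.

    Every live prey sharing the cell undergoes an independent
    Bernoulli(capture_probability) trial; captured prey are removed
    immediately and credited to a predator's ledger. When both predators
    occupy the same cell, each captured mobile prey is assigned by
    :func:`resolve_contested`. Ambush predators take mobile prey only.

    Under uncertain capture a prey that survives a trial stays in place and
    is eligible again at the next check — co-occupancy is re-evaluated every
    time anything moves, so a sedentary prey sharing the predator's cell
    faces one trial per check, not one per visit.

    Returns the capture events and whether the check constitutes an ARS
    trigger for the active predator (sedentary encounter or capture,
    depending on ``ARSParams.trigger``; always False for the ambush check).
    """
    rng = state.rng
    p = state.capture.capture_probability
    certain = p >= 1.0
    cx = math.floor(predator.x)
    cy = math.floor(predator.y)
    is_active = predator.kind == ACTIVE_PREDATOR
    other = state.ambush if is_active else state.active
    contested = (
        other is not None
        and math.floor(other.x) == cx
        and math.floor(other.y) == cy
    )
    events: list[CaptureEvent] = []
    trig = False

    mob_here = np.flatnonzero(
        state.mobile_alive
        & (state.mobile_x >= cx)
        & (state.mobile_x < cx + 1.0)
        & (state.mobile_y >= cy)
        & (state.mobile_y < cy + 1.0)
    )
    for i in mob_here:
        if certain or rng.random() < p:
            state.mobile_alive[i] = False
            winner = resolve_contested(state) if contested else predator.kind
            if winner == ACTIVE_PREDATOR:
                state.active.captured_mobile += 1
            else:
                state.captured_mobile_ambush += 1
            events.append(CaptureEvent(MOBILE_PREY, int(i), winner))

    if is_active:
        sed_here = np.flatnonzero(
            state.sedentary_alive
            & (state.sedentary_x >= cx)
            & (state.sedentary_x < cx + 1.0)
            & (state.sedentary_y >= cy)
            & (state.sedentary_y < cy + 1.0)
        )
        if sed_here.size and state.ars.trigger == "on_encounter":
            trig = True
        for i in sed_here:
            if certain or rng.random() < p:
                state.sedentary_alive[i] = False
                state.active.captured_sedentary += 1
                events.append(CaptureEvent(SEDENTARY_PREY, int(i), ACTIVE_PREDATOR))
                if state.ars.trigger == "on_capture":
                    trig = True
    return events, trig


# ---------------------------------------------------------------------------
# Reappearance
# ---------------------------------------------------------------------------

def reappearance_step(state: SimulationState, rng: np.random.Generator) -> SimulationState:
    """One per-type Bernoulli draw for a new prey item of each type.

    A new mobile prey appears at a uniform random position with a uniform
    heading and starts moving on the next time step. A new sedentary prey is
    placed uniformly inside one of the eight Moore-neighbor cells (adjacent
    across the torus seam in wrap mode) of a uniformly chosen live sedentary
    prey; when none survive, the draw is a non-event.
    """
    if not state.reappearance.enabled:
        return state
    pr = state.reappearance.per_type_probability
    arena = state.arena
    if rng.random() < pr:
        x = float(rng.uniform(0.0, arena.width))
        y = float(rng.uniform(0.0, arena.height))
        h = float(rng.uniform(0.0, 360.0))
        state._append_mobile(x, y, h)
        state.reappeared_mobile += 1
    if rng.random() < pr:
        live = np.flatnonzero(state.sedentary_alive)
        if live.size:
            anchor = int(live[rng.integers(live.size)])
            cx = math.floor(state.sedentary_x[anchor])
            cy = math.floor(state.sedentary_y[anchor])
            if arena.boundary_mode == "wrap":
                dx, dy = MOORE_OFFSETS[int(rng.integers(8))]
                ncx = (cx + dx) % arena.width
                ncy = (cy + dy) % arena.height
            else:
                valid = [
                    (cx + dx, cy + dy)
                    for dx, dy in MOORE_OFFSETS
                    if 0 <= cx + dx < arena.width and 0 <= cy + dy < arena.height
                ]
                ncx, ncy = valid[int(rng.integers(len(valid)))]
            x = ncx + float(rng.uniform(0.0, 1.0))
            y = ncy + float(rng.uniform(0.0, 1.0))
            state._append_sedentary(x, y)
            state.reappeared_sedentary += 1
    return state


# ---------------------------------------------------------------------------
# Scheduler
# ---------------------------------------------------------------------------

def _move_all_mobile(state: SimulationState) -> None:
    """Advance every mobile-prey slot one unit move (vectorized).

    Dead slots are advanced too — their positions are inert because every
    interaction filters on the alive mask — which keeps the step a fixed
    sequence of whole-array operations.
    """
    mv = state.movement
    rng = state.rng
    n = state.mobile_x.shape[0]
    h = state.mobile_heading
    h += rng.uniform(-state.mobile_max_turn, state.mobile_max_turn, n)
    h %= 360.0
    rad = np.radians(h)
    x = state.mobile_x
    y = state.mobile_y
    x += mv.step_length * np.cos(rad)
    y += mv.step_length * np.sin(rad)
    arena = state.arena
    if arena.boundary_mode == "wrap":
        x %= arena.width
        y %= arena.height
        # tiny negatives can round the modulo up to the modulus itself
        x[x >= arena.width] = 0.0
        y[y >= arena.height] = 0.0
    else:
        _reflect_arrays(x, y, h, arena)
    h[h >= 360.0] = 0.0


def _reflect_arrays(x: np.ndarray, y: np.ndarray, h: np.ndarray, arena: ArenaConfig) -> None:
    # single mirror per axis suffices for unit steps in arenas >= 3 cells wide
    w = float(arena.width)
    hh = float(arena.height)
    lo = x < 0.0
    hi = x >= w
    x[lo] = -x[lo]
    x[hi] = 2.0 * w - x[hi]
    flip = lo | hi
    h[flip] = (180.0 - h[flip]) % 360.0
    x[x >= w] = np.nextafter(w, 0.0)
    lo = y < 0.0
    hi = y >= hh
    y[lo] = -y[lo]
    y[hi] = 2.0 * hh - y[hi]
    flip = lo | hi
    h[flip] = (-h[flip]) % 360.0
    y[y >= hh] = np.nextafter(hh, 0.0)


def _move_active(state: SimulationState, max_turn: float) -> None:
    a = state.active
    rng = state.rng
    h = _norm_deg(a.heading + rng.uniform(-max_turn, max_turn))
    rad = math.radians(h)
    x = a.x + state.movement.step_length * math.cos(rad)
    y = a.y + state.movement.step_length * math.sin(rad)
    arena = state.arena
    if arena.boundary_mode == "wrap":
        x, y = wrap_position((x, y), arena)
    else:
        (x, y), h = reflect_position((x, y), h, arena)
    a.x = x
    a.y = y
    a.heading = h


def simulation_step(state: SimulationState) -> SimulationState:
    """Advance the world one time step.

    Event order: (1) each live mobile prey takes its unit sub-steps, the
    active predator's cell checked after each; (2) the active predator takes
    its unit sub-steps (turn limit fixed on entry to the step by the ARS
    timer), its cell checked after each; (3) the ambush predator's single
    per-step check; (4) ARS timer update — reset to full duration if a
    sedentary trigger occurred this step, else decremented; (5) prey
    reappearance; (6) stop condition. ``t`` increments by exactly 1.
    """
    if state.terminated:
        raise RuntimeError("simulation_step called on a terminated state")
    mv = state.movement
    active = state.active
    max_turn = _active_max_turn(state)
    triggered = False

    for _ in range(mv.speed_multiplier_mobile):
        _move_all_mobile(state)
        _, trig = resolve_cell_captures(state, active)
        triggered = triggered or trig

    for _ in range(mv.speed_multiplier_active):
        _move_active(state, max_turn)
        _, trig = resolve_cell_captures(state, active)
        triggered = triggered or trig

    if state.ambush is not None:
        resolve_cell_captures(state, state.ambush)

    if active.mode == "ars":
        if triggered:
            active.ars_timer = state.ars.duration
        elif active.ars_timer > 0:
            active.ars_timer -= 1

    reappearance_step(state, state.rng)

    state.t += 1
    if active.captured_total >= state.stop_threshold:
        state.termination = "threshold_reached"
    elif state.t >= state.max_steps:
        state.termination = "max_steps"
    return state


def run_simulation(scenario, seed: int) -> RunResult:
    """Run one replicate to termination; a pure function of (scenario, seed).

    The run ends when the active predator's total captures reach the stop
    threshold (default 200, half the default total prey), or at the
    ``max_steps`` safety cap (reported in the result, never raised).
    """
    state = init_state(scenario, seed)
    while not state.terminated:
        simulation_step(state)
    return state.result()
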