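"""Scenario catalog: the 18-row treatment table × ambush presence = 36 experiments.

Treatments manipulate, one at a time relative to defaults: prey and predator
movement directionality (D = ±10° max turn, ND = ±120°), area-restricted
search (ARS) by the active predator, a ×2 speed advantage for either mover,
uncertain capture (50%), and prey reappearance. The defaults are coupled to
the sedentary-prey spatial pattern: with a random pattern the default active
predator moves directionally, with a clumped pattern it uses ARS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .engine import (
    ARSParams,
    ArenaConfig,
    CaptureParams,
    MovementParams,
    ReappearanceParams,
    RunResult,
    run_simulation,
)

__all__ = [
    "TreatmentSpec",
    "ScenarioSpec",
    "build_scenario_table",
    "get_scenario",
    "scenario_ids",
    "run_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment row: what it changes relative to the defaults."""

    prey_directionality: str = "D"  # "D" | "ND"
    predator_mode: str = "D"  # "D" | "ND" | "ARS"
    speed_double: str = "none"  # "none" | "prey" | "predator"
    capture_probability: float = 1.0
    reappearance: bool = False

    def __post_init__(self) -> None:
        if self.prey_directionality not in ("D", "ND"):
            raise ValueError("prey_directionality must be 'D' or 'ND'")
        if self.predator_mode not in ("D", "ND", "ARS"):
            raise ValueError("predator_mode must be 'D', 'ND' or 'ARS'")
        if self.speed_double not in ("none", "prey", "predator"):
            raise ValueError("speed_double must be 'none', 'prey' or 'predator'")


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete immutable description of one experimental condition.

    Couples a treatment row with the sedentary-prey spatial pattern, the
    ambush-predator flag, and every engine parameter a sensitivity analysis
    might override (arena geometry, turn limits, ARS duration/trigger,
    reappearance probability, stop threshold).
    """

    spatial_pattern: str = "random"  # "random" | "clumped"
    ambush_present: bool = False
    treatment: TreatmentSpec = field(default_factory=TreatmentSpec)
    label: str = "custom"

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    n_mobile: int = 200
    n_sedentary: int = 200
    n_patches: int = 8
    per_patch: int = 25
    patch_radius: float = 5.0
    directional_max_turn: float = 10.0
    nondirectional_max_turn: float = 120.0
    step_length: float = 1.0
    ars_duration: int = 20
    ars_trigger: str = "on_encounter"
    reappearance_probability: float = 0.10
    contested_active_share: float = 0.5
    stop_threshold: int = 200
    max_steps: int = 1_000_000

    @property
    def scenario_id(self) -> str:
        comp = "ambush" if self.ambush_present else "solo"
        return f"{self.spatial_pattern}/{comp}/{self.label}"

    def total_sedentary(self) -> int:
        if self.spatial_pattern == "clumped":
            return self.n_patches * self.per_patch
        return self.n_sedentary

    def validate(self) -> None:
        if self.spatial_pattern not in ("random", "clumped"):
            raise ValueError(f"unknown spatial_pattern {self.spatial_pattern!r}")
        if self.treatment.predator_mode == "ARS" and self.total_sedentary() == 0:
            raise ValueError("ARS predator requires sedentary prey to trigger on")
        if self.stop_threshold < 1:
            raise ValueError("stop_threshold must be >= 1")
        # construct parameter containers so their own invariants run
        self.movement_params()
        self.ars_params()
        self.capture_params()
        self.reappearance_params()

    # -- engine parameter views -------------------------------------------

    def predator_mode(self) -> str:
        return {
            "D": "fixed_directional",
            "ND": "fixed_nondirectional",
            "ARS": "ars",
        }[self.treatment.predator_mode]

    def mobile_max_turn(self) -> float:
        if self.treatment.prey_directionality == "ND":
            return self.nondirectional_max_turn
        return self.directional_max_turn

    def movement_params(self) -> MovementParams:
        return MovementParams(
            directional_max_turn=self.directional_max_turn,
            nondirectional_max_turn=self.nondirectional_max_turn,
            step_length=self.step_length,
            speed_multiplier_active=2 if self.treatment.speed_double == "predator" else 1,
            speed_multiplier_mobile=2 if self.treatment.speed_double == "prey" else 1,
        )

    def ars_params(self) -> ARSParams:
        return ARSParams(
            enabled=self.treatment.predator_mode == "ARS",
            duration=self.ars_duration,
            trigger=self.ars_trigger,
        )

    def capture_params(self) -> CaptureParams:
        return CaptureParams(
            capture_probability=self.treatment.capture_probability,
            contested_active_share=self.contested_active_share,
        )

    def reappearance_params(self) -> ReappearanceParams:
        return ReappearanceParams(
            enabled=self.treatment.reappearance,
            per_type_probability=self.reappearance_probability,
        )


# (label, prey_directionality, predator_mode, speed_double, capture_p, reappearance)
_RANDOM_ROWS = (
    ("default", "D", "D", "none", 1.0, False),
    ("pred_ars", "D", "ARS", "none", 1.0, False),
    ("prey_nd", "ND", "D", "none", 1.0, False),
    ("pred_nd", "D", "ND", "none", 1.0, False),
    ("both_nd", "ND", "ND", "none", 1.0, False),
    ("prey_speed_x2", "D", "D", "prey", 1.0, False),
    ("pred_speed_x2", "D", "D", "predator", 1.0, False),
    ("capture_50", "D", "D", "none", 0.5, False),
    ("reappearance", "D", "D", "none", 1.0, True),
)

_CLUMPED_ROWS = (
    ("pred_directional", "D", "D", "none", 1.0, False),
    ("default", "D", "ARS", "none", 1.0, False),
    ("prey_nd", "ND", "ARS", "none", 1.0, False),
    ("pred_nd", "D", "ND", "none", 1.0, False),
    ("both_nd", "ND", "ND", "none", 1.0, False),
    ("prey_speed_x2", "D", "ARS", "prey", 1.0, False),
    ("pred_speed_x2", "D", "ARS", "predator", 1.0, False),
    ("capture_50", "D", "ARS", "none", 0.5, False),
    ("reappearance", "D", "ARS", "none", 1.0, True),
)


def build_scenario_table() -> list[ScenarioSpec]:
    """The full experiment catalog, in presentation order.

    18 treatment rows (9 per spatial pattern) each expanded with the ambush
    predator absent and present: random/solo, random/ambush, clumped/solo,
    clumped/ambush — 36 scenarios with stable slug identifiers like
    ``clumped/ambush/pred_speed_x2``.
    """
    table: list[ScenarioSpec] = []
    for pattern, rows in (("random", _RANDOM_ROWS), ("clumped", _CLUMPED_ROWS)):
        for ambush in (False, True):
            for label, prey_d, pred_m, speed, capt, reapp in rows:
                table.append(
                    ScenarioSpec(
                        spatial_pattern=pattern,
                        ambush_present=ambush,
                        treatment=TreatmentSpec(
                            prey_directionality=prey_d,
                            predator_mode=pred_m,
                            speed_double=speed,
                            capture_probability=capt,
                            reappearance=reapp,
                        ),
                        label=label,
                    )
                )
    return table


def scenario_ids() -> list[str]:
    return [s.scenario_id for s in build_scenario_table()]


def get_scenario(scenario_id: str) -> ScenarioSpec:
    """Look up a catalog scenario by its slug identifier."""
    for s in build_scenario_table():
        if s.scenario_id == scenario_id:
            return s
    raise KeyError(f"unknown scenario id {scenario_id!r}")


def run_experiment(
    scenario: ScenarioSpec, n_reps: int = 50, base_seed: int = 0
) -> list[RunResult]:
    """Replicate a scenario ``n_reps`` times with seeds base_seed .. base_seed+n-1.

    Replicates are mutually independent (one fresh RNG stream per seed), so
    the returned list — ordered by replicate index — does not depend on
    execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = []
    for r in range(n_reps):
        seed = base_seed + r
        try:
            results.append(run_simulation(scenario, seed))
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(
                f"replicate {r} (seed {seed}) of {scenario.scenario_id} failed"
            ) from exc
        log.debug("run %s replicate=%d seed=%d done", scenario.scenario_id, r, seed)
    return results
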