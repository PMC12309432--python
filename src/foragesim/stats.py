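"""Evaluation layer: the mobile-prey proportion and percentile bootstrap CIs.

The per-run statistic is the proportion of mobile prey among the active
predator's captures; values above 0.5 mean mobile prey were captured more
often than sedentary prey. Experiments (50 replicates per scenario by
default) are summarized by the sample mean with a 95% percentile bootstrap
confidence interval, and two treatments are called different when their
intervals do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .engine import RunResult

__all__ = [
    "ExperimentSummary",
    "proportion_mobile",
    "bootstrap_ci",
    "summarize_experiment",
    "cis_overlap",
]

RngLike = Union[None, int, np.random.Generator]


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-scenario aggregate: replicate proportions, mean and 95% CI."""

    scenario_id: str
    proportions: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int = 10_000

    @property
    def n(self) -> int:
        return len(self.proportions)


def proportion_mobile(result: RunResult) -> float:
    """Mobile captures over total captures, active predator's ledger only."""
    total = result.captured_mobile_active + result.captured_sedentary_active
    if total == 0:
        raise ValueError(
            "proportion undefined: the active predator captured no prey "
            f"(scenario {result.scenario_id}, seed {result.seed})"
        )
    return result.captured_mobile_active / total


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: RngLike = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: ``(mean, ci_low, ci_high)``.

    Draws ``n_boot`` resamples of the full sample size with replacement,
    takes each resample's mean, sorts the means, and reads the interval off
    the 1-based order statistics at ranks ``ceil(alpha/2 * n_boot)`` and
    ``ceil((1 - alpha/2) * n_boot)`` — ranks 250 and 9,750 at the defaults.
    The point estimate is the plain sample mean.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("values must be a non-empty 1-D collection")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = vals.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = vals[idx].mean(axis=1)
    means.sort()
    lo_rank = max(1, math.ceil(alpha / 2.0 * n_boot))
    hi_rank = max(1, math.ceil((1.0 - alpha / 2.0) * n_boot))
    return float(vals.mean()), float(means[lo_rank - 1]), float(means[hi_rank - 1])


def summarize_experiment(
    results: Iterable[RunResult],
    n_boot: int = 10_000,
    seed: RngLike = None,
    scenario_id: Optional[str] = None,
) -> ExperimentSummary:
    """Bootstrap summary of one replicated experiment.

    The bootstrap uses its own RNG stream (``seed``), kept separate from the
    simulation seeds so re-summarizing never perturbs the runs themselves.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    sid = scenario_id if scenario_id is not None else results[0].scenario_id
    props = tuple(proportion_mobile(r) for r in results)
    mean, lo, hi = bootstrap_ci(props, n_boot=n_boot, seed=seed)
    return ExperimentSummary(
        scenario_id=sid,
        proportions=props,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
    )


def cis_overlap(a: ExperimentSummary, b: ExperimentSummary) -> bool:
    """Closed-interval overlap of two 95% CIs; touching endpoints overlap.

    Non-overlap is the decision rule for calling two treatments different.
    """
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
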