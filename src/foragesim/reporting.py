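"""Reproducibility surface: run records, config overrides, summaries, figures.

Run-level output is a flat CSV (one row per replicate) from which every
summary quantity can be recomputed; summaries and figures are always derived
from that table, never from in-memory state, so each stage can be checked in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .engine import ArenaConfig, RunResult
from .scenarios import ScenarioSpec, build_scenario_table, run_experiment
from .stats import bootstrap_ci, proportion_mobile

__all__ = [
    "RUN_COLUMNS",
    "SUMMARY_COLUMNS",
    "ConfigError",
    "runs_to_frame",
    "frame_to_results",
    "write_runs_csv",
    "read_runs_csv",
    "summarize_runs",
    "load_config",
    "apply_overrides",
    "plot_pattern_summary",
    "reproduce_paper",
]

log = logging.getLogger(__name__)

RUN_COLUMNS = [
    "scenario_id",
    "replicate",
    "seed",
    "captured_mobile_active",
    "captured_sedentary_active",
    "captured_mobile_ambush",
    "reappeared_mobile",
    "reappeared_sedentary",
    "duration_steps",
    "termination",
    "proportion_mobile",
]

SUMMARY_COLUMNS = ["scenario_id", "n", "mean", "ci_low", "ci_high"]


def _package_version() -> str:
    try:
        return metadata.version("foragesim")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# Run records
# ---------------------------------------------------------------------------

def runs_to_frame(results: Iterable[RunResult]) -> pd.DataFrame:
    """Tabulate run results; replicate indices restart at 0 per scenario."""
    rows = []
    counters: dict[str, int] = {}
    for r in results:
        rep = counters.get(r.scenario_id, 0)
        counters[r.scenario_id] = rep + 1
        rows.append(
            {
                "scenario_id": r.scenario_id,
                "replicate": rep,
                "seed": r.seed,
                "captured_mobile_active": r.captured_mobile_active,
                "captured_sedentary_active": r.captured_sedentary_active,
                "captured_mobile_ambush": r.captured_mobile_ambush,
                "reappeared_mobile": r.reappeared_mobile,
                "reappeared_sedentary": r.reappeared_sedentary,
                "duration_steps": r.duration_steps,
                "termination": r.termination,
                "proportion_mobile": proportion_mobile(r),
            }
        )
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


def frame_to_results(df: pd.DataFrame) -> list[RunResult]:
    """Rebuild :class:`RunResult` objects from a runs table."""
    return [
        RunResult(
            scenario_id=row.scenario_id,
            seed=int(row.seed),
            captured_mobile_active=int(row.captured_mobile_active),
            captured_sedentary_active=int(row.captured_sedentary_active),
            captured_mobile_ambush=int(row.captured_mobile_ambush),
            reappeared_mobile=int(row.reappeared_mobile),
            reappeared_sedentary=int(row.reappeared_sedentary),
            duration_steps=int(row.duration_steps),
            termination=row.termination,
        )
        for row in df.itertuples(index=False)
    ]


def write_runs_csv(results: Iterable[RunResult], path: Union[str, Path]) -> pd.DataFrame:
    df = runs_to_frame(results)
    df.to_csv(path, index=False)
    return df


def read_runs_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RUN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"runs table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_runs(
    runs: pd.DataFrame,
    n_boot: int = 10_000,
    seed: Union[None, int, np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-scenario mean and 95% bootstrap CI of the mobile-prey proportion.

    Replicates that hit the ``max_steps`` safety cap never reached the stop
    condition; they are excluded from the summary with a loud warning (none
    occur under catalog scenarios, whose stop condition is always reachable).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sid, grp in runs.groupby("scenario_id", sort=False):
        ok = grp[grp["termination"] == "threshold_reached"]
        dropped = len(grp) - len(ok)
        if dropped:
            log.warning(
                "scenario %s: excluding %d/%d replicates that hit the step cap",
                sid, dropped, len(grp),
            )
        if len(ok) == 0:
            log.warning("scenario %s: no completed replicates; skipping", sid)
            continue
        mean, lo, hi = bootstrap_ci(
            ok["proportion_mobile"].to_numpy(), n_boot=n_boot, seed=rng
        )
        rows.append(
            {"scenario_id": sid, "n": len(ok), "mean": mean, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# Config overrides
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """A config file violated the override schema."""


_ARENA_KEYS = {"width", "height", "boundary_mode"}
_ARS_KEYS = {"duration", "trigger"}
_SCALAR_KEYS = {
    "n_mobile",
    "n_sedentary",
    "n_patches",
    "per_patch",
    "patch_radius",
    "directional_max_turn",
    "nondirectional_max_turn",
    "step_length",
    "reappearance_probability",
    "contested_active_share",
    "stop_threshold",
    "max_steps",
}


def load_config(path: Union[str, Path]) -> dict:
    """Load and validate engine overrides from a YAML or JSON file.

    Recognized keys: ``arena`` (width, height, boundary_mode), ``ars``
    (duration, trigger), and the scalar engine parameters (prey counts,
    patch geometry, turn limits, step length, reappearance probability,
    contested share, stop threshold, step cap). Unknown keys are rejected
    with their path; absent keys keep the catalog defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    overrides: dict = {}
    for key, value in data.items():
        if key == "arena":
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: 'arena' must be a mapping")
            bad = set(value) - _ARENA_KEYS
            if bad:
                raise ConfigError(f"{path}: unknown keys under 'arena': {sorted(bad)}")
            overrides["arena"] = dict(value)
        elif key == "ars":
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: 'ars' must be a mapping")
            bad = set(value) - _ARS_KEYS
            if bad:
                raise ConfigError(f"{path}: unknown keys under 'ars': {sorted(bad)}")
            if "duration" in value:
                overrides["ars_duration"] = int(value["duration"])
            if "trigger" in value:
                overrides["ars_trigger"] = str(value["trigger"])
        elif key in _SCALAR_KEYS:
            overrides[key] = value
        else:
            raise ConfigError(f"{path}: unknown key {key!r}")
    return overrides


def apply_overrides(scenario: ScenarioSpec, overrides: dict) -> ScenarioSpec:
    """A new scenario with validated overrides applied over the original."""
    kwargs = dict(overrides)
    arena_kwargs = kwargs.pop("arena", None)
    if arena_kwargs is not None:
        kwargs["arena"] = dataclasses.replace(scenario.arena, **arena_kwargs)
    out = dataclasses.replace(scenario, **kwargs)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_pattern_summary(
    summary: pd.DataFrame, pattern: str, path: Union[str, Path]
) -> None:
    """Two-panel mean ± 95% CI plot for one spatial pattern.

    Panel (a): active predator alone; panel (b): with an ambush predator.
    The dashed reference line at 0.5 marks no preference between prey types.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    for ax, comp, title in zip(
        axes, ("solo", "ambush"), ("(a) active predator only", "(b) with ambush predator")
    ):
        prefix = f"{pattern}/{comp}/"
        sub = summary[summary["scenario_id"].str.startswith(prefix)]
        labels = [sid[len(prefix):] for sid in sub["scenario_id"]]
        xs = np.arange(len(sub))
        yerr = np.vstack(
            [sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]]
        )
        ax.errorbar(xs, sub["mean"], yerr=yerr, fmt="o", capsize=3, color="black")
        ax.axhline(0.5, linestyle="--", color="tab:blue")
        ax.set_xticks(xs)
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_title(title)
    axes[0].set_ylabel("proportion of mobile prey captured")
    fig.suptitle(f"{pattern} sedentary-prey pattern")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Full reproduction driver
# ---------------------------------------------------------------------------

def reproduce_paper(
    base_seed: int = 0,
    reps: int = 50,
    out_dir: Union[str, Path] = "results",
    scenarios: Optional[Sequence[ScenarioSpec]] = None,
    overrides: Optional[dict] = None,
    n_boot: int = 10_000,
    make_figures: bool = True,
) -> pd.DataFrame:
    """Run the whole catalog and write ``runs.csv``, ``summary.csv``, figures.

    Each scenario gets its own disjoint block of replicate seeds derived
    from ``base_seed``. Returns the summary table (one row per scenario).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen_list = list(build_scenario_table() if scenarios is None else scenarios)
    if overrides:
        scen_list = [apply_overrides(s, overrides) for s in scen_list]
    version = _package_version()
    results: list[RunResult] = []
    for i, scen in enumerate(scen_list):
        seed0 = base_seed + i * max(reps, 1000)
        log.info(
            "running %s: reps=%d base_seed=%d foragesim=%s",
            scen.scenario_id, reps, seed0, version,
        )
        results.extend(run_experiment(scen, n_reps=reps, base_seed=seed0))
    runs = write_runs_csv(results, out / "runs.csv")
    summary = summarize_runs(runs, n_boot=n_boot, seed=base_seed)
    summary.to_csv(out / "summary.csv", index=False)
    if make_figures:
        for pattern in ("random", "clumped"):
            if summary["scenario_id"].str.startswith(pattern + "/").any():
                plot_pattern_summary(summary, pattern, out / f"fig_{pattern}.png")
    return summary
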