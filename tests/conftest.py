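import numpy as np
import pytest
from hypothesis import settings

from foragesim import ScenarioSpec, TreatmentSpec, run_experiment, scenario_ids
from foragesim.engine import ArenaConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_scenario(**kwargs) -> ScenarioSpec:
    """Small, fast scenario for unit tests; fields overridable per test."""
    defaults = dict(
        spatial_pattern="random",
        ambush_present=False,
        treatment=TreatmentSpec(),
        label="test",
        arena=ArenaConfig(width=11, height=11),
        n_mobile=5,
        n_sedentary=5,
        stop_threshold=3,
        max_steps=2_000,
    )
    defaults.update(kwargs)
    return ScenarioSpec(**defaults)


@pytest.fixture(scope="session")
def experiment_cache():
    """Memoized 50-replicate experiments, one fixed seed block per scenario.

    Shared across the acceptance tests so each catalog scenario is simulated
    at most once per session.
    """
    cache: dict[str, list] = {}
    ids = scenario_ids()

    def get(scenario_id: str, n_reps: int = 50):
        key = f"{scenario_id}:{n_reps}"
        if key not in cache:
            from foragesim import get_scenario

            base_seed = 20_000 + 1_000 * ids.index(scenario_id)
            cache[key] = run_experiment(
                get_scenario(scenario_id), n_reps=n_reps, base_seed=base_seed
            )
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
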