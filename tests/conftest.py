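import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mrmash import (
    CovarianceRecipe,
    ScenarioSpec,
    build_prior,
    fit_mrmash,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def fit_scenario(scenario, seed, n=600, p=50, r=10, n_causal=5, kind="data_driven",
                 missing_rate=0.0, **spec_kw):
    """Simulate one dataset under a scenario and fit the default model to it."""
    spec = ScenarioSpec(scenario=scenario, n=n, p=p, r=r, n_causal=n_causal,
                        missing_rate=missing_rate, seed=seed, **spec_kw)
    sim = simulate_dataset(spec)
    prior = build_prior(sim.train, CovarianceRecipe(kind=kind))
    fit = fit_mrmash(sim.train, prior)
    return sim, fit


@pytest.fixture(scope="session")
def scenario_a_fits():
    """Ten seeded equal-effects datasets with their fitted models (shared)."""
    return [fit_scenario("A", seed) for seed in range(1, 11)]
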