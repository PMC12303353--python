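import numpy as np
import pytest

from bcscreen import (
    BMI_SCENARIOS,
    CohortSpec,
    NaturalHistoryModel,
    RunConfig,
    ScreeningSimulation,
    generate_population,
    simulate_life_histories,
)


@pytest.fixture(scope="session")
def nh_model():
    return NaturalHistoryModel()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_histories(nh_model):
    """40k-woman normal-weight natural-history table (no screening)."""
    pop = generate_population(
        CohortSpec(1986, 2020, 40_000 // 35 + 1), BMI_SCENARIOS["normal"], seed=7
    )
    return simulate_life_histories(pop, nh_model, seed=11)


@pytest.fixture(scope="session")
def biennial_normal_results():
    """Moderate-scale paired run: biennial program, normal-weight scenario."""
    from dataclasses import replace

    cfg = RunConfig(
        cohorts=CohortSpec(1986, 2020, 1500),
        scenario=BMI_SCENARIOS["normal"],
    )
    return ScreeningSimulation(cfg).run(seed=42)
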