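import numpy as np
import pytest

from trio_mirnet import SimulationPlan, run_scenario
from trio_mirnet.simulate import simulate_all


@pytest.fixture(scope="session")
def small_plan() -> SimulationPlan:
    """A fast scenario: 12x12 catalogue, 12 planted sites, 4 antagonistic."""
    return SimulationPlan(
        n_mirna=12,
        n_transcript=12,
        n_planted_pairs=12,
        n_antagonistic=4,
        transcript_length=400,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_plan):
    return simulate_all(small_plan)


@pytest.fixture(scope="session")
def default_scenario():
    """The full reference scenario, run once per session (~20 s)."""
    return run_scenario(SimulationPlan(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
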