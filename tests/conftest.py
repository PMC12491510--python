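import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from latentdx.data_model import PopulationCounts, StudyData  # noqa: E402
from latentdx.mcmc import McmcConfig  # noqa: E402
from latentdx.priors import minimally_informative_set  # noqa: E402
from latentdx.synthetic_data import ScenarioSpec, simulate  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data():
    """A small, well-behaved two-population dataset with fixed counts."""
    return StudyData(
        populations=(
            PopulationCounts("Belgian", 36, 10, 16, 38),
            PopulationCounts("Swiss", 26, 9, 3, 4),
        )
    )


@pytest.fixture
def flat_priors():
    return minimally_informative_set(2)


@pytest.fixture
def short_config():
    """A reduced chain protocol for fast unit-level runs."""
    return McmcConfig(n_chains=2, burn_in=300, n_iterations=1500, seed=42)


@pytest.fixture
def simulated_medium():
    """A moderately sized simulated dataset at the study's truth."""
    spec = ScenarioSpec(
        population_sizes=(800, 800), population_ids=("A", "B"), seed=5
    )
    return simulate(spec)
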