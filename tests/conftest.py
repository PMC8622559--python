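import pytest

from fcmscreen.matching import MatchConfig
from fcmscreen.synthetic import SimulationConfig, SimulatedStudy, simulate_study


@pytest.fixture(scope="session")
def study() -> SimulatedStudy:
    """The reference synthetic screening study: triplicate injections,
    20 planted compounds + 20 shuffled decoys, 1 ppm / 5% noise, seed 1."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_study() -> SimulatedStudy:
    """A smaller, cheaper study for unit-level pipeline tests."""
    return simulate_study(SimulationConfig(seed=3, n_planted=10, n_decoys=10))


@pytest.fixture(scope="session")
def match_cfg() -> MatchConfig:
    return MatchConfig()
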