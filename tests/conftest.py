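import numpy as np
import pytest

from ecocrit.synthetic import ChangeRule, ScenarioConfig, generate_timeseries


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A light scenario used by unit tests (full-size runs live in the
    acceptance suite)."""
    return ScenarioConfig(
        seed=7,
        shape=(96, 96),
        n_zones=9,
        change_rules=(
            ChangeRule(("2005", "2010"), "degradation", "edge", 0.02),
            ChangeRule(("2010", "2015"), "expansion", "edge", 0.02),
        ),
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_timeseries(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
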