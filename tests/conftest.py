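import pytest

from coralbleach import Config, CoralBleachingModel
from coralbleach.forcing import ScenarioSpec, generate_forcing, preset

SCENARIOS = ("ambient_unshaded", "ambient_shaded", "heat_unshaded", "heat_shaded")


@pytest.fixture(scope="session")
def default_config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def ambient_spec() -> ScenarioSpec:
    return preset("ambient_unshaded", seed=1)


@pytest.fixture(scope="session")
def ambient_forcing(ambient_spec):
    return generate_forcing(ambient_spec)


@pytest.fixture(scope="session")
def scenario_runs(default_config):
    """The four-treatment factorial experiment at default calibration,
    shared 'weather' seed, dt = 1 min; reused across test modules."""
    runs = {}
    for name in SCENARIOS:
        model = CoralBleachingModel.from_scenario(name, default_config, seed=1)
        runs[name] = model.run()
    return runs
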