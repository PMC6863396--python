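import pytest
from hypothesis import HealthCheck, settings

from cellrear import (
    canonical_wiring,
    compile_model,
    default_initial_conditions,
    run_scenario,
    scenario_catalog,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def diagram():
    return canonical_wiring()


@pytest.fixture(scope="session")
def model(diagram):
    return compile_model(diagram)


@pytest.fixture(scope="session")
def ics(diagram):
    return default_initial_conditions(diagram)


class _ScenarioCache:
    """Runs each catalog scenario at most once per test session."""

    def __init__(self, model):
        self.model = model
        self._results = {}

    def __getitem__(self, name):
        if name not in self._results:
            self._results[name] = run_scenario(name, self.model)
        return self._results[name]

    def names(self):
        return [s.name for s in scenario_catalog()]


@pytest.fixture(scope="session")
def scenarios(model):
    return _ScenarioCache(model)
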