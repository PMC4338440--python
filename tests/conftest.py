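import pytest

from ftds.model import Scenario, calibrated_params, run_scenario


@pytest.fixture(scope="session")
def calibrated_summaries():
    """Steady states of all four Fj-action scenarios at the calibrated point.

    Session-scoped: the 23-cell integrations are shared by the model-property
    and acceptance tests.
    """
    return {
        scenario.value: run_scenario(scenario, calibrated_params())
        for scenario in Scenario
    }
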