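import numpy as np
import pytest

from pms_pipeline.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle7():
    """Default cohort at seed 7, shared read-only across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def clean_bundle():
    """Error-free cohort: no genotyping errors, no hemizygote no-calls."""
    cfg = SimulationConfig(seed=11, genotyping_error_rate=0.0, hemizygote_nocall_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
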