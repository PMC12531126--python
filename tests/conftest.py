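import pytest

from clonespread import PipelineConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort shared across tests (deterministic)."""
    cfg = SimulationConfig(seed=7, n_patients=4, depth=None, log2r_sd=0.0, baf_sd=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = SimulationConfig(seed=7, n_patients=4, depth=1000, log2r_sd=0.1, baf_sd=0.01)
    return simulate_cohort(cfg)


@pytest.fixture()
def clean_pipeline_config():
    return PipelineConfig()


@pytest.fixture()
def noisy_pipeline_config():
    return PipelineConfig(log2r_sd=0.1, baf_sd=0.01)
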