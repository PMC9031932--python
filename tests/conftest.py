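import pytest

from mycoderep.synthetic_data import ScenarioConfig, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scenario synthetic experiment shared across tests."""
    return generate_experiment(ScenarioConfig(), seed=11)


@pytest.fixture(scope="session")
def noise_free_experiment():
    config = ScenarioConfig(
        rt_jitter_sd=0.0, mz_jitter_sd=0.0, intensity_cv=0.0, ms2_peak_dropout=0.0
    )
    return generate_experiment(config, seed=11)
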