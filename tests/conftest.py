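import pytest

from sabmfi.synthetic_data import default_config, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A reduced default cohort: same panel and noise, fewer patients."""
    return default_config(seed=7, n_patients=12, samples_per_patient=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)
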