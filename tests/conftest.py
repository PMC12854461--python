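import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_table():
    """A noiseless multiplicative onset-rate table plus its truth."""
    from co2sense import genotype, synthetic

    df, truth = synthetic.simulate_rate_table(
        cis_effects=[1.0, 1.3, 0.9],
        cds_effects=[1.0, 0.7, 2.0],
        base_rate=100.0,
        noise_cv=0.0,
        n_per_cell=10,
        seed=0,
    )
    return genotype.OnsetRateTable(df), truth
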