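import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bsascan as b

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def causal_dataset():
    """A small simulated mapping experiment with a central causal locus."""
    config = b.SimConfig(chrom_lengths={"chr1": 5_000_000}, seed=42)
    design = b.CrossDesign(causal_chrom="chr1", causal_pos=2_500_000)
    sites, truth = b.simulate_experiment(design, config)
    return config, design, sites, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
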