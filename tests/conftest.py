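import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grnnfoa as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped 360-row dataset at 10% noise, seed 1."""
    return g.simulate(g.default_design(), g.default_surface(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Single-replicate 120-row dataset for fast fitting tests."""
    design = g.default_design()
    design.replicates = 1
    return g.simulate(design, g.default_surface(), seed=1)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Deployment models on the small dataset with a reduced tuning budget."""
    cfg = g.PipelineConfig(seed=1, foa_maxgen=30)
    return g.fit_pipeline(small_dataset, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
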