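import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigdistill import SimulationConfig, simulate_layer

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted():
    """A strongly separated 4-subtype layer with planted redundant blocks."""
    config = SimulationConfig(
        n_subtypes=4,
        samples_per_subtype=10,
        blocks_per_subtype=2,
        block_size=5,
        effect_size=5.0,
        within_block_correlation=0.9,
        n_noise_genes=100,
        seed=11,
    )
    expr, labels, truth = simulate_layer(config)
    return config, expr, labels, truth


@pytest.fixture()
def tiny_expr():
    """3 genes x 2 samples with hand-checkable geometry."""
    return pd.DataFrame(
        np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]]),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
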