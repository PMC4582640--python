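import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from digestnet import OtuTable, generate_community

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def community():
    """Default-size synthetic community (16 + 27 samples, 300 OTUs)."""
    return generate_community(seed=42)


@pytest.fixture(scope="session")
def small_community():
    """Reduced community for the more expensive pipeline paths."""
    return generate_community(
        n_samples_I=8, n_samples_II=8, n_otus=150, depth=800, seed=7,
        enforce_prevalence=False,
    )


@pytest.fixture()
def tiny_table():
    return OtuTable(
        pd.DataFrame(
            [[5, 0, 3], [1, 3, 2], [4, 4, 0]],
            index=["s1", "s2", "s3"],
            columns=["OTU1", "OTU2", "OTU3"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
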