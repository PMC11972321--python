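import numpy as np
import pytest
from hypothesis import settings

from cardiopcso import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cvd_schema():
    return synthetic.default_cvd_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-signal table reused across IGFS/classifier tests."""
    return synthetic.gen_tabular(
        n=2000,
        seed=7,
        imbalance_ratio=0.4,
        informative_names=["LVEF", "Age", "TC"],
        effect_sizes=[2.0, 1.5, 1.0],
    )


@pytest.fixture(scope="session")
def phantom_pairs():
    return synthetic.gen_phantoms(n=12, size=64, seed=3, noise_sigma=0.05)
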