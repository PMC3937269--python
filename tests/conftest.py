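import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """10 genes x 8 samples of independent Gaussians."""
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(8)]
    return pd.DataFrame(rng.standard_normal((10, 8)), index=genes, columns=samples)
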