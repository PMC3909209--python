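import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """A compact synthetic world: 8 years, 2 stations per bin."""
    from copetrend import synthetic

    return synthetic.default_truth(seed=42, years=(1980, 1987), gap_spec=(),
                                   stations_per_bin=2)


@pytest.fixture(scope="session")
def small_samples(small_truth):
    from copetrend import synthetic

    return synthetic.generate_abundance(small_truth)


def make_series(values, region="GOM", species="X", year0=1977):
    """Wrap a value array into an AbundanceSeries on a contiguous axis."""
    from copetrend.structural import AbundanceSeries

    n = len(values)
    assert n % 6 == 0
    data = pd.DataFrame(
        {
            "year": np.repeat(np.arange(n // 6), 6) + year0,
            "bin": np.tile(np.arange(1, 7), n // 6),
            "value": np.asarray(values, dtype=float),
            "n_samples": 1,
        }
    )
    return AbundanceSeries(species, region, data)
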