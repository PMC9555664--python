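import numpy as np
import pandas as pd
import pytest

from eggsync import morphometrics, synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One seeded scenario: (env frame, annual series dict, eggs frame)."""
    return synthetic.simulate_dataset(default_config)


@pytest.fixture()
def tiny_eggs_frame():
    """Three clutches in one year: one 2-egg gull clutch + two single-egg."""
    return pd.DataFrame(
        {
            "species": ["gull"] * 4,
            "year": [2002] * 4,
            "nest_id": ["n1", "n1", "n2", "n3"],
            "length_mm": [70.0, 71.0, 69.0, 72.0],
            "width_mm": [49.0, 48.5, 50.0, 47.0],
        }
    )


@pytest.fixture()
def aligned_series_pair():
    """Two 18-year series with a known shared sawtooth structure."""
    years = np.arange(2002, 2020)
    x = np.array([1.0, 3, 2, 4, 1, 5, 2, 6, 3, 7, 2, 8, 4, 9, 3, 10, 5, 11])
    a = morphometrics.AnnualSeries(
        "gull", years, x, np.ones(18, int), np.zeros(18)
    )
    b = morphometrics.AnnualSeries(
        "shearwater", years, 2 * x + 5, np.ones(18, int), np.zeros(18)
    )
    return a, b
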