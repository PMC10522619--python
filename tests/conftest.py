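import numpy as np
import pandas as pd
import pytest

from habforecast.preprocess import SensorSeries
from habforecast.synthetic_data import SyntheticConfig, generate

GRID_START = "2020-05-01"


def make_series(values, name="chl470", freq="10min", units="µg/L"):
    values = np.asarray(values, dtype=float)
    index = pd.date_range(GRID_START, periods=len(values), freq=freq)
    return SensorSeries(name, index, values, units)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def small_dataset():
    """10 days of 10-minute data with defects, for cross-module tests."""
    cfg = SyntheticConfig(n_samples=1440, n_dependent=30, seed=42)
    dataset, truth = generate(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def clean_small_dataset():
    """Defect-free small dataset (tiny channel noise keeps the design
    full-rank; the dependent series is an exact linear map of channels)."""
    cfg = SyntheticConfig(
        n_samples=1440,
        n_dependent=40,
        ar_sigma=1e-3,
        dependent_noise_sigma=0.0,
        missing_rate=0.0,
        outlier_rate=0.0,
        seed=7,
    )
    dataset, truth = generate(cfg)
    return dataset, truth
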