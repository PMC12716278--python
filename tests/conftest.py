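import numpy as np
import pandas as pd
import pytest

from chillmap import TemperatureSeries
from chillmap.datasets import BEETLE_PARAMS, THRIPS_PARAMS


@pytest.fixture(scope="session")
def thrips():
    return THRIPS_PARAMS


@pytest.fixture(scope="session")
def beetle():
    return BEETLE_PARAMS


def make_series(temps, start="2010-01-01", resolution_min=60, station="TST"):
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq=f"{resolution_min}min")
    return TemperatureSeries(station, idx, temps, resolution_min)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def station_network():
    """Small synthetic station network reused across weather/spatial tests."""
    from chillmap.synthetic import gen_station_network

    meta, series = gen_station_network(9, severity_gradient=1.5, seed=3, n_years=11)
    return meta, series
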