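import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from runoffmit.cn_hydrology import WeatherSeries
from runoffmit.muss import FieldPlot

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def plot_2018() -> FieldPlot:
    """Plot factors of the 2018 trial control (sandy loam, 9% slope)."""
    return FieldPlot(
        area_ha=0.0072,
        curve_number=80.0,
        k_factor=0.12,
        ls_factor=1.05,
        c_factor=7.17,
        p_factor=1.0,
        slope_pct=9.0,
    )


@pytest.fixture
def wet_weather() -> WeatherSeries:
    """A short, deterministic series with storms on both sides of Ia."""
    dates = pd.date_range("2018-05-01", periods=10, freq="D")
    precip = np.array([0.0, 5.0, 26.0, 0.0, 12.0, 40.0, 0.0, 3.0, 19.9, 55.0])
    return WeatherSeries(dates, precip)
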