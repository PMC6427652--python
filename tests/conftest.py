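import numpy as np
import pandas as pd
import pytest

from heatsignal.climate import FieldSeries, GridDefinition


@pytest.fixture
def grid2x2():
    return GridDefinition(lat=np.array([15.0, 15.75]), lon=np.array([75.0, 75.75]),
                          resolution=0.75)


@pytest.fixture
def make_field():
    """Factory for small daily field series on an n x m grid."""

    def _make(values, start="2010-01-01", variable="T_mean", grid=None):
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:  # single-pixel convenience
            values = values[:, None, None]
        if grid is None:
            nlat, nlon = values.shape[1:]
            grid = GridDefinition(
                lat=15.0 + 0.75 * np.arange(nlat),
                lon=75.0 + 0.75 * np.arange(nlon),
                resolution=0.75,
            )
        times = pd.date_range(start, periods=values.shape[0], freq="D")
        return FieldSeries(grid, times, variable, values)

    return _make
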