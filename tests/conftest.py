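import numpy as np
import pandas as pd
import pytest

from sandwin import DailyFlowSeries, HydrographParams, generate_rating_curve


def flow_series(start, values, station="test"):
    """Build a DailyFlowSeries from a start date and a value list."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailyFlowSeries(station, pd.Series(np.asarray(values, float), index=idx))


@pytest.fixture
def deterministic_params():
    """Noise-free bimodal hydrograph parameters (analytic skeleton)."""
    return HydrographParams(
        baseflow=30.0,
        early_rise_peak=100.0,
        late_rise_peak=200.0,
        noise_sigma=0.0,
        noise_rho=0.0,
        interannual_cv=0.0,
    )


@pytest.fixture
def power_curve():
    """Dense power-law rating table: stage = 0.1 * Q**0.5 over 1..5000 m³/s."""
    return generate_rating_curve(0.1, 0.5, 1.0, 5000.0, n_points=4000)
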