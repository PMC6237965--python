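import datetime as dt

import numpy as np
import pandas as pd
import pytest

from coldsoil.rasters import GridGeometry, RasterScene
from coldsoil.sensors import SensorSeries
from coldsoil.synthetic import CampaignConfig, generate_campaign


def hourly_series(values, start="2014-01-01", plot="P1", sensor="S1", variable="TS"):
    idx = pd.date_range(start, periods=len(values), freq="h", tz="UTC")
    return SensorSeries(plot, sensor, variable, pd.Series(np.asarray(values, float), index=idx))


def make_daily(dates, rng_vals, max_vals, mean_vals=None):
    """Daily-summary frame from explicit ranges and maxima."""
    rng_vals = np.asarray(rng_vals, float)
    max_vals = np.asarray(max_vals, float)
    if mean_vals is None:
        mean_vals = max_vals - rng_vals / 2
    return pd.DataFrame(
        {
            "mean": np.asarray(mean_vals, float),
            "min": max_vals - rng_vals,
            "max": max_vals,
            "range": rng_vals,
            "n_hours": 24,
        },
        index=pd.Index(dates, name="date"),
    )


def dates_from(start: dt.date, n: int):
    return [start + dt.timedelta(days=i) for i in range(n)]


def toy_scene(vals, date=dt.date(2014, 1, 15), tier="fine", qa=None, cell=30.0):
    vals = np.asarray(vals, dtype=np.int16)
    g = GridGeometry(0.0, vals.shape[0] * cell, cell, vals.shape[0], vals.shape[1])
    return RasterScene(date=date, tier=tier, geometry=g,
                       bands={b: vals.copy() for b in ("green", "red", "nir", "swir2")}, qa=qa)


@pytest.fixture(scope="session")
def noise_free_campaign():
    cfg = CampaignConfig(noise_sd_ts=0.0, noise_sd_ta=0.0, seed=11)
    return generate_campaign(cfg)


@pytest.fixture(scope="session")
def noisy_campaign():
    return generate_campaign(CampaignConfig(seed=5))
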