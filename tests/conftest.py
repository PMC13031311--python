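"""Shared fixtures: a tiny simulated world small enough for fast unit tests."""
import logging

import numpy as np
import pandas as pd
import pytest

from periclim.climatology import (StationSeries, compute_deviations,
                                  fit_station_climatology)
from periclim.linkage import AnomalyField, LinkageConfig
from periclim.synthetic import SimConfig, simulate_cohort, simulate_station_network

logging.getLogger("periclim").setLevel(logging.ERROR)


def make_station(station_id="S1", lat=52.0, lon=-1.0, dates=None, means=None,
                 diurnal=6.0):
    """Build a StationSeries from daily mean temperatures."""
    dates = pd.DatetimeIndex(dates)
    means = np.asarray(means, dtype=float)
    return StationSeries(
        station_id=station_id, lat=lat, lon=lon,
        records=pd.DataFrame({"date": dates,
                              "tmin": means - diurnal / 2,
                              "tmax": means + diurnal / 2}),
    )


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(
        n_stations=6, n_participants=400, n_areas=4,
        bbox=(51.0, 53.0, -2.5, 0.5), year_range=(1950, 1956),
        gestation_sd=0.0, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    """Full simulated world: network, anomaly field, cohort, truth."""
    network = simulate_station_network(tiny_config)
    models = [fit_station_climatology(s, tiny_config.year_range)
              for s in network.stations]
    deviations = [compute_deviations(s, m)
                  for s, m in zip(network.stations, models)]
    coords = {s.station_id: (s.lat, s.lon) for s in network.stations}
    field = AnomalyField.from_deviations(deviations, coords)
    cohort, truth = simulate_cohort(tiny_config, network)
    return {"network": network, "models": models, "field": field,
            "cohort": cohort, "truth": truth, "config": tiny_config,
            "linkage": LinkageConfig()}
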