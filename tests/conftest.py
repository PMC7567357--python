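import numpy as np
import pandas as pd
import pytest

from covisit import AnalysisConfig


def make_stations(coords, valid=None, crop=None):
    """Station table from {station_id: (x, y)}."""
    ids = list(coords)
    return pd.DataFrame({
        "site": "S",
        "station_id": ids,
        "x_m": [coords[i][0] for i in ids],
        "y_m": [coords[i][1] for i in ids],
        "crop_size": crop if crop is not None else [100] * len(ids),
        "active_start": pd.Timestamp("2019-05-01 00:00:00"),
        "active_end": pd.Timestamp("2019-07-01 00:00:00"),
        "valid": valid if valid is not None else [True] * len(ids),
    })


def make_visits(rows):
    """Visit table from (station_id, species, iso_time[, interaction]) rows."""
    records = []
    for row in rows:
        station, species, time = row[:3]
        interaction = row[3] if len(row) > 3 else 0
        t = pd.Timestamp(time)
        records.append((station, species, t, t, 1, interaction))
    return pd.DataFrame(records, columns=["station_id", "species",
                                          "start_time", "end_time",
                                          "n_records", "interaction"])


@pytest.fixture
def config():
    return AnalysisConfig(seed=7, iterations=50, bootstrap_resamples=200)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def four_stations():
    return make_stations({"A": (0, 0), "B": (150, 0),
                          "C": (80, 0), "D": (400, 300)})
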