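"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (O(n^2) scans, hand-rolled IRLS)
and shares no code with the implementation under test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def brute_observed_lags(visits: pd.DataFrame, sp_first: str, sp_second: str,
                        max_lag_hours: float,
                        include_zero: bool = False) -> list[float]:
    """All-pairs scan: first later same-station visit of sp_second."""
    lags = []
    for _, row in visits[visits["species"] == sp_first].iterrows():
        cands = visits[(visits["species"] == sp_second)
                       & (visits["station_id"] == row["station_id"])]
        if include_zero:
            later = cands[cands["start_time"] >= row["start_time"]]
        else:
            later = cands[cands["start_time"] > row["start_time"]]
        if len(later) == 0:
            continue
        lag = (later["start_time"].min() - row["start_time"]) \
            / pd.Timedelta(hours=1)
        if lag <= max_lag_hours:
            lags.append(float(lag))
    return sorted(lags)


def brute_spatial_null_lags(visits: pd.DataFrame, sp_first: str,
                            sp_second: str, stations: pd.DataFrame,
                            min_distance_m: float,
                            max_lag_hours: float) -> list[float]:
    """All ordered station pairs beyond the distance threshold."""
    st = stations[stations["valid"]].set_index("station_id")
    lags = []
    for a in st.index:
        for b in st.index:
            if a == b:
                continue
            d = np.hypot(st.loc[a, "x_m"] - st.loc[b, "x_m"],
                         st.loc[a, "y_m"] - st.loc[b, "y_m"])
            if d <= min_distance_m:
                continue
            firsts = visits[(visits["species"] == sp_first)
                            & (visits["station_id"] == a)]
            seconds = visits[(visits["species"] == sp_second)
                             & (visits["station_id"] == b)]
            for _, row in firsts.iterrows():
                later = seconds[seconds["start_time"] > row["start_time"]]
                if len(later) == 0:
                    continue
                lag = (later["start_time"].min() - row["start_time"]) \
                    / pd.Timedelta(hours=1)
                if lag <= max_lag_hours:
                    lags.append(float(lag))
    return sorted(lags)


def brute_cluster_count(times_minutes: list[float], window_minutes: float) -> int:
    """Sequential scan: count visits for one (station, species) stream."""
    if not times_minutes:
        return 0
    times = sorted(times_minutes)
    n = 1
    for prev, cur in zip(times, times[1:]):
        if cur - prev > window_minutes:
            n += 1
    return n


def irls_poisson(y: np.ndarray, x: np.ndarray, offset: np.ndarray | None = None,
                 tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Hand-rolled IRLS for a Poisson log-link GLM; returns coefficients.

    ``x`` is the design matrix including the intercept column.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    off = np.zeros_like(y) if offset is None else np.asarray(offset, float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta + off
        mu = np.exp(eta)
        w = mu
        z = eta - off + (y - mu) / mu
        wx = x * w[:, None]
        beta_new = np.linalg.solve(x.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def pearson_r(x, y) -> float:
    """Textbook product-moment formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def random_visits(rng: np.random.Generator, n_max: int = 200,
                  n_stations: int | None = None,
                  n_species: int | None = None) -> pd.DataFrame:
    """A random small visit table for oracle comparisons."""
    if n_stations is None:
        n_stations = int(rng.integers(2, 11))
    if n_species is None:
        n_species = int(rng.integers(2, 6))
    n = int(rng.integers(1, n_max + 1))
    start = pd.Timestamp("2019-05-01")
    times = start + pd.to_timedelta(
        np.round(rng.uniform(0, 10 * 24 * 3600, n)), unit="s")
    df = pd.DataFrame({
        "station_id": rng.choice([f"P{i:02d}" for i in range(n_stations)], n),
        "species": rng.choice([f"sp{i}" for i in range(n_species)], n),
        "start_time": times,
        "end_time": times,
        "n_records": 1,
        "interaction": rng.integers(0, 2, n),
    })
    return df.sort_values(["station_id", "species", "start_time"],
                          kind="mergesort").reset_index(drop=True)


def random_station_table(rng: np.random.Generator, station_ids,
                         side_m: float = 500.0) -> pd.DataFrame:
    xy = rng.uniform(0, side_m, size=(len(station_ids), 2))
    return pd.DataFrame({
        "site": "S",
        "station_id": list(station_ids),
        "x_m": xy[:, 0],
        "y_m": xy[:, 1],
        "crop_size": rng.integers(10, 500, len(station_ids)),
        "active_start": pd.Timestamp("2019-05-01"),
        "active_end": pd.Timestamp("2019-07-01"),
        "valid": True,
    })
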