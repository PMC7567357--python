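"""Detection and station tables, visit clustering, sampling effort.

A *detection* is one camera photo: station, species, timestamp and an
interaction flag (1 = the animal physically contacts the focal plant,
most likely eating fruit; 0 = present without contact). A *visit* is a
maximal chain of same-species detections at one station in which every
gap between consecutive photos is at most the independence window;
a gap strictly greater than the window starts a new visit. Clustering
is per (station, species): other species' photos never split or join a
visit.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SCOPE_INTERACTIONS
from .errors import ValidationError

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ("site", "station_id", "species", "timestamp", "interaction")
STATION_COLUMNS = (
    "site",
    "station_id",
    "x_m",
    "y_m",
    "crop_size",
    "active_start",
    "active_end",
    "valid",
)
VISIT_COLUMNS = (
    "station_id",
    "species",
    "start_time",
    "end_time",
    "n_records",
    "interaction",
)


def _rename(df: pd.DataFrame, expected: Sequence[str], column_map: Mapping | None,
            path) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_stations(path, column_map: Mapping | None = None) -> pd.DataFrame:
    """Read the station table (one row per camera/plant).

    Expected columns: site, station_id, x_m, y_m, crop_size,
    active_start, active_end (ISO 8601), valid (0/1). ``column_map``
    maps canonical names to the file's own header names.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    df = _rename(df, STATION_COLUMNS, column_map, path)
    for col in ("active_start", "active_end"):
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: bad timestamp in {col}: {exc}") from exc
    df["valid"] = df["valid"].astype(int).astype(bool)
    df["crop_size"] = pd.to_numeric(df["crop_size"])
    if (df["crop_size"] < 0).any():
        raise ValidationError(f"{path}: negative crop_size")
    if df["station_id"].duplicated().any():
        dupes = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise ValidationError(f"{path}: duplicate station ids {dupes}")
    bad = df["active_end"] < df["active_start"]
    if bad.any():
        ids = df.loc[bad, "station_id"].tolist()
        raise ValidationError(f"{path}: active_end before active_start at {ids}")
    xy = df[["x_m", "y_m"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValidationError(f"{path}: non-finite station coordinates")
    return df.reset_index(drop=True)


def read_detections(path, stations: pd.DataFrame,
                    column_map: Mapping | None = None,
                    validate_activity: bool = False) -> pd.DataFrame:
    """Read detections, drop rows at invalid (discarded) cameras.

    Rows referencing stations absent from ``stations`` raise a
    :class:`ValidationError` listing the offending ids; rows at stations
    flagged ``valid = 0`` are dropped with a logged count. The result is
    sorted by (station_id, species, timestamp).
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    df = _rename(df, DETECTION_COLUMNS, column_map, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed timestamp: {exc}") from exc
    df["interaction"] = pd.to_numeric(df["interaction"])
    if not df["interaction"].isin([0, 1]).all():
        raise ValidationError(f"{path}: interaction flag must be 0 or 1")
    known = set(stations["station_id"])
    unknown = sorted(set(df["station_id"]) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown station ids {unknown}")
    invalid = set(stations.loc[~stations["valid"], "station_id"])
    at_invalid = df["station_id"].isin(invalid)
    if at_invalid.any():
        logger.info("dropped %d detections at %d discarded stations",
                    int(at_invalid.sum()), len(invalid & set(df["station_id"])))
        df = df[~at_invalid]
    if validate_activity:
        st = stations.set_index("station_id")
        start = st["active_start"].reindex(df["station_id"]).to_numpy()
        end = st["active_end"].reindex(df["station_id"]).to_numpy()
        ts = df["timestamp"].to_numpy()
        outside = (ts < start) | (ts > end)
        if outside.any():
            rows = df.index[outside].tolist()[:10]
            raise ValidationError(
                f"{path}: {int(outside.sum())} detections outside the camera "
                f"active interval (first rows: {rows})")
    return (df.sort_values(["station_id", "species", "timestamp"], kind="mergesort")
              .reset_index(drop=True))


def cluster_visits(detections: pd.DataFrame, window_minutes: float) -> pd.DataFrame:
    """Chain-cluster detections into independent visits.

    A detection starts a new visit iff its gap to the immediately
    previous detection of the same species at the same station strictly
    exceeds ``window_minutes`` (a gap of exactly the window continues
    the visit). The visit's interaction flag is the max over member
    photos; its start_time (the triggering photo) is the timestamp used
    by all downstream lag computations.
    """
    if window_minutes <= 0:
        raise ValidationError("window_minutes must be > 0")
    if len(detections) == 0:
        return pd.DataFrame(columns=VISIT_COLUMNS)
    df = detections.sort_values(["station_id", "species", "timestamp"],
                                kind="mergesort")
    same_group = (df["station_id"].eq(df["station_id"].shift())
                  & df["species"].eq(df["species"].shift()))
    gap = df["timestamp"].diff()
    window = pd.Timedelta(minutes=window_minutes)
    new_visit = ~same_group | (gap > window)
    visit_id = new_visit.cumsum()
    visits = df.groupby(visit_id).agg(
        station_id=("station_id", "first"),
        species=("species", "first"),
        start_time=("timestamp", "first"),
        end_time=("timestamp", "last"),
        n_records=("timestamp", "size"),
        interaction=("interaction", "max"),
    )
    return visits.reset_index(drop=True)


def effort_days(stations: pd.DataFrame) -> pd.Series:
    """Camera active days per station: (active_end − active_start) in days."""
    bad = stations["active_end"] < stations["active_start"]
    if bad.any():
        ids = stations.loc[bad, "station_id"].tolist()
        raise ValidationError(f"active_end before active_start at {ids}")
    days = (stations["active_end"] - stations["active_start"]) / pd.Timedelta(days=1)
    return pd.Series(days.to_numpy(float), index=stations["station_id"].to_numpy(),
                     name="effort_days")


def scope_visits(visits: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Restrict a visit table to the active dataset scope."""
    if scope == SCOPE_INTERACTIONS:
        return visits[visits["interaction"] == 1].reset_index(drop=True)
    return visits


def write_visits(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, index=False, columns=list(VISIT_COLUMNS))


def read_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str},
                     parse_dates=["start_time", "end_time"])
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df
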