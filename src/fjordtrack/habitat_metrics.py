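"""Habitat classification, sea-ice joining, movement metrics and time budgets.

Works on hourly-track DataFrames (``animal_id, timestamp, lon, lat``)
produced by :mod:`fjordtrack.track_processing`.

Habitat classes, in precedence order:

1. ``Glacier-Fronts`` — within the distance threshold of a glacier front;
2. ``Fjords`` — inside a fjord polygon (and beyond the glacier threshold);
3. ``Coastal`` — within the threshold of the coastline, not 1 or 2;
4. ``At-Sea`` — everything else.

"Less than" is strict: a point at exactly the threshold distance falls
through to the next rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError
from .geospatial import (
    CoastModel,
    LocalProjection,
    _read_geojson_layer,
    distances_to_geometry_km,
    geodesic_distance_arrays,
    points_in_fjord,
    write_geojson_layer,
)

__all__ = [
    "HABITAT_CLASSES",
    "ICE_TYPES",
    "HabitatConfig",
    "IceField",
    "movement_metrics",
    "classify_habitat",
    "assign_ice_type",
    "occupancy_series",
    "day_index",
    "summarize_time_budget",
]

HABITAT_CLASSES = ("Glacier-Fronts", "Fjords", "Coastal", "At-Sea")

ICE_TYPES = (
    "Fast ice",
    "Very Close Drift Ice",
    "Close Drift Ice",
    "Open Drift Ice",
    "Very Open Drift Ice",
    "Open Water",
)

#: season anchor: day indices count whole days since the most recent 7 July
SEASON_ANCHOR = (7, 7)


@dataclass(frozen=True)
class HabitatConfig:
    radius_threshold_km: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_threshold_km <= 0:
            raise ConfigurationError("radius_threshold_km must be positive")


@dataclass(frozen=True)
class IceField:
    """Dated set of typed sea-ice polygons."""

    date: pd.Timestamp
    polygons: tuple  # of (ice_type, shapely polygon)

    def __post_init__(self) -> None:
        for ice_type, _ in self.polygons:
            if ice_type not in ICE_TYPES:
                raise ConfigurationError(f"unknown ice type {ice_type!r}")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "IceField":
        """Read ``ice_YYYYMMDD.geojson`` with a ``type`` property per feature."""
        path = Path(path)
        m = re.match(r"ice_(\d{8})", path.stem)
        if not m:
            raise ConfigurationError(f"ice file name must be ice_YYYYMMDD.geojson, got {path.name}")
        import json

        with open(path) as fh:
            doc = json.load(fh)
        polys = []
        for feat in doc.get("features", []):
            polys.append((feat["properties"]["type"], shapely.geometry.shape(feat["geometry"])))
        return cls(date=pd.Timestamp(m.group(1)), polygons=tuple(polys))

    def to_geojson(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"ice_{self.date.strftime('%Y%m%d')}.geojson"
        write_geojson_layer(
            path,
            [g for _, g in self.polygons],
            [{"type": t} for t, _ in self.polygons],
        )
        return path


# ---------------------------------------------------------------------
# Movement metrics
# ---------------------------------------------------------------------


def movement_metrics(hourly: pd.DataFrame, step: pd.Timedelta = pd.Timedelta(hours=1)) -> pd.DataFrame:
    """Attach ``speed`` (m/s) and ``turn`` (deg, 0–180) columns.

    Speed at row i is the distance from the previous location divided by
    elapsed time; the turn is the unsigned deviation between the incoming
    and outgoing headings (0 = straight ahead, 180 = full reversal). Both
    are only defined between consecutive rows exactly ``step`` apart
    within an animal; elsewhere they are NaN.
    """
    out = hourly.copy()
    out["speed"] = np.nan
    out["turn"] = np.nan
    for _, sub in out.groupby("animal_id", sort=False):
        idx = sub.index
        t = pd.DatetimeIndex(sub["timestamp"])
        lon = sub["lon"].to_numpy()
        lat = sub["lat"].to_numpy()
        if len(sub) < 2:
            continue
        dt = (t[1:] - t[:-1]) == step
        d = geodesic_distance_arrays(lon[:-1], lat[:-1], lon[1:], lat[1:])
        speed = np.full(len(sub), np.nan)
        speed[1:][dt] = d[dt] / step.total_seconds()
        proj = LocalProjection.for_bounds(lon, lat)
        x, y = proj.forward(lon, lat)
        heading = np.arctan2(np.diff(x), np.diff(y))  # bearing-like, radians
        turn = np.full(len(sub), np.nan)
        if len(sub) >= 3:
            dh = np.degrees(np.abs(np.angle(np.exp(1j * (heading[1:] - heading[:-1])))))
            ok = dt[:-1] & dt[1:]
            turn[1:-1][ok] = dh[ok]
        out.loc[idx, "speed"] = speed
        out.loc[idx, "turn"] = turn
    return out


# ---------------------------------------------------------------------
# Habitat classification
# ---------------------------------------------------------------------


def classify_habitat(
    hourly: pd.DataFrame,
    model: CoastModel,
    cfg: HabitatConfig | None = None,
    projection: LocalProjection | None = None,
) -> pd.DataFrame:
    """Attach ``habitat``, ``dist_coast`` and ``dist_glacier`` (km) columns."""
    cfg = cfg or HabitatConfig()
    if not model.glacier_fronts or not model.fjords:
        raise ConfigurationError(
            f"CoastModel({model.epoch_label!r}) needs glacier_fronts and fjords layers for classification"
        )
    out = hourly.copy()
    if len(out) == 0:
        out["dist_coast"] = pd.Series(dtype=float)
        out["dist_glacier"] = pd.Series(dtype=float)
        out["habitat"] = pd.Series(dtype=str)
        return out
    lon = out["lon"].to_numpy()
    lat = out["lat"].to_numpy()
    proj = projection or LocalProjection.for_bounds(lon, lat)
    dist_coast = distances_to_geometry_km(lon, lat, model.coastline_union, proj)
    dist_glacier = distances_to_geometry_km(lon, lat, model.glacier_union, proj)
    in_fjord = points_in_fjord(lon, lat, model)
    thr = cfg.radius_threshold_km
    habitat = np.where(
        dist_glacier < thr,
        "Glacier-Fronts",
        np.where(in_fjord, "Fjords", np.where(dist_coast < thr, "Coastal", "At-Sea")),
    )
    out["dist_coast"] = dist_coast
    out["dist_glacier"] = dist_glacier
    out["habitat"] = habitat
    return out


# ---------------------------------------------------------------------
# Sea ice
# ---------------------------------------------------------------------


def assign_ice_type(hourly: pd.DataFrame, fields: list[IceField]) -> pd.DataFrame:
    """Attach an ``ice_type`` column from the nearest-dated ice field.

    Ties between two equally near field dates resolve to the earlier
    field; locations outside all typed polygons are ``Open Water``.
    """
    if not fields:
        raise ConfigurationError("assign_ice_type requires at least one IceField")
    fields = sorted(fields, key=lambda f: f.date)
    field_days = np.array([f.date.normalize().value for f in fields], dtype="int64")
    out = hourly.copy()
    if len(out) == 0:
        out["ice_type"] = pd.Series(dtype=str)
        return out
    days = pd.DatetimeIndex(out["timestamp"]).normalize().values.astype("int64")
    # nearest field per location, earlier date on ties
    diffs = np.abs(days[:, None] - field_days[None, :])
    nearest = np.argmin(diffs, axis=1)  # argmin takes the first (earlier) on ties
    ice = np.full(len(out), "Open Water", dtype=object)
    pts = shapely.points(out["lon"].to_numpy(), out["lat"].to_numpy())
    for fi in np.unique(nearest):
        sel = nearest == fi
        # check denser ice first so overlapping bands resolve to the densest type
        for ice_type in ICE_TYPES[:-1]:
            for t, poly in fields[fi].polygons:
                if t != ice_type:
                    continue
                undecided = sel & (ice == "Open Water")
                if not undecided.any():
                    break
                hit = shapely.covers(poly, pts[undecided])
                ice[np.nonzero(undecided)[0][hit]] = t
    out["ice_type"] = ice
    return out


# ---------------------------------------------------------------------
# Seasonal indexing & occupancy
# ---------------------------------------------------------------------


def day_index(timestamps) -> np.ndarray:
    """Whole days since the most recent 7 July at or before each timestamp."""
    ts = pd.DatetimeIndex(timestamps)
    anchor_year = np.where(
        (ts.month > SEASON_ANCHOR[0]) | ((ts.month == SEASON_ANCHOR[0]) & (ts.day >= SEASON_ANCHOR[1])),
        ts.year,
        ts.year - 1,
    )
    anchors = pd.to_datetime(
        {"year": anchor_year, "month": SEASON_ANCHOR[0], "day": SEASON_ANCHOR[1]}
    )
    return ((ts.normalize() - pd.DatetimeIndex(anchors)).days).to_numpy()


def occupancy_series(classified: pd.DataFrame) -> pd.DataFrame:
    """One-hot habitat indicators plus ``day_index`` per hourly location."""
    out = classified.copy()
    for habitat in HABITAT_CLASSES:
        out[f"occ_{habitat}"] = (out["habitat"] == habitat).astype(int)
    out["day_index"] = day_index(out["timestamp"])
    return out


def summarize_time_budget(
    classified: pd.DataFrame,
    grouping: str = "period",
    column: str = "habitat",
) -> pd.DataFrame:
    """Proportion of hourly locations per class, by group.

    ``grouping`` is one of ``"period"``, ``"month"``, ``"animal"`` or
    ``"none"`` (pooled). For months the table carries ``n_individuals``,
    the number of animals with at least one location in the month.
    ``column`` may be ``"habitat"`` or ``"ice_type"``.
    """
    levels = HABITAT_CLASSES if column == "habitat" else ICE_TYPES
    df = classified.copy()
    if grouping == "period":
        keys = ["period"]
    elif grouping == "month":
        df["month"] = pd.DatetimeIndex(df["timestamp"]).to_period("M").astype(str)
        keys = ["month"]
        if "period" in df.columns:
            keys = ["period", "month"]
    elif grouping == "animal":
        keys = ["animal_id"]
        if "period" in df.columns:
            keys = ["period", "animal_id"]
    elif grouping == "none":
        df["_all"] = "all"
        keys = ["_all"]
    else:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    rows = []
    for key_vals, sub in df.groupby(keys, sort=True):
        if len(sub) == 0:
            continue
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        row = dict(zip(keys, key_vals))
        row["n_locations"] = len(sub)
        row["n_individuals"] = sub["animal_id"].nunique()
        counts = sub[column].value_counts()
        for level in levels:
            row[level] = counts.get(level, 0) / len(sub)
        rows.append(row)
    out = pd.DataFrame(rows)
    if "_all" in out.columns:
        out = out.drop(columns="_all")
    return out
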