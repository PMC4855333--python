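"""Readers and writers for the package's delimited-text formats.

Tracks arrive as CSV/TSV with columns ``id, timestamp, x_km, y_km[, quality]``
(ISO-8601 timestamps, projected kilometre coordinates). All outputs are
comma-separated UTF-8 with ISO-8601 timestamps. Calving-ground polygons are
read from GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fpt import FptProfile
from .pipeline import BreakEvent, MigrationRecord
from .trajectory import RegularPath, Track

__all__ = [
    "read_tracks",
    "write_regular_path",
    "write_fpt_profile",
    "read_fpt_profile",
    "write_events",
    "write_records",
    "read_polygon",
]

TRACK_COLUMNS = ["id", "timestamp", "x_km", "y_km"]


def read_tracks(path, sep: str = ",") -> list[Track]:
    """Read one or more animals' relocations from a delimited file."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file lacks columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for animal, sub in df.groupby("id", sort=True):
        cols = {"timestamp": sub["timestamp"], "x": sub["x_km"], "y": sub["y_km"]}
        if "quality" in sub.columns:
            cols["quality"] = sub["quality"].astype(str)
        out.append(Track(str(animal), pd.DataFrame(cols)))
    return out


def write_regular_path(path_obj: RegularPath, dest) -> None:
    df = path_obj.data.rename(columns={"x": "x_km", "y": "y_km"}).copy()
    df.insert(0, "id", path_obj.animal_id)
    df.to_csv(dest, index=False)


def write_fpt_profile(profile: FptProfile, dest) -> None:
    df = profile.to_frame().rename(columns={"x": "x_km", "y": "y_km"})
    df.insert(0, "id", profile.path.animal_id)
    df.to_csv(dest, index=False)


def read_fpt_profile(src) -> FptProfile:
    df = pd.read_csv(src, parse_dates=["timestamp"])
    animal = str(df["id"].iloc[0]) if "id" in df.columns else ""
    interval_h = (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]) / pd.Timedelta(hours=1)
    pdata = pd.DataFrame(
        {
            "timestamp": df["timestamp"],
            "x": df["x_km"],
            "y": df["y_km"],
            "is_interpolated": df.get("is_interpolated", False),
            "gap_h": df.get("gap_h", 0.0),
        }
    )
    path = RegularPath(pdata, float(interval_h), animal)
    return FptProfile(path, float(df["radius_km"].iloc[0]), df["fpt_days"].to_numpy())


def events_frame(events: list[BreakEvent], animal_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": animal_id,
                "kind": e.kind,
                "start_date": e.start_date,
                "end_date": e.end_date,
                "mean_fpt_days": e.mean_fpt,
                "duration_days": e.duration,
                "complete": e.complete,
                "detection_route": e.detection_route,
            }
            for e in events
        ]
    )


def write_events(events: list[BreakEvent], dest, animal_id: str = "") -> None:
    events_frame(events, animal_id).to_csv(dest, index=False)


def write_records(records: list[MigrationRecord], dest) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "year": r.year,
            "departure_date": r.departure_date,
            "arrival_date": r.arrival_date,
            "complete": r.complete,
            "notes": r.notes,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(dest, index=False)


def read_polygon(src):
    """Load the first polygon found in a GeoJSON file as a shapely geometry."""
    from shapely.geometry import shape

    with open(src) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [gj["geometry"]]
    else:
        geoms = [gj]
    polys = [g for g in geoms if g and g.get("type") in ("Polygon", "MultiPolygon")]
    if not polys:
        raise ValueError("no polygon found in GeoJSON")
    return shape(polys[0])
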