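"""Relocation tracks: quality/speed filtering and 12-h regularization.

Satellite relocation data (e.g. ARGOS collars) arrive irregularly — typically
one fix every few days, sometimes several per day — with a per-fix quality
class. Downstream first-passage-time analysis assumes a path sampled at a
constant interval with straight constant-speed legs between real fixes, so
this module (1) keeps the best fix per transmission period, (2) removes fixes
implying unrealistic travel speeds, and (3) linearly interpolates the track
onto a regular 12-h grid anchored at the first fix.

Coordinates must already be projected, in kilometres; no CRS handling is done
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "RegularPath",
    "AnnualPath",
    "TrackUnusableError",
    "filter_track",
    "regularize",
    "split_annual",
]

#: ARGOS location classes from most to least accurate; lower rank is better.
ARGOS_QUALITY_RANK = {"3": 0, "2": 1, "1": 2, "0": 3, "A": 4, "B": 5, "Z": 6}


class TrackUnusableError(ValueError):
    """Raised when filtering leaves too few locations to build a path."""


@dataclass
class Track:
    """Ordered relocations of a single animal.

    ``data`` columns: ``timestamp`` (datetime64), ``x``, ``y`` (km, projected)
    and optionally ``quality`` (ARGOS class as string).
    """

    animal_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        if not df["timestamp"].is_monotonic_increasing:
            df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
        for col in ("x", "y"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in column {col!r}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RegularPath:
    """A track resampled on a fixed time grid.

    ``data`` columns: ``timestamp``, ``x``, ``y``, ``is_interpolated`` (False
    exactly at points carrying a real fix) and ``gap_h`` (length in hours of
    the inter-fix gap the point lies in; 0 at real fixes).
    """

    data: pd.DataFrame
    interval_h: float = 12.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        dt = self.data["timestamp"].diff().dropna()
        step = pd.Timedelta(hours=self.interval_h)
        if len(dt) and not (dt == step).all():
            raise ValueError("timestamps are not on a regular grid")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def slice(self, start: int, stop: int) -> "RegularPath":
        """Sub-path over point rows [start, stop)."""
        return RegularPath(self.data.iloc[start:stop].copy(), self.interval_h, self.animal_id)


@dataclass
class AnnualPath:
    """One biological-year window of a regular path (Aug 1 .. Jul 31)."""

    year: int
    path: RegularPath
    complete: bool


def _best_per_period(df: pd.DataFrame, period: str) -> pd.DataFrame:
    rank = df["quality"].astype(str).map(ARGOS_QUALITY_RANK)
    if rank.isna().any():
        # unknown classes sort after known ones
        rank = rank.fillna(len(ARGOS_QUALITY_RANK))
    key = df["timestamp"].dt.floor(period)
    order = pd.DataFrame({"key": key, "rank": rank, "ts": df["timestamp"]})
    # stable sort: best quality first, earliest fix breaks ties
    idx = order.sort_values(["key", "rank", "ts"], kind="stable").groupby("key").head(1).index
    return df.loc[sorted(idx)]


def filter_track(track: Track, max_speed: float = 50.0, period: str = "D") -> Track:
    """Clean a raw track with the best-of-period and speed filters.

    Within each transmission period (default: calendar day) only the most
    accurate fix is kept (ties broken by the earliest fix); when no quality
    column exists this step is skipped. Then, iterating forward, any fix whose
    implied speed from the last *retained* fix exceeds ``max_speed`` (km/day)
    is dropped, so a single aberrant location cannot take anchor fixes with it.

    Raises :class:`TrackUnusableError` when fewer than two locations survive.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be positive")
    if len(track) == 0:
        raise TrackUnusableError(f"track {track.animal_id!r} is empty")
    df = track.data
    if "quality" in df.columns:
        df = _best_per_period(df, period)

    ts = df["timestamp"].to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)
    keep = [0]
    for i in range(1, len(df)):
        j = keep[-1]
        dt_days = (ts[i] - ts[j]) / np.timedelta64(1, "D")
        dist = float(np.hypot(*(xy[i] - xy[j])))
        if dt_days <= 0:
            continue
        if dist / dt_days <= max_speed:
            keep.append(i)
    out = df.iloc[keep].reset_index(drop=True)
    if len(out) < 2:
        raise TrackUnusableError(
            f"track {track.animal_id!r} unusable after filtering ({len(out)} locations)"
        )
    return Track(track.animal_id, out)


def regularize(track: Track, interval_h: float = 12.0) -> RegularPath:
    """Resample a filtered track onto a regular grid by linear interpolation.

    The grid is anchored at the first fix and spaced ``interval_h`` hours.
    Each real fix is snapped to its nearest grid time (keeping its coordinates;
    when several fixes snap to the same grid point only the earliest is kept),
    and positions between consecutive real fixes are filled in assuming
    straight-line movement at constant speed, i.e. one interpolated point
    every ``interval_h`` hours. Gaps of any length are interpolated; the
    ``gap_h`` column reports the enclosing inter-fix gap so callers can judge
    how much of the path is bridged.
    """
    if len(track) < 2:
        raise TrackUnusableError("regularize needs at least two locations")
    df = track.data
    step = pd.Timedelta(hours=interval_h)
    t0 = df["timestamp"].iloc[0]
    grid_idx = ((df["timestamp"] - t0) / step).round().astype(int)
    # thin sub-interval fixes: first fix wins a contested grid slot
    first = ~grid_idx.duplicated(keep="first")
    real = pd.DataFrame(
        {"k": grid_idx[first].to_numpy(), "x": df.loc[first, "x"].to_numpy(dtype=float),
         "y": df.loc[first, "y"].to_numpy(dtype=float)}
    )
    n = int(real["k"].iloc[-1]) + 1
    k = np.arange(n)
    x = np.interp(k, real["k"], real["x"])
    y = np.interp(k, real["k"], real["y"])
    is_interp = np.ones(n, dtype=bool)
    is_interp[real["k"].to_numpy()] = False
    gaps = np.diff(real["k"].to_numpy())
    gap_h = np.zeros(n)
    for a, g in zip(real["k"].to_numpy()[:-1], gaps):
        if g > 1:
            gap_h[a + 1 : a + g] = g * interval_h
    out = pd.DataFrame(
        {
            "timestamp": t0 + k * step,
            "x": x,
            "y": y,
            "is_interpolated": is_interp,
            "gap_h": gap_h,
        }
    )
    return RegularPath(out, interval_h, track.animal_id)


def split_annual(path: RegularPath, start: tuple[int, int] = (8, 1)) -> list[AnnualPath]:
    """Cut a multi-year path into biological-year windows.

    A window runs from ``start`` (month, day; default Aug 1) of year *y* to the
    day before the same date of year *y+1*, and is flagged complete only when
    the path covers the window end to end (Aug 1 through Jul 31 inclusive).
    """
    ts = path.timestamps
    if len(ts) < 2:
        raise ValueError("path too short to split")
    month, day = start
    t_first, t_last = ts.iloc[0], ts.iloc[-1]
    first_year = t_first.year if (t_first.month, t_first.day) >= (month, day) else t_first.year - 1
    out: list[AnnualPath] = []
    for year in range(first_year, t_last.year + 1):
        w0 = pd.Timestamp(year=year, month=month, day=day)
        w1 = pd.Timestamp(year=year + 1, month=month, day=day)
        mask = (ts >= w0) & (ts < w1)
        if mask.sum() < 2:
            continue
        sub = path.data.loc[mask].copy()
        complete = (t_first <= w0) and (t_last >= w1 - pd.Timedelta(days=1))
        out.append(AnnualPath(year, RegularPath(sub, path.interval_h, path.animal_id), complete))
    return out
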