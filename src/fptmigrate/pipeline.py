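"""Two-step detection of migration timing from an FPT profile.

Spring migration of a seasonal migrant is bracketed by two pauses: the long
winter break on the winter range and the short early-summer pause on the
calving ground. Both show up as high-FPT bouts, but the winter bout dwarfs
everything else, so a single segmentation of a multi-year profile resolves
winters only. The procedure is therefore two-step:

1. segment the whole profile and classify high-mean segments intersecting
   the winter window as winter breaks (with a per-year fallback segmentation
   for winters the whole-path run missed);
2. cut the profile into inter-winter slices and re-segment each slice alone
   — removing the winter-dominated contrast — to find the June break marking
   arrival on the calving ground, optionally confirmed spatially against a
   known calving-ground polygon when the FPT signal alone is equivocal.

Departure is the end of the winter break (or of a pre-migration pause
directly following it); arrival is the start of the June break.

A segment counts as a "break" when its mean FPT exceeds ``c`` times the
median of all segment means in the same segmentation (default c = 2) — a
scale-free rule robust to differences in fix rate between animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fpt import FptProfile
from .lavielle import (
    Segmentation,
    SegmentationConfig,
    prepare_series,
    segment_series,
    snap_breakpoints,
)
from .trajectory import RegularPath

__all__ = [
    "DetectionConfig",
    "BreakEvent",
    "MigrationRecord",
    "detect_winter_breaks",
    "yearly_fallback",
    "extract_inter_winter",
    "detect_calving",
    "migration_dates",
    "process_profile",
]


@dataclass
class DetectionConfig:
    """Windows and rules of the two-step detection.

    winter_months: calendar months a winter-break segment must touch.
    calving window: the June interval where arrival is expected.
    break_factor: c in the break rule (segment mean > c * median of means).
    polygon_min_inside: fraction of a candidate June segment's points that
        must fall in the calving-ground polygon for the spatial check to
        accept it.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    winter_months: tuple[int, ...] = (12, 1, 2, 3, 4)
    calving_window: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (6, 30))
    break_factor: float = 2.0
    polygon_min_inside: float = 0.9
    year_start: tuple[int, int] = (8, 1)  # biological year begins Aug 1


@dataclass
class BreakEvent:
    kind: str                  # winter | calving | pre_migration | other
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    mean_fpt: float            # days
    start_observed: bool       # False when the break runs into the data edge
    end_observed: bool
    detection_route: str       # whole_path | yearly_fallback | spatial_check
    start_index: int = -1      # path coordinates, for slicing
    end_index: int = -1

    @property
    def complete(self) -> bool:
        return self.start_observed and self.end_observed

    @property
    def duration(self) -> float:
        """Days between the snapped boundary dates."""
        return (self.end_date - self.start_date) / pd.Timedelta(days=1)


@dataclass
class MigrationRecord:
    animal_id: str
    year: int
    departure_date: pd.Timestamp | None
    arrival_date: pd.Timestamp | None
    complete: bool
    notes: str = ""

    def __post_init__(self) -> None:
        if (
            self.departure_date is not None
            and self.arrival_date is not None
            and not self.departure_date < self.arrival_date
        ):
            raise ValueError("departure must precede arrival")


def _segment_profile(profile: FptProfile, cfg: SegmentationConfig) -> Segmentation:
    series, index = prepare_series(profile.values)
    seg, _ = segment_series(series, cfg)
    return replace(seg, index=index)


def _break_segments(seg: Segmentation, cfg: DetectionConfig) -> list[int]:
    """Indices of segments passing the scale-free high-FPT break rule."""
    med = float(np.median(seg.means))
    return [i for i in range(seg.k) if seg.means[i] > cfg.break_factor * med]


def _event_from_segment(seg: Segmentation, i: int, profile: FptProfile, kind: str,
                        route: str, cfg: DetectionConfig) -> BreakEvent:
    pa, pb = seg.segments_parent()[i]
    path = profile.path
    dates = _snap_bounds(seg, path)
    return BreakEvent(
        kind=kind,
        start_date=dates[i],
        end_date=dates[i + 1],
        mean_fpt=float(seg.means[i]),
        # a boundary shared with the data edge was never actually observed
        start_observed=i > 0,
        end_observed=i < seg.k - 1,
        detection_route=route,
        start_index=pa,
        end_index=pb,
    )


def _snap_bounds(seg: Segmentation, path: RegularPath) -> list[pd.Timestamp]:
    """Dates of all K+1 segment edges: interior edges snapped to real fixes,
    outer edges taken at the first/last segmented point."""
    inner = snap_breakpoints(seg, path)
    parent = seg.segments_parent()
    first = path.timestamps.iloc[parent[0][0]]
    last = path.timestamps.iloc[parent[-1][1] - 1]
    return [first, *inner, last]


def _intersects_months(seg: Segmentation, i: int, path: RegularPath,
                       months: tuple[int, ...]) -> bool:
    pa, pb = seg.segments_parent()[i]
    m = path.timestamps.iloc[pa:pb].dt.month.unique()
    return bool(np.isin(m, months).any())


def detect_winter_breaks(profile: FptProfile, config: DetectionConfig | None = None,
                         route: str = "whole_path") -> list[BreakEvent]:
    """First (coarse) segmentation: winter breaks on the whole profile.

    A segment is returned when it passes the break rule and its span touches
    the winter window. Events whose start or end coincides with the ends of
    the observed profile are flagged incomplete.
    """
    config = config or DetectionConfig()
    seg = _segment_profile(profile, config.segmentation)
    out = []
    for i in _break_segments(seg, config):
        if _intersects_months(seg, i, profile.path, config.winter_months):
            out.append(_event_from_segment(seg, i, profile, "winter", route, config))
    return out


def _winter_years(profile: FptProfile, config: DetectionConfig) -> list[int]:
    """Biological years (by starting year) whose winter window the profile touches."""
    ts = profile.timestamps
    month, day = config.year_start
    years = set()
    for t in (ts.iloc[0], ts.iloc[-1]):
        y = t.year if (t.month, t.day) >= (month, day) else t.year - 1
        years.add(y)
    lo, hi = min(years), max(years)
    out = []
    for y in range(lo, hi + 1):
        # winter window of biological year y: Dec y .. Apr y+1 (by months)
        w0 = pd.Timestamp(year=y, month=config.winter_months[0], day=1)
        w1 = pd.Timestamp(year=y + 1, month=config.winter_months[-1] + 1, day=1)
        if (ts.iloc[-1] >= w0) and (ts.iloc[0] < w1):
            out.append(y)
    return out


def yearly_fallback(profile: FptProfile, events: list[BreakEvent],
                    config: DetectionConfig | None = None) -> list[BreakEvent]:
    """Re-segment yearly windows whose expected winter the whole-path run missed.

    Each biological year (Aug 1 .. Jul 31) overlapping the profile is checked
    for a winter event; missing ones are re-segmented on the yearly slice
    alone, where a weak winter pause is no longer flattened by the contrast
    with stronger years. Newly found events are tagged ``yearly_fallback``.
    """
    config = config or DetectionConfig()
    month, day = config.year_start
    ts = profile.timestamps
    found = list(events)
    for y in _winter_years(profile, config):
        w0 = pd.Timestamp(year=y, month=month, day=day)
        w1 = pd.Timestamp(year=y + 1, month=month, day=day)
        has = any(e.start_date < w1 and e.end_date >= w0 for e in found
                  if e.kind == "winter")
        if has:
            continue
        mask = ((ts >= w0) & (ts < w1)).to_numpy()
        if mask.sum() < 2 * config.segmentation.l_min:
            continue
        lo = int(np.argmax(mask))
        hi = lo + int(mask[lo:].sum())
        sub = profile.slice(lo, hi)
        if not np.isfinite(sub.values).any():
            continue
        for ev in detect_winter_breaks(sub, config, route="yearly_fallback"):
            ev.start_index += lo
            ev.end_index += lo
            found.append(ev)
    return sorted(found, key=lambda e: e.start_date)


def _winter_slices(profile: FptProfile, winter_events: list[BreakEvent],
                   min_points: int = 2) -> list[tuple[BreakEvent, FptProfile]]:
    ev = sorted((e for e in winter_events if e.kind == "winter"),
                key=lambda e: e.start_index)
    for a, b in zip(ev[:-1], ev[1:]):
        if a.end_index > b.start_index:
            raise ValueError("winter events overlap")
    out = []
    n = len(profile)
    for i, e in enumerate(ev):
        stop = ev[i + 1].start_index if i + 1 < len(ev) else n
        if stop - e.end_index >= min_points:
            out.append((e, profile.slice(e.end_index, stop)))
    return out


def extract_inter_winter(profile: FptProfile, winter_events: list[BreakEvent],
                         min_points: int = 2) -> list[FptProfile]:
    """Profile slices between consecutive winter breaks.

    Slices run from each winter break's end to the next break's start; after
    the last break an open-ended slice to the end of the profile is included
    when long enough. Overlapping winter events are an upstream error.
    """
    return [sl for _, sl in _winter_slices(profile, winter_events, min_points)]


def _in_calving_window(t: pd.Timestamp, config: DetectionConfig) -> bool:
    (m0, d0), (m1, d1) = config.calving_window
    return (m0, d0) <= (t.month, t.day) <= (m1, d1)


def detect_calving(slice_profile: FptProfile, calving_polygon=None,
                   config: DetectionConfig | None = None,
                   ) -> tuple[BreakEvent | None, Segmentation | None]:
    """Fine segmentation of an inter-winter slice for calving-ground use.

    Returns the accepted June break (or None) together with the slice's fine
    segmentation (reused for the departure-date rule). Candidates are
    segments overlapping the calving window; the highest-mean candidate
    passing the break rule wins. When none passes but a calving-ground
    polygon is supplied, the best June candidate is accepted anyway if its
    points lie within the polygon (detection route ``spatial_check``) — the
    programmatic counterpart of confirming an equivocal break on a map.
    """
    config = config or DetectionConfig()
    finite = np.isfinite(slice_profile.values)
    if finite.sum() < 2 * config.segmentation.l_min:
        return None, None
    seg = _segment_profile(slice_profile, config.segmentation)
    path = slice_profile.path
    june = [
        i for i in range(seg.k)
        if any(
            _in_calving_window(t, config)
            for t in path.timestamps.iloc[slice(*seg.segments_parent()[i])]
        )
    ]
    if not june:
        return None, seg
    breaks = set(_break_segments(seg, config))
    passing = [i for i in june if i in breaks]
    if passing:
        best = max(passing, key=lambda i: seg.means[i])
        return _event_from_segment(seg, best, slice_profile, "calving",
                                   "whole_path", config), seg
    if calving_polygon is not None:
        from shapely.geometry import Point

        best = max(june, key=lambda i: seg.means[i])
        pa, pb = seg.segments_parent()[best]
        pts = path.xy[pa:pb]
        inside = np.fromiter(
            (calving_polygon.covers(Point(*p)) for p in pts), bool, len(pts)
        )
        if inside.mean() >= config.polygon_min_inside:
            return _event_from_segment(seg, best, slice_profile, "calving",
                                       "spatial_check", config), seg
    return None, seg


def migration_dates(winter_event: BreakEvent, calving_event: BreakEvent | None,
                    slice_seg: Segmentation | None, slice_profile: FptProfile,
                    config: DetectionConfig | None = None) -> MigrationRecord:
    """Departure/arrival dates of one spring migration.

    Departure is the winter break's end — unless the inter-winter slice opens
    with a pre-migration pause (first fine segment's mean FPT above the
    following segment's), in which case departure is that pause's end.
    Arrival is the start of the calving break when one was found.
    """
    config = config or DetectionConfig()
    animal = slice_profile.path.animal_id
    notes = []
    departure = winter_event.end_date if winter_event.end_observed else None
    if departure is None:
        notes.append("winter-break end unobserved")
    if slice_seg is not None and slice_seg.k >= 2:
        if slice_seg.means[0] > slice_seg.means[1]:
            dates = _snap_bounds(slice_seg, slice_profile.path)
            departure = dates[1]
            notes.append("departure set at end of leading pre-migration pause")
    arrival = calving_event.start_date if calving_event is not None else None
    if calving_event is not None and calving_event.detection_route == "spatial_check":
        notes.append("arrival accepted via calving-ground polygon")
    if departure is not None and arrival is not None and not departure < arrival:
        notes.append("arrival not after departure; record left incomplete")
        arrival = None
    year = (arrival or departure).year if (arrival or departure) is not None else -1
    return MigrationRecord(
        animal_id=animal,
        year=year,
        departure_date=departure,
        arrival_date=arrival,
        complete=departure is not None and arrival is not None,
        notes="; ".join(notes),
    )


def process_profile(profile: FptProfile, calving_polygon=None,
                    config: DetectionConfig | None = None,
                    ) -> tuple[list[BreakEvent], list[MigrationRecord]]:
    """Full two-step detection on one animal's FPT profile."""
    config = config or DetectionConfig()
    events = detect_winter_breaks(profile, config)
    events = yearly_fallback(profile, events, config)
    records = []
    winters = [e for e in events if e.kind == "winter"]
    for w, sl in _winter_slices(profile, winters):
        calv, seg = detect_calving(sl, calving_polygon, config)
        if calv is not None:
            events.append(calv)
        records.append(migration_dates(w, calv, seg, sl, config))
    return events, records
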