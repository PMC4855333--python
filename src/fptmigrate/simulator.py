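"""Labeled correlated-random-walk paths mimicking a migratory ungulate year.

A simulated path concatenates eight contiguous segments:

    range 1, migration leg, stopover, migration leg,
    range 2, migration leg, stopover, migration leg

Two designs are provided. In the ``2LB`` design both seasonal ranges are long
breaks (200 locations in a 50-km patch); in the ``1LB`` design the second
range is a short break (100 locations in a 25-km patch), indistinguishable in
scale from a stopover — the situation of caribou, whose calving pause is as
brief as an ordinary stopover.

Movement is a correlated random walk at one location every 12 h: per-step
speeds are log-normal (arithmetic mean 15 km/day during migration, 3 km/day
during breaks, coefficient of variation 1 for both) and turning angles are
wrapped Cauchy with mean 0 and concentration 0.8 (migration) or 0.1 (break).
During a break the walker is confined to a circular patch: a step crossing
the patch edge is truncated at the edge and the next step's base heading
points back at the patch centre (the edge reflects). A stopover's patch is
25 km across; it is centred wherever the preceding migration leg ended.
Migration legs start headed along the migration axis toward the next waypoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

from .trajectory import RegularPath

__all__ = [
    "SimConfig",
    "LabeledSimPath",
    "TrueSegment",
    "sample_wrapped_cauchy",
    "sample_speed",
    "simulate_break",
    "simulate_migration_leg",
    "simulate_path",
]

BREAK = "break"
MIGRATION = "migration"


@dataclass
class SimConfig:
    """Study design of one simulated path; defaults are the validated setup."""

    path_type: str = "2LB"
    n_migration_leg: int = 100
    n_short_break: int = 100
    n_long_break: int = 200
    interval_h: float = 12.0
    speed_mean_migration: float = 15.0   # km/day
    speed_mean_break: float = 3.0        # km/day
    speed_cv: float = 1.0
    turn_concentration_migration: float = 0.8
    turn_concentration_break: float = 0.1
    patch_diameter_short: float = 25.0   # km
    patch_diameter_long: float = 50.0    # km
    waypoint_spacing: float = 400.0      # km between successive waypoints
    migration_heading: float = 0.0       # radians; the migration axis
    start: datetime = datetime(2004, 1, 15)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.path_type not in ("2LB", "1LB"):
            raise ValueError("path_type must be '2LB' or '1LB'")
        for rho in (self.turn_concentration_migration, self.turn_concentration_break):
            if not 0 <= rho < 1:
                raise ValueError("turn concentrations must be in [0, 1)")
        for v in (self.n_migration_leg, self.n_short_break, self.n_long_break,
                  self.interval_h, self.speed_mean_migration, self.speed_mean_break,
                  self.speed_cv, self.patch_diameter_short, self.patch_diameter_long):
            if v <= 0:
                raise ValueError("all sizes, speeds and diameters must be positive")


@dataclass
class TrueSegment:
    """Ground-truth block: half-open point range, name and behavioural class."""

    start: int
    stop: int
    name: str      # range1 | migration_leg | stopover | range2
    cls: str       # break | migration


@dataclass
class LabeledSimPath:
    """Simulated path plus its ground-truth segmentation."""

    path: RegularPath
    segments: list[TrueSegment]
    config: SimConfig

    @property
    def labels(self) -> np.ndarray:
        out = np.empty(len(self.path), dtype=object)
        for s in self.segments:
            out[s.start : s.stop] = s.name
        return out

    @property
    def classes(self) -> np.ndarray:
        out = np.empty(len(self.path), dtype=object)
        for s in self.segments:
            out[s.start : s.stop] = s.cls
        return out

    def coarse_segments(self) -> list[TrueSegment]:
        """Four-segment truth: each migration (leg + stopover + leg) merged.

        This is the ground truth relevant when the number of segments is
        constrained to the four *expected* blocks (two seasonal ranges, two
        migration movements), where a stopover counts as part of its
        migration.
        """
        r1, l1, s1, l2, r2, l3, s2, l4 = self.segments
        return [
            TrueSegment(r1.start, r1.stop, "range1", BREAK),
            TrueSegment(l1.start, l2.stop, "migration1", MIGRATION),
            TrueSegment(r2.start, r2.stop, "range2", BREAK),
            TrueSegment(l3.start, l4.stop, "migration2", MIGRATION),
        ]

    def to_frame(self) -> pd.DataFrame:
        df = self.path.data[["timestamp", "x", "y"]].copy()
        df["true_label"] = self.labels
        df["true_class"] = self.classes
        seg_id = np.empty(len(df), dtype=int)
        for i, s in enumerate(self.segments):
            seg_id[s.start : s.stop] = i
        df["segment_id"] = seg_id
        return df


def sample_wrapped_cauchy(mu: float, rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw turning angles in (-pi, pi] from a wrapped Cauchy distribution.

    Inverse-CDF sampling: theta = mu + 2 atan(((1-rho)/(1+rho)) tan(pi(u-1/2))).
    rho = 0 reduces to the circular uniform; rho -> 1 concentrates at mu.
    """
    if not 0 <= rho < 1:
        raise ValueError("concentration rho must be in [0, 1)")
    u = rng.random(n)
    theta = mu + 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))
    return (theta + np.pi) % (2.0 * np.pi) - np.pi


def sample_speed(mean: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal speeds (km/day) with the given *arithmetic* mean and CV.

    sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2 / 2, so that E[speed]
    equals ``mean`` exactly and SD/mean equals ``cv``.
    """
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be positive")
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _crw_steps(n: int, mean_speed: float, cv: float, rho: float, interval_h: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    dt_days = interval_h / 24.0
    lengths = sample_speed(mean_speed, cv, n, rng) * dt_days
    turns = sample_wrapped_cauchy(0.0, rho, n, rng)
    return lengths, turns


def simulate_break(centre: np.ndarray, diameter: float, n: int, rng: np.random.Generator,
                   config: SimConfig, start_pos: np.ndarray | None = None,
                   heading: float | None = None,
                   include_start: bool = False) -> tuple[np.ndarray, float]:
    """CRW confined to a circular patch; returns (points, final heading).

    ``n`` points are produced by ``n`` steps from ``start_pos`` (default the
    patch centre); with ``include_start`` the starting point itself is the
    first emitted point (used for the very first segment of a path). A step
    whose endpoint would leave the patch is cut at the edge, and the next
    step's base heading is the bearing to the patch centre with the usual
    turning noise around it.
    """
    centre = np.asarray(centre, dtype=float)
    radius = diameter / 2.0
    pos = centre.copy() if start_pos is None else np.asarray(start_pos, dtype=float).copy()
    if heading is None:
        heading = rng.uniform(-np.pi, np.pi)
    n_steps = n - 1 if include_start else n
    lengths, turns = _crw_steps(
        n_steps, config.speed_mean_break, config.speed_cv,
        config.turn_concentration_break, config.interval_h, rng,
    )
    pts = []
    if include_start:
        pts.append(pos.copy())
    reflected = False
    for L, th in zip(lengths, turns):
        if reflected:
            heading = float(np.arctan2(centre[1] - pos[1], centre[0] - pos[0])) + th
            reflected = False
        else:
            heading = heading + th
        step = L * np.array([np.cos(heading), np.sin(heading)])
        prop = pos + step
        if np.hypot(*(prop - centre)) > radius:
            # cut the step at the patch edge: |pos + t*step - centre| = radius
            a = pos - centre
            A = float(step @ step)
            B = 2.0 * float(a @ step)
            C = float(a @ a) - radius * radius
            disc = max(B * B - 4.0 * A * C, 0.0)
            t = (-B + np.sqrt(disc)) / (2.0 * A) if A > 0 else 0.0
            t = min(max(t, 0.0), 1.0)
            pos = pos + t * step
            reflected = True
        else:
            pos = prop
        pts.append(pos.copy())
    return np.array(pts), float(heading)


def simulate_migration_leg(start_pos: np.ndarray, base_heading: float, n: int,
                           rng: np.random.Generator, config: SimConfig,
                           ) -> tuple[np.ndarray, float]:
    """Directed CRW leg of ``n`` steps starting toward ``base_heading``."""
    pos = np.asarray(start_pos, dtype=float).copy()
    lengths, turns = _crw_steps(
        n, config.speed_mean_migration, config.speed_cv,
        config.turn_concentration_migration, config.interval_h, rng,
    )
    heading = float(base_heading)
    pts = []
    for L, th in zip(lengths, turns):
        heading = heading + th
        pos = pos + L * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pos.copy())
    return np.array(pts), heading


def simulate_path(config: SimConfig) -> LabeledSimPath:
    """Generate one labeled eight-segment path; bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    long_d, short_d = config.patch_diameter_long, config.patch_diameter_short
    range2_long = config.path_type == "2LB"
    plan = [
        ("range1", BREAK, config.n_long_break, long_d),
        ("migration_leg", MIGRATION, config.n_migration_leg, None),
        ("stopover", BREAK, config.n_short_break, short_d),
        ("migration_leg", MIGRATION, config.n_migration_leg, None),
        ("range2", BREAK,
         config.n_long_break if range2_long else config.n_short_break,
         long_d if range2_long else short_d),
        ("migration_leg", MIGRATION, config.n_migration_leg, None),
        ("stopover", BREAK, config.n_short_break, short_d),
        ("migration_leg", MIGRATION, config.n_migration_leg, None),
    ]
    axis = config.migration_heading
    pos = np.zeros(2)
    heading = 0.0
    pieces: list[np.ndarray] = []
    segments: list[TrueSegment] = []
    cursor = 0
    for i, (name, cls, n, diam) in enumerate(plan):
        if cls == BREAK:
            centre = pos.copy()  # patch centred where the walker arrives
            pts, heading = simulate_break(
                centre, diam, n, rng, config,
                start_pos=pos, heading=None if i == 0 else heading,
                include_start=(i == 0),
            )
        else:
            # next waypoint lies one spacing further along the migration axis
            waypoint = pos + config.waypoint_spacing * np.array([np.cos(axis), np.sin(axis)])
            base = float(np.arctan2(waypoint[1] - pos[1], waypoint[0] - pos[0]))
            pts, heading = simulate_migration_leg(pos, base, n, rng, config)
        pos = pts[-1].copy()
        pieces.append(pts)
        segments.append(TrueSegment(cursor, cursor + len(pts), name, cls))
        cursor += len(pts)
    xy = np.vstack(pieces)
    n_total = len(xy)
    ts = pd.Timestamp(config.start) + pd.to_timedelta(
        np.arange(n_total) * config.interval_h, unit="h"
    )
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "is_interpolated": False,
            "gap_h": 0.0,
        }
    )
    path = RegularPath(df, config.interval_h, animal_id=f"sim-{config.path_type}")
    return LabeledSimPath(path, segments, config)
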