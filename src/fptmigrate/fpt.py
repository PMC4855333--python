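"""First-passage time (FPT) along a regular path and radius selection.

The FPT at a point of the path, for a circle of radius ``r`` centred on that
point, is the time the animal takes to cross the circle while passing through
its centre: the backward passage time (elapsed time, looking back along the
path, until the trajectory is first more than ``r`` away) plus the forward
passage time (same, looking ahead). Slow, tortuous movement — area-restricted
search on a seasonal range — gives high FPT; fast directed travel such as
migration gives low FPT.

The operative radius is chosen from the data: compute, per path, the variance
of log FPT as a function of ``r``, average it over paths, and take the radius
``r_max`` at the peak of the mean variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import RegularPath

__all__ = [
    "FptProfile",
    "VarianceProfile",
    "DEFAULT_RADII_KM",
    "compute_fpt",
    "variance_profile",
    "select_rmax",
]

#: Radius grid (km): 10–100 in 5-km steps then 110–300 in 10-km steps.
DEFAULT_RADII_KM = np.concatenate([np.arange(10, 101, 5), np.arange(110, 301, 10)])


@dataclass
class FptProfile:
    """Per-point FPT values (days), aligned to a :class:`RegularPath`.

    ``values`` holds NaN where a passage time is undefined (the path ends
    before leaving the circle in one direction or the other, which happens
    near the ends of the path).
    """

    path: RegularPath
    radius_km: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.path):
            raise ValueError("profile not aligned to path")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.Series:
        return self.path.timestamps

    def slice(self, start: int, stop: int) -> "FptProfile":
        return FptProfile(self.path.slice(start, stop), self.radius_km, self.values[start:stop])

    def to_frame(self) -> pd.DataFrame:
        df = self.path.data[["timestamp", "x", "y", "is_interpolated"]].copy()
        df["fpt_days"] = self.values
        df["fpt_missing"] = ~np.isfinite(self.values)
        df["radius_km"] = self.radius_km
        return df


@dataclass
class VarianceProfile:
    """Mean (over paths) of Var[log FPT(r)] on a radius grid."""

    radii_km: np.ndarray
    mean_s: np.ndarray
    se: np.ndarray
    n_paths: np.ndarray  # paths contributing at each radius

    @property
    def r_max(self) -> float:
        return select_rmax(self)


def _passage_steps(d: np.ndarray, r: float, dt_days: float, xy: np.ndarray,
                   centre: np.ndarray) -> float:
    """Passage time (days) along one direction given distances ``d`` from the
    centre for the ordered points leaving the centre (d[0] is the centre
    itself). NaN when the circle is never crossed."""
    outside = d > r
    if not outside.any():
        return np.nan
    j = int(np.argmax(outside))  # first point strictly outside
    a = xy[j - 1] - centre
    b = xy[j] - centre
    dvec = b - a
    # |a + s*dvec| = r on s in [0, 1]; the outward root is the larger one
    A = float(dvec @ dvec)
    B = 2.0 * float(a @ dvec)
    C = float(a @ a) - r * r
    disc = B * B - 4.0 * A * C
    s = (-B + np.sqrt(max(disc, 0.0))) / (2.0 * A) if A > 0 else 0.0
    s = min(max(s, 0.0), 1.0)
    return (j - 1 + s) * dt_days


def compute_fpt(path: RegularPath, r: float) -> FptProfile:
    """FPT profile of a path for circle radius ``r`` (km).

    For every point (real or interpolated) the backward and forward passage
    times are found by walking the path away from the point until the distance
    first exceeds ``r``; the crossing instant is located exactly on the
    crossing step by solving the circle–segment intersection, consistent with
    the constant-speed-per-leg model of the path. The FPT is their sum, NaN
    if either side never crosses.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    xy = path.xy
    n = len(xy)
    dt_days = path.interval_h / 24.0
    values = np.full(n, np.nan)
    for i in range(n):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        fwd = _passage_steps(d[i:], r, dt_days, xy[i:], xy[i])
        bwd = _passage_steps(d[i::-1], r, dt_days, xy[i::-1], xy[i])
        values[i] = fwd + bwd
    if not np.isfinite(values).any():
        warnings.warn(
            f"radius {r} km exceeds the path extent: all FPT values missing",
            stacklevel=2,
        )
    return FptProfile(path, r, values)


def variance_profile(paths: list[RegularPath], radii=DEFAULT_RADII_KM) -> VarianceProfile:
    """Mean of S(r) = Var[log FPT(r)] across paths, with its standard error.

    A path contributes at a radius only when it has at least two finite FPT
    values there (natural log; missing values are excluded, never zero-filled).
    """
    radii = np.asarray(radii, dtype=float)
    if len(paths) == 0:
        raise ValueError("need at least one path")
    if not (np.diff(radii) > 0).all() or (radii <= 0).any():
        raise ValueError("radii must be positive and strictly increasing")
    per_path = np.full((len(paths), len(radii)), np.nan)
    for ip, path in enumerate(paths):
        for ir, r in enumerate(radii):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = compute_fpt(path, r).values
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 2:
                per_path[ip, ir] = np.var(np.log(vals), ddof=1)
    n_contrib = np.isfinite(per_path).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_s = np.nanmean(per_path, axis=0)
        sd = np.nanstd(per_path, axis=0, ddof=1)
    se = np.where(n_contrib > 1, sd / np.sqrt(np.maximum(n_contrib, 1)), 0.0)
    return VarianceProfile(radii, mean_s, se, n_contrib)


def select_rmax(vp: VarianceProfile) -> float:
    """Radius at the peak of the mean variance curve (ties: smaller radius)."""
    finite = np.isfinite(vp.mean_s)
    if finite.sum() < 3:
        raise ValueError("need mean S(r) at three or more radii")
    s = np.where(finite, vp.mean_s, -np.inf)
    i = int(np.argmax(s))
    if i == 0 or i == len(vp.radii_km) - 1:
        warnings.warn(
            "variance peak lies at the edge of the radius grid; "
            "r_max may not be an interior maximum",
            stacklevel=2,
        )
    return float(vp.radii_km[i])
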