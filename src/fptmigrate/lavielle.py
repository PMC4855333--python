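"""Penalized-contrast segmentation of a 1-D series (Lavielle's procedure).

A series y_1..y_n is partitioned into K contiguous segments so that the
within-segment sum of squared deviations from the segment means — the mean
contrast J — is minimal. The optimum is found exactly by dynamic programming
for every K up to ``Kmax``. The number of segments K* is then selected
heuristically from the shape of K -> J(K): J is rescaled to a decreasing
curve from Kmax down to 1,

    J~(K) = (J(Kmax) - J(K)) / (J(Kmax) - J(1)) * (Kmax - 1) + 1,

and K* is the largest K whose discrete second derivative
D(K) = J~(K-1) - 2 J~(K) + J~(K+1) exceeds a threshold S (default 0.75).
Past the true number of segments the contrast curve is nearly flat, so large
curvature at K marks the last structurally justified split. An explicit
penalty weight is never needed; the curvature rule plays its role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import RegularPath

__all__ = [
    "SegmentationConfig",
    "ContrastCurve",
    "Segmentation",
    "best_segmentation_K",
    "select_K",
    "segment_series",
    "snap_breakpoints",
    "prepare_series",
]


@dataclass
class SegmentationConfig:
    """Tuning parameters of the segmentation.

    kmax: most segments ever considered; set well above the number expected.
    l_min: minimum points per segment (1 = unconstrained).
    s_threshold: curvature threshold S for selecting K*.
    contrast: which segment statistic is homogeneous; only "mean" is
        implemented — for FPT profiles the dominant changes are in the mean.
    """

    kmax: int = 30
    l_min: int = 1
    s_threshold: float = 0.75
    contrast: str = "mean"

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be at least 2")
        if self.l_min < 1:
            raise ValueError("l_min must be at least 1")
        if self.s_threshold <= 0:
            raise ValueError("s_threshold must be positive")
        if self.contrast != "mean":
            raise NotImplementedError("only the mean contrast is implemented")


@dataclass
class ContrastCurve:
    """Diagnostics of the K* selection: J(K), its rescaled form and D(K)."""

    J: np.ndarray              # J[k-1] = optimal contrast with k segments
    normalized: np.ndarray     # J~(K), decreasing from Kmax to 1
    second_derivative: np.ndarray  # D(K) for K = 2..Kmax-1 (NaN padded ends)
    k_star: int

    @property
    def kmax(self) -> int:
        return len(self.J)


@dataclass
class Segmentation:
    """A partition of series indices into contiguous segments.

    ``bounds`` are K+1 half-open edges 0 = b_0 < b_1 < ... < b_K = n; segment
    i covers [b_i, b_{i+1}). When the segmented series was extracted from a
    longer parent (e.g. an FPT profile whose undefined points were dropped),
    ``index`` holds the parent position of every series point, so segment i
    covers parent points ``index[b_i] .. index[b_{i+1} - 1]``.
    """

    bounds: np.ndarray
    means: np.ndarray
    index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        if self.index is not None:
            self.index = np.asarray(self.index, dtype=int)
            if len(self.index) != self.n:
                raise ValueError("index map not aligned to the segmented series")

    @property
    def k(self) -> int:
        return len(self.bounds) - 1

    @property
    def n(self) -> int:
        return int(self.bounds[-1])

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.bounds)

    @property
    def breakpoints(self) -> np.ndarray:
        """Interior segment-start positions, in parent coordinates."""
        b = self.bounds[1:-1]
        return self.index[b] if self.index is not None else b

    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) pairs in local series coordinates."""
        return list(zip(self.bounds[:-1], self.bounds[1:]))

    def segments_parent(self) -> list[tuple[int, int]]:
        """Closed-start, open-stop parent index ranges of each segment.

        For segment i this is (first parent point, last parent point + 1);
        with an index map the range may span parent points that were not in
        the series (undefined values inside the segment).
        """
        if self.index is None:
            return self.segments()
        return [(int(self.index[a]), int(self.index[b - 1]) + 1) for a, b in self.segments()]

    def labels(self) -> np.ndarray:
        """Per-point segment index (length n, local coordinates)."""
        return np.repeat(np.arange(self.k), self.lengths)

    def to_frame(self, path: RegularPath | None = None) -> pd.DataFrame:
        rows = []
        for i, ((a, b), (pa, pb)) in enumerate(zip(self.segments(), self.segments_parent())):
            row = {
                "segment_id": i,
                "start_index": pa,
                "end_index": pb,
                "n_points": b - a,
                "mean": self.means[i],
            }
            if path is not None:
                row["start_date"] = path.timestamps.iloc[pa]
                row["end_date"] = path.timestamps.iloc[pb - 1]
            rows.append(row)
        return pd.DataFrame(rows)


def _cost_matrix(y: np.ndarray) -> np.ndarray:
    """C[i, j] = sum of squared deviations of y[i..j] about its mean."""
    n = len(y)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cq = np.concatenate([[0.0], np.cumsum(y * y)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cs[j + 1] - cs[i]
        c = (cq[j + 1] - cq[i]) - s * s / length
    c[length < 1] = np.inf
    return np.maximum(c, 0.0)  # guard tiny negative round-off


def _dp(y: np.ndarray, kmax: int, l_min: int):
    """Exact DP over admissible breakpoints.

    Returns (J, back) with J[k-1] the optimal contrast using k segments and
    back[k, j] the start index of the last segment in the optimal k-partition
    of y[0..j]. Ties take the smallest start index (earliest breakpoints),
    making the output deterministic.
    """
    n = len(y)
    if n < kmax * l_min:
        raise ValueError(f"series of length {n} cannot hold {kmax} segments of >= {l_min}")
    C = _cost_matrix(y)
    J = np.full((kmax + 1, n), np.inf)
    back = np.zeros((kmax + 1, n), dtype=int)
    J[1, l_min - 1 :] = C[0, l_min - 1 :]
    for k in range(2, kmax + 1):
        lo = (k - 1) * l_min  # earliest admissible start of the last segment
        for j in range(k * l_min - 1, n):
            hi = j - l_min + 1
            cand = J[k - 1, lo - 1 : hi] + C[lo : hi + 1, j]
            a = int(np.argmin(cand))
            J[k, j] = cand[a]
            back[k, j] = lo + a
    return J[1:, n - 1], (J, back)


def _backtrack(back: np.ndarray, k: int, n: int) -> np.ndarray:
    bounds = [n]
    j = n - 1
    for kk in range(k, 1, -1):
        i = int(back[kk, j])
        bounds.append(i)
        j = i - 1
    bounds.append(0)
    return np.array(bounds[::-1], dtype=int)


def best_segmentation_K(series, K: int, l_min: int = 1) -> Segmentation:
    """Exact least-squares optimal partition of ``series`` into K segments.

    Minimizes the mean contrast (within-segment sum of squares) by dynamic
    programming; every segment has at least ``l_min`` points.
    """
    y = np.asarray(series, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("series must be finite")
    if len(y) < K * l_min:
        raise ValueError(f"series of length {len(y)} cannot hold {K} segments of >= {l_min}")
    _, (J, back) = _dp(y, K, l_min)
    bounds = _backtrack(back, K, len(y))
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return Segmentation(bounds, means)


def select_K(curve_J: np.ndarray, s_threshold: float = 0.75) -> tuple[int, ContrastCurve]:
    """Pick K* from the contrast curve by the curvature rule.

    Returns the largest K (2 <= K <= Kmax-1) whose second derivative of the
    rescaled contrast exceeds ``s_threshold``; 1 when no K qualifies or the
    curve is degenerate (constant series).
    """
    J = np.asarray(curve_J, dtype=float)
    kmax = len(J)
    norm = np.full(kmax, np.nan)
    D = np.full(kmax, np.nan)
    if kmax < 3:
        warnings.warn("kmax < 3: cannot evaluate curvature, returning K*=1", stacklevel=2)
        return 1, ContrastCurve(J, norm, D, 1)
    span = J[0] - J[-1]
    if span <= 0:  # flat curve: a single segment already fits perfectly
        return 1, ContrastCurve(J, norm, D, 1)
    norm = (J[-1] - J) / (J[-1] - J[0]) * (kmax - 1) + 1
    D[1:-1] = norm[:-2] - 2 * norm[1:-1] + norm[2:]
    above = np.nonzero(D > s_threshold)[0]
    k_star = int(above[-1]) + 1 if len(above) else 1
    return k_star, ContrastCurve(J, norm, D, k_star)


def segment_series(series, config: SegmentationConfig | None = None,
                   force_k: int | None = None) -> tuple[Segmentation, ContrastCurve]:
    """Full segmentation pipeline: DP for all K, K* selection, backtrack.

    ``force_k`` bypasses the automatic choice and returns the optimal
    partition with exactly that many segments (the contrast curve is still
    computed and returned for diagnostics).
    """
    config = config or SegmentationConfig()
    y = np.asarray(series, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("series must be finite; trim or fill missing values first")
    n = len(y)
    kmax_eff = min(config.kmax, n // config.l_min)
    if n < 2 * config.l_min or kmax_eff < 2:
        seg = Segmentation(np.array([0, n]), np.array([y.mean()]))
        return seg, ContrastCurve(np.array([float(((y - y.mean()) ** 2).sum())]),
                                  np.array([np.nan]), np.array([np.nan]), 1)
    curve_J, (J, back) = _dp(y, kmax_eff, config.l_min)
    k_star, curve = select_K(curve_J, config.s_threshold)
    k = force_k if force_k is not None else k_star
    if not 1 <= k <= kmax_eff:
        raise ValueError(f"requested K={k} outside 1..{kmax_eff}")
    bounds = _backtrack(back, k, n)
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return Segmentation(bounds, means), curve


def prepare_series(values) -> tuple[np.ndarray, np.ndarray]:
    """Make an FPT series segmentable by dropping its undefined points.

    Passage times are undefined near the ends of a path (and occasionally in
    mid-break stretches the animal never leaves); those points carry no
    observation the contrast could fit, so they are removed rather than
    imputed — imputation across a long undefined run would manufacture a ramp
    that the mean contrast then treats as real structure. Returns the compact
    series and the index map giving the original position of each kept point
    (pass it to :class:`Segmentation` via ``index``).
    """
    v = np.asarray(values, dtype=float)
    keep = np.nonzero(np.isfinite(v))[0]
    if len(keep) == 0:
        raise ValueError("series has no finite values")
    return v[keep], keep


def snap_breakpoints(seg: Segmentation, path: RegularPath) -> list[pd.Timestamp]:
    """Dates of the interior breakpoints, snapped to real locations.

    Interpolated points carry no observation, so each breakpoint index is
    mapped to the timestamp of the nearest point backed by a real fix; exact
    ties go to the earlier one.
    """
    real_idx = np.nonzero(~path.data["is_interpolated"].to_numpy())[0]
    if len(real_idx) == 0:
        raise ValueError("path has no real locations to snap to")
    ts = path.timestamps
    out = []
    for b in seg.breakpoints:
        d = np.abs(real_idx - b)
        j = real_idx[int(np.argmin(d))]  # argmin takes the first = earlier on ties
        out.append(ts.iloc[int(j)])
    return out
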