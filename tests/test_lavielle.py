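import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fptmigrate.lavielle import (
    Segmentation,
    SegmentationConfig,
    best_segmentation_K,
    prepare_series,
    segment_series,
    select_K,
    snap_breakpoints,
)
from fptmigrate.trajectory import RegularPath


def exhaustive_best(y, K, l_min=1):
    """Enumerate every admissible breakpoint placement; return (J, bounds)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), K - 1):
        bounds = (0, *cuts, n)
        if any(b - a < l_min for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        J = sum(((y[a:b] - y[a:b].mean()) ** 2).sum() for a, b in zip(bounds[:-1], bounds[1:]))
        if J < best[0] - 1e-12:
            best = (J, bounds)
    return best


def seg_cost(y, seg):
    return sum(((y[a:b] - y[a:b].mean()) ** 2).sum() for a, b in seg.segments())


class TestBestSegmentationK:
    def test_perfect_step_found_exactly(self):
        y = np.array([0.0, 0, 0, 10, 10, 10])
        seg = best_segmentation_K(y, K=2)
        assert seg.bounds.tolist() == [0, 3, 6]
        assert seg_cost(y, seg) == 0.0
        assert seg.means.tolist() == [0.0, 10.0]

    def test_single_segment_is_total_sum_of_squares(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 25)
        seg = best_segmentation_K(y, K=1)
        assert seg.k == 1
        assert seg_cost(y, seg) == pytest.approx(((y - y.mean()) ** 2).sum())

    def test_dp_equals_exhaustive_n18_k3(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 18)
        seg = best_segmentation_K(y, K=3)
        J_star, _ = exhaustive_best(y, 3)
        assert seg_cost(y, seg) == pytest.approx(J_star)

    @pytest.mark.parametrize("seed,n,K,l_min", [
        (0, 12, 2, 1), (1, 15, 3, 2), (2, 20, 4, 1), (3, 16, 4, 3), (4, 20, 3, 5),
    ])
    def test_dp_equals_exhaustive_random(self, seed, n, K, l_min):
        rng = np.random.default_rng(seed)
        y = np.cumsum(rng.normal(0, 1, n))  # random-walk series
        seg = best_segmentation_K(y, K, l_min)
        J_star, _ = exhaustive_best(y, K, l_min)
        assert seg_cost(y, seg) == pytest.approx(J_star)
        assert (seg.lengths >= l_min).all()

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            best_segmentation_K(np.zeros(5), K=3, l_min=2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dp_matches_exhaustive_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        K = int(rng.integers(2, 5))
        y = rng.normal(0, 1, n)
        seg = best_segmentation_K(y, K)
        J_star, _ = exhaustive_best(y, K)
        assert seg_cost(y, seg) == pytest.approx(J_star)


class TestSelectK:
    def test_noiseless_step_selects_two(self):
        y = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        seg, curve = segment_series(y, SegmentationConfig(kmax=8))
        assert curve.k_star == 2
        assert seg.bounds.tolist() == [0, 10, 20]

    def test_constant_series_selects_one(self):
        seg, curve = segment_series(np.full(30, 3.0), SegmentationConfig(kmax=10))
        assert curve.k_star == 1
        assert seg.k == 1

    def test_kmax_below_three_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="kmax"):
            k, _ = select_K(np.array([5.0, 1.0]))
        assert k == 1


class TestSegmentSeries:
    def test_returned_J_matches_exhaustive_for_all_K(self):
        rng = np.random.default_rng(11)
        y = np.cumsum(rng.normal(0, 1, 18))
        _, curve = segment_series(y, SegmentationConfig(kmax=5))
        for K in range(1, 6):
            J_star, _ = exhaustive_best(y, K)
            assert curve.J[K - 1] == pytest.approx(J_star)

    def test_J_non_increasing(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 60)
        _, curve = segment_series(y, SegmentationConfig(kmax=12))
        assert (np.diff(curve.J) <= 1e-9).all()

    def test_lmin_irrelevant_on_clean_steps(self):
        y = np.concatenate([np.zeros(15), np.full(15, 8.0), np.full(15, 1.0)])
        s1, _ = segment_series(y, SegmentationConfig(kmax=4, l_min=1), force_k=3)
        s10, _ = segment_series(y, SegmentationConfig(kmax=4, l_min=10), force_k=3)
        assert s1.bounds.tolist() == s10.bounds.tolist()

    def test_affine_transform_leaves_breakpoints(self):
        rng = np.random.default_rng(17)
        y = np.cumsum(rng.normal(0, 1, 40))
        a, b = 3.7, -12.0
        s_raw, c_raw = segment_series(y, SegmentationConfig(kmax=6))
        s_aff, c_aff = segment_series(a * y + b, SegmentationConfig(kmax=6))
        assert s_raw.bounds.tolist() == s_aff.bounds.tolist()
        np.testing.assert_allclose(c_aff.J, a * a * c_raw.J, rtol=1e-9)

    def test_k_equals_n_gives_zero_contrast(self):
        rng = np.random.default_rng(19)
        y = rng.normal(0, 1, 10)
        seg, curve = segment_series(y, SegmentationConfig(kmax=10), force_k=10)
        assert seg.k == 10
        assert curve.J[-1] == pytest.approx(0.0, abs=1e-9)

    def test_short_series_single_segment(self):
        seg, _ = segment_series(np.array([1.0, 2.0]), SegmentationConfig(kmax=30, l_min=10))
        assert seg.k == 1


class TestPrepareSeries:
    def test_drops_undefined_and_maps_indices(self):
        v = np.array([np.nan, np.nan, 1.0, 2.0, np.nan, 3.0, np.nan])
        series, index = prepare_series(v)
        assert series.tolist() == [1.0, 2.0, 3.0]
        assert index.tolist() == [2, 3, 5]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            prepare_series(np.full(4, np.nan))


class TestSnapBreakpoints:
    def _path(self, interp_flags):
        n = len(interp_flags)
        ts = pd.Timestamp("2000-01-01") + pd.to_timedelta(np.arange(n) * 12, unit="h")
        return RegularPath(
            pd.DataFrame({"timestamp": ts, "x": 0.0, "y": 0.0,
                          "is_interpolated": interp_flags, "gap_h": 0.0}),
            12.0, "t",
        )

    def test_breakpoint_on_real_fix_keeps_its_date(self):
        path = self._path([False, True, False, True, False])
        seg = Segmentation(np.array([0, 2, 5]), np.array([0.0, 1.0]))
        assert snap_breakpoints(seg, path) == [path.timestamps.iloc[2]]

    def test_interpolated_breakpoint_snaps_to_nearer_fix(self):
        # real fixes at 0 and 10; breakpoint at 3 -> nearer fix is 0
        flags = [False] + [True] * 9 + [False]
        seg = Segmentation(np.array([0, 3, 11]), np.array([0.0, 1.0]))
        assert snap_breakpoints(seg, self._path(flags)) == [
            self._path(flags).timestamps.iloc[0]
        ]

    def test_equidistant_tie_goes_to_earlier_fix(self):
        flags = [False] + [True] * 3 + [False]  # real at 0 and 4, break at 2
        path = self._path(flags)
        seg = Segmentation(np.array([0, 2, 5]), np.array([0.0, 1.0]))
        assert snap_breakpoints(seg, path) == [path.timestamps.iloc[0]]
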