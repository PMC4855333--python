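import numpy as np
import pandas as pd
import pytest

from fptmigrate.fpt import (
    DEFAULT_RADII_KM,
    FptProfile,
    VarianceProfile,
    compute_fpt,
    select_rmax,
    variance_profile,
)
from fptmigrate.trajectory import RegularPath


def make_path(xy, interval_h=12.0):
    xy = np.asarray(xy, dtype=float)
    ts = pd.Timestamp("2000-01-01") + pd.to_timedelta(
        np.arange(len(xy)) * interval_h, unit="h"
    )
    return RegularPath(
        pd.DataFrame(
            {
                "timestamp": ts,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "is_interpolated": False,
                "gap_h": 0.0,
            }
        ),
        interval_h,
        "t",
    )


def oracle_fpt(xy, i, r, dt_days, n_sub=5000):
    """Independent brute force: march in tiny substeps until the distance
    from point i first exceeds r, in each direction; None when never."""
    xy = np.asarray(xy, dtype=float)
    c = xy[i]

    def march(order):
        t = 0.0
        for a, b in zip(order[:-1], order[1:]):
            for k in range(1, n_sub + 1):
                p = a + (b - a) * k / n_sub
                if np.hypot(*(p - c)) > r:
                    return t + dt_days * k / n_sub
            t += dt_days
        return None

    fwd = march(xy[i:])
    bwd = march(xy[i::-1])
    if fwd is None or bwd is None:
        return None
    return fwd + bwd


class TestComputeFpt:
    def test_straight_constant_speed_closed_form(self):
        # 25 km per 12-h step = 50 km/day; r = 25 -> FPT = 2r/v = 1 day
        xy = np.c_[np.arange(10) * 25.0, np.zeros(10)]
        prof = compute_fpt(make_path(xy), r=25.0)
        interior = prof.values[2:-2]
        assert np.allclose(interior, 1.0)

    def test_path_ends_are_missing(self):
        xy = np.c_[np.arange(10) * 25.0, np.zeros(10)]
        prof = compute_fpt(make_path(xy), r=25.0)
        assert np.isnan(prof.values[0]) and np.isnan(prof.values[-1])

    def test_matches_brute_force_oracle_on_zigzag(self):
        rng = np.random.default_rng(42)
        steps = rng.normal(0, 9, (39, 2))
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        path = make_path(xy)
        prof = compute_fpt(path, r=25.0)
        for i in range(0, 40, 3):
            expect = oracle_fpt(xy, i, 25.0, 0.5)
            if expect is None:
                assert np.isnan(prof.values[i])
            else:
                assert prof.values[i] == pytest.approx(expect, abs=2e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_rotation_translation_reversal(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 8, (30, 2)), axis=0)
        base = compute_fpt(make_path(xy), 20.0).values
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + [123.0, -77.0]
        rotated = compute_fpt(make_path(moved), 20.0).values
        reversed_ = compute_fpt(make_path(xy[::-1]), 20.0).values
        np.testing.assert_allclose(rotated, base, rtol=1e-9)
        np.testing.assert_allclose(reversed_[::-1], base, rtol=1e-9)

    def test_scales_with_inverse_speed(self):
        # same geometry traversed twice as fast -> every FPT halves exactly
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 8, (30, 2)), axis=0)
        slow = compute_fpt(make_path(xy, interval_h=12.0), 20.0).values
        fast = compute_fpt(make_path(xy, interval_h=6.0), 20.0).values
        np.testing.assert_allclose(fast, slow / 2.0, rtol=1e-9)

    def test_radius_exceeding_extent_warns_all_missing(self):
        xy = np.c_[np.arange(5) * 1.0, np.zeros(5)]
        with pytest.warns(UserWarning, match="exceeds the path extent"):
            prof = compute_fpt(make_path(xy), r=1000.0)
        assert np.isnan(prof.values).all()


class TestVarianceProfile:
    def test_constant_speed_straight_path_zero_variance(self):
        xy = np.c_[np.arange(60) * 10.0, np.zeros(60)]
        vp = variance_profile([make_path(xy)], radii=[10, 25, 40])
        assert np.allclose(vp.mean_s[np.isfinite(vp.mean_s)], 0.0, atol=1e-12)

    def test_duplicated_path_zero_se(self):
        rng = np.random.default_rng(9)
        xy = np.cumsum(rng.normal(0, 8, (50, 2)), axis=0)
        p = make_path(xy)
        vp = variance_profile([p, p], radii=[10, 20, 30])
        assert np.allclose(vp.se[np.isfinite(vp.mean_s)], 0.0, atol=1e-12)

    def test_simulated_paths_show_interior_variance_peak(self, sim_2lb, sim_1lb):
        radii = np.arange(10, 151, 10)
        vp = variance_profile([sim_2lb.path, sim_1lb.path], radii=radii)
        r_max = select_rmax(vp)
        assert radii[0] < r_max < radii[-1]


class TestSelectRmax:
    def test_argmax(self):
        vp = VarianceProfile(np.array([10.0, 25, 40]), np.array([1.0, 3, 2]),
                             np.zeros(3), np.full(3, 5))
        assert select_rmax(vp) == 25.0

    def test_tie_takes_smaller_radius(self):
        vp = VarianceProfile(np.array([10.0, 25, 40]), np.array([1.0, 3, 3]),
                             np.zeros(3), np.full(3, 5))
        assert select_rmax(vp) == 25.0

    def test_monotone_curve_warns_at_edge(self):
        vp = VarianceProfile(np.array([10.0, 25, 40]), np.array([1.0, 2, 3]),
                             np.zeros(3), np.full(3, 5))
        with pytest.warns(UserWarning, match="edge"):
            assert select_rmax(vp) == 40.0

    def test_default_radius_grid(self):
        assert DEFAULT_RADII_KM[0] == 10 and DEFAULT_RADII_KM[-1] == 300
        assert (np.diff(DEFAULT_RADII_KM) > 0).all()
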