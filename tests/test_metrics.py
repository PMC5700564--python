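import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from piipath import (
    MetricConfig,
    MetricRecord,
    ScalingConstants,
    compute_metrics,
    compute_scaling,
    movement_index_record,
    site_fidelity,
    speed_at,
    standardize,
    step_geometry,
    straightness,
    turn_standard,
)
from piipath.errors import DataError
from piipath.metrics import CAPPED_HIGH, StepGeometry, _site_fidelity_all

from conftest import make_trajectory as make_traj


def brute_force_fidelity(traj, seq, radius, window, max_poss):
    """O(n^2)-style pairwise oracle, independent of the KD-tree path."""
    xy = traj.coords()
    mins = traj.minutes()
    valid = traj.valid_mask()
    if not valid[seq]:
        return math.nan
    dists = []
    for j in range(len(valid)):
        if j == seq or not valid[j]:
            continue
        # same distance primitive as production; the independent part of
        # this oracle is the O(n^2) scan, not the sqrt implementation
        d = float(np.hypot(xy[j, 0] - xy[seq, 0], xy[j, 1] - xy[seq, 1]))
        if d <= radius and abs(mins[j] - mins[seq]) <= window:
            dists.append(d)
    if not dists:
        return 0.0
    # neighbor search is the independent part; use the standard mean
    # primitive so exact equality with the production path is meaningful
    return float(np.mean(np.asarray(dists))) * (len(dists) / max_poss)


class TestStepGeometry:
    def test_collinear(self, traj_factory):
        traj = traj_factory([(0, 0), (1000, 0), (2000, 0)])
        g = step_geometry(traj, 1)
        assert (g.d1, g.d2, g.c) == (1000, 1000, 2000)
        assert g.turn_deg == pytest.approx(0.0)
        assert g.dt1 == g.dt2 == 240.0

    def test_right_triangle(self, traj_factory):
        traj = traj_factory([(0, 0), (300, 0), (300, 400)])
        g = step_geometry(traj, 1)
        assert (g.d1, g.d2) == (300, 400)
        assert g.c == pytest.approx(500.0)
        assert g.turn_deg == pytest.approx(90.0)

    def test_near_reversal(self, traj_factory):
        traj = traj_factory([(0, 0), (1000, 0), (10, 0)])
        g = step_geometry(traj, 1)
        assert (g.d1, g.d2, g.c) == (1000, 990, 10)
        assert g.turn_deg == pytest.approx(180.0)

    def test_endpoints_undefined(self, traj_factory):
        traj = traj_factory([(0, 0), (100, 0), (200, 0)])
        assert step_geometry(traj, 0) is None
        assert step_geometry(traj, 2) is None

    def test_gap_policy(self, traj_factory):
        # neighbor across a single missed fix (8 h) is allowed; 12 h is not
        traj = traj_factory([(0, 0), None, (200, 0), (300, 0), None, None, (600, 0)])
        assert step_geometry(traj, 2) is not None
        assert step_geometry(traj, 3) is None  # forward gap 12 h

    def test_invalid_fix_undefined(self, traj_factory):
        traj = traj_factory([(0, 0), None, (200, 0)])
        assert step_geometry(traj, 1) is None


class TestScalarMetrics:
    def test_speed_hand_values(self):
        g = StepGeometry(1200, 1200, 2400, 240, 240, 0)
        assert speed_at(g) == pytest.approx(5.0)
        g = StepGeometry(0, 0, 0, 240, 240, 0)
        assert speed_at(g) == 0.0
        g = StepGeometry(600, 0, 600, 240, 240, 0)
        assert speed_at(g) == pytest.approx(1.25)

    @pytest.mark.parametrize("deg,expected", [(0, 0.0), (180, 1.0), (90, 0.5)])
    def test_turn_standard(self, deg, expected):
        g = StepGeometry(10, 10, 20, 240, 240, deg)
        assert turn_standard(g) == expected

    def test_straightness_hand_values(self):
        assert straightness(StepGeometry(500, 500, 1000, 240, 240, 0)) == 1.0
        assert straightness(StepGeometry(300, 400, 500, 240, 240, 90)) == pytest.approx(1.4)
        assert straightness(StepGeometry(1000, 990, 10, 240, 240, 180)) == pytest.approx(199.0)

    def test_straightness_chord_floor_sentinel(self):
        g = StepGeometry(500, 500, 0.5, 240, 240, 180)
        assert straightness(g) == CAPPED_HIGH

    def test_non_positive_dt_rejected(self):
        with pytest.raises(DataError):
            StepGeometry(1, 1, 2, 0, 240, 0)

    def test_triangle_inequality_enforced(self):
        with pytest.raises(DataError):
            StepGeometry(100, 100, 300, 240, 240, 0)


class TestSiteFidelity:
    def test_isolated_fix_is_zero(self, traj_factory):
        traj = traj_factory([(0, 0), (5000, 0), (10000, 0)])
        assert site_fidelity(traj, 1) == 0.0

    def test_single_neighbor_hand_value(self, traj_factory):
        traj = traj_factory([(0, 0), (50, 0), (10000, 0)])
        # one neighbor at 50 m over 672 possible -> 50/672
        assert site_fidelity(traj, 0) == pytest.approx(50.0 / 672.0)

    def test_coincident_fixes_give_zero(self, traj_factory):
        traj = traj_factory([(0, 0), (0, 0), (0, 0)])
        assert site_fidelity(traj, 1) == 0.0

    def test_vectorized_matches_brute_force(self, sim60):
        traj = sim60.trajectory
        config = MetricConfig()
        fast = _site_fidelity_all(traj, config)
        max_poss = config.resolved_max_neighbors(traj.nominal_interval)
        for seq in range(0, len(traj), 17):
            expected = brute_force_fidelity(
                traj, seq, config.fidelity_radius, config.fidelity_window_min, max_poss
            )
            if math.isnan(expected):
                assert math.isnan(fast[seq])
            else:
                assert fast[seq] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_added_mean_distance_neighbor(self, traj_factory):
        base = traj_factory([(0, 0), (30, 0), (9000, 0), (9500, 0)])
        f0 = site_fidelity(base, 0)
        # add a neighbor at exactly the current mean distance (30 m)
        more = traj_factory([(0, 0), (30, 0), (0, 30), (9000, 0), (9500, 0)])
        f1 = site_fidelity(more, 0)
        assert f1 >= f0


class TestScalingAndIndex:
    def test_max_speed(self, traj_factory):
        df = pd.DataFrame(
            {
                "speed": [1.0, 2.0, 10.0],
                "straightness_raw": [1.0, 1.0, 1.0],
                "site_fidelity_raw": [0, 0, 0],
                "defined": True,
            }
        )
        assert compute_scaling(df).max_speed == 10.0

    def test_percentile_linear_interpolation(self):
        df = pd.DataFrame(
            {
                "speed": 1.0,
                "straightness_raw": np.arange(1.0, 101.0),
                "site_fidelity_raw": 0.0,
                "defined": True,
            }
        )
        assert compute_scaling(df).straightness_p90 == pytest.approx(90.1)

    def test_single_record(self):
        df = pd.DataFrame(
            {
                "speed": [3.0],
                "straightness_raw": [2.0],
                "site_fidelity_raw": [0.4],
                "defined": [True],
            }
        )
        c = compute_scaling(df)
        assert (c.max_speed, c.straightness_p90, c.max_fidelity) == (3.0, 2.0, 0.4)

    def test_all_undefined_is_error(self):
        df = pd.DataFrame(
            {"speed": [1.0], "straightness_raw": [1.0], "site_fidelity_raw": [0.0],
             "defined": [False]}
        )
        with pytest.raises(DataError):
            compute_scaling(df)

    def test_sentinel_tail_falls_back_to_max_finite(self):
        df = pd.DataFrame(
            {
                "speed": 1.0,
                "straightness_raw": [2.0] + [CAPPED_HIGH] * 9,
                "site_fidelity_raw": 0.0,
                "defined": True,
            }
        )
        assert compute_scaling(df).straightness_p90 == 2.0

    def _constants(self):
        return ScalingConstants("A1", max_speed=10.0, straightness_p90=2.0, max_fidelity=1.0)

    def test_index_extremes(self):
        c = self._constants()
        top = MetricRecord(
            seq=0, speed=0.0, ta_standard=1.0, straightness_raw=5.0,
            site_fidelity_raw=1.0, defined=True,
        )
        assert movement_index_record(top, c) == 4.0
        bottom = MetricRecord(
            seq=0, speed=10.0, ta_standard=0.0, straightness_raw=0.0,
            site_fidelity_raw=0.0, defined=True,
        )
        assert movement_index_record(bottom, c) == 0.0

    def test_index_midpoint(self):
        c = self._constants()
        rec = MetricRecord(
            seq=0, speed=5.0, ta_standard=0.5, straightness_raw=1.0,
            site_fidelity_raw=0.5, defined=True,
        )
        assert movement_index_record(rec, c) == pytest.approx(2.0)

    def test_undefined_record_gives_nan(self):
        assert math.isnan(movement_index_record(MetricRecord(seq=0), self._constants()))

    def test_top_decile_straightness_maps_to_one(self, sim60):
        metrics = compute_metrics(sim60.trajectory)
        constants = compute_scaling(metrics, "S")
        std = standardize(metrics, constants)
        d = std[std["defined"]]
        high = d[d["straightness_raw"] >= constants.straightness_p90]
        assert (high["straightness_std"] == 1.0).all()


class TestTableProperties:
    def test_bounds_on_simulated_record(self, sim60):
        metrics = compute_metrics(sim60.trajectory)
        constants = compute_scaling(metrics, "S")
        std = standardize(metrics, constants)
        d = std[std["defined"]]
        assert (d["straightness_raw"] >= 1.0 - 1e-12).all()
        for col in ("speed_std", "ta_std", "straightness_std", "fidelity_std"):
            assert d[col].between(0, 1).all()
        assert d["index"].between(0, 4).all()

    def test_first_last_undefined(self, traj_factory):
        traj = traj_factory([(0, 0), (10, 0), (20, 0), (30, 0)])
        metrics = compute_metrics(traj)
        assert not metrics.loc[0, "defined"]
        assert not metrics.loc[len(traj) - 1, "defined"]

    @settings(max_examples=20, deadline=None)
    @given(
        angle=st.floats(0, 2 * math.pi, allow_nan=False),
        dx=st.floats(-1e5, 1e5, allow_nan=False),
        dy=st.floats(-1e5, 1e5, allow_nan=False),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = np.array([(0, 0), (300, 50), (500, 400), (450, 380), (700, 900)], float)
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = pts @ rot.T + np.array([dx, dy])
        m1 = compute_metrics(make_traj(pts))
        m2 = compute_metrics(make_traj(moved))
        for col in ("speed", "ta_standard", "straightness_raw", "site_fidelity_raw"):
            np.testing.assert_allclose(
                m1[col].to_numpy(), m2[col].to_numpy(), rtol=1e-7, atol=1e-7
            )

    def test_rigid_motion_invariance_concrete(self, traj_factory):
        pts = [(0, 0), (300, 50), (500, 400), (450, 380), (700, 900)]
        angle, dx, dy = 0.83, 12345.0, -9876.0
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = [tuple(np.array(p) @ rot.T + np.array([dx, dy])) for p in pts]
        m1 = compute_metrics(traj_factory(pts))
        m2 = compute_metrics(traj_factory(moved))
        for col in ("speed", "ta_standard", "straightness_raw", "site_fidelity_raw"):
            np.testing.assert_allclose(
                m1[col].to_numpy(), m2[col].to_numpy(), rtol=1e-9, atol=1e-9
            )

    def test_time_dilation_halves_speed(self, traj_factory):
        pts = [(0, 0), (300, 50), (500, 400), (450, 380), (700, 900)]
        fast = traj_factory(pts, interval=240.0)
        slow = traj_factory(pts, interval=480.0)
        m_fast = compute_metrics(fast)
        config = MetricConfig(fidelity_window_min=2 * MetricConfig().fidelity_window_min,
                              max_possible_neighbors=672)
        m_slow = compute_metrics(slow, config)
        np.testing.assert_allclose(
            m_slow["speed"].to_numpy(), m_fast["speed"].to_numpy() / 2.0, rtol=1e-12
        )
        np.testing.assert_allclose(
            m_slow["ta_standard"].to_numpy(), m_fast["ta_standard"].to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(
            m_slow["straightness_raw"].to_numpy(),
            compute_metrics(fast, MetricConfig(max_possible_neighbors=672))["straightness_raw"].to_numpy(),
            rtol=1e-12,
        )
        # with the window doubled the fidelity neighbor sets are unchanged
        np.testing.assert_allclose(
            m_slow["site_fidelity_raw"].to_numpy(),
            compute_metrics(fast, MetricConfig(max_possible_neighbors=672))["site_fidelity_raw"].to_numpy(),
            rtol=1e-12,
        )
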