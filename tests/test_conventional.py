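import math

import numpy as np
import pytest

from mazenet.conventional import (count_errors, daily_average,
                                  fit_learning_curve, hole_visit_events,
                                  latency_and_distance, normalize_series,
                                  probe_latency, probe_profile)
from mazenet.geometry import hole_positions, region_of

from conftest import make_traj, sample_arc, sample_polyline


def _hole_path(spec, holes, end_at_target=True):
    """Polyline through the given hole centers (radial in/out via gates)."""
    pos = hole_positions(spec)
    waypoints = [[0.0, 0.0]]
    seq = list(holes) + ([0] if end_at_target else [])
    for h in seq:
        gate = pos[h] * (1 - (spec.hole_area_radius + 60) /
                         np.linalg.norm(pos[h]))
        waypoints += [gate, pos[h], gate]
    return sample_polyline(waypoints)


class TestHoleVisitEvents:
    def test_no_hole_contact_gives_no_events(self, bm1):
        traj = make_traj([[0, 0], [50, 50], [100, 0]])
        assert hole_visit_events(traj, bm1) == []

    def test_reentry_is_a_new_visit(self, bm1):
        traj = _hole_path(bm1, [3, 3], end_at_target=False)
        events = hole_visit_events(traj, bm1)
        assert [e.hole for e in events] == [3, 3]

    def test_ring_sweep_visits_all_holes_in_order(self, bm1):
        """A circular sweep along the hole ring produces one event per hole
        in angular order, matching a per-sample region oracle."""
        traj = sample_arc(bm1.hole_ring_radius, math.radians(90),
                          math.radians(90 + 360), speed=400.0)
        traj = traj.slice(0, len(traj) - 5)  # stop short of re-entering hole 0
        events = hole_visit_events(traj, bm1)
        assert [e.hole for e in events] == list(range(12))
        # oracle: per-sample region labels agree with the event intervals
        for ev in events:
            i = int(round(ev.t_entry * 20))
            assert region_of(traj.points[i], bm1).hole == ev.hole


class TestCountErrors:
    def test_straight_run_has_no_errors(self, bm1):
        traj = sample_polyline([[0, 0], hole_positions(bm1)[0]])
        assert count_errors(traj, bm1) == 0

    def test_three_distinct_nontarget_visits(self, bm1):
        traj = _hole_path(bm1, [1, 2, 3])
        assert count_errors(traj, bm1) == 3

    def test_reentry_counts_twice(self, bm1):
        traj = _hole_path(bm1, [5, 5])
        assert count_errors(traj, bm1) == 2

    def test_visits_after_goal_do_not_count(self, bm1):
        traj = _hole_path(bm1, [1, 0, 2], end_at_target=False)
        assert count_errors(traj, bm1) == 1

    def test_rotation_invariance_via_normalization(self, bm1):
        """Error counts are invariant under rotating the whole scene (goal
        hole moved, trajectory rotated accordingly, then normalized)."""
        import dataclasses
        from mazenet.geometry import normalize_to_target, rotate_points
        traj = _hole_path(bm1, [1, 5, 5])
        base = count_errors(traj, bm1)
        for k in (2, 7, 11):
            rot = rotate_points(traj.points, math.radians(k * 30))
            rotated = dataclasses.replace(
                traj, points=rot,
                meta=dataclasses.replace(traj.meta, target_index=k))
            back = normalize_to_target(rotated, bm1)
            assert count_errors(back, bm1) == base


class TestLatencyAndDistance:
    def test_stationary_trajectory(self, bm1):
        traj = make_traj(np.tile([[10.0, 10.0]], (100, 1)))
        lat, dist = latency_and_distance(traj, bm1)
        assert lat == 600.0 and dist == 0.0

    def test_straight_constant_speed_run(self, bm1):
        # 400 mm at 40 mm/s; the scoring circle is entered at 320 mm / 8 s
        traj = sample_polyline([[0, 0], hole_positions(bm1)[0]], speed=40.0)
        lat, dist = latency_and_distance(traj, bm1)
        assert lat == pytest.approx(8.0, abs=0.1)
        assert dist == pytest.approx(320.0, abs=5.0)

    def test_distance_bounds_net_displacement(self, bm1):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(0, 5, (200, 2)), axis=0)
        traj = make_traj(pts)
        _, dist = latency_and_distance(traj, bm1)
        assert dist >= np.linalg.norm(pts[-1] - pts[0]) - 1e-9


class TestDailyAverage:
    def test_mean_of_three_trials(self):
        assert daily_average([3, 6, 9], [1, 1, 1]) == {1: 6.0}

    def test_single_trial_day(self):
        assert daily_average([5, 1, 2, 3], [1, 2, 2, 2]) == {1: 5.0, 2: 2.0}

    def test_constant_series(self):
        out = daily_average([4.0] * 6, [1, 1, 1, 2, 2, 2])
        assert out == {1: 4.0, 2: 4.0}


class TestNormalizeSeries:
    def test_uniform(self):
        np.testing.assert_allclose(normalize_series([2, 2, 2, 2]), 0.25)

    def test_proportions(self):
        np.testing.assert_allclose(normalize_series([1, 3]), [0.25, 0.75])

    def test_sums_to_one(self):
        rng = np.random.default_rng(5)
        out = normalize_series(rng.random(50))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_series([0.0, 0.0])


class TestFitLearningCurve:
    @pytest.mark.parametrize("alpha", [2.0, 5.0, 10.0])
    @pytest.mark.parametrize("beta", [0.05, 0.2, 0.5])
    def test_noiseless_recovery(self, alpha, beta):
        t = np.arange(1, 19)
        fit = fit_learning_curve(alpha * np.exp(-beta * t))
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.beta == pytest.approx(beta, abs=1e-6)

    def test_constant_series_gives_zero_decay(self):
        fit = fit_learning_curve(np.full(12, 3.5))
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.alpha == pytest.approx(3.5, abs=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        """Parameter recovery under Gaussian noise: mean decay estimate
        within +-0.05 of the truth over 200 replicates."""
        rng = np.random.default_rng(6)
        t = np.arange(1, 19)
        truth = 5 * np.exp(-0.3 * t)
        betas = []
        for _ in range(200):
            fit = fit_learning_curve(truth + rng.normal(0, 0.1, 18))
            betas.append(fit.beta)
        assert abs(np.mean(betas) - 0.3) < 0.05

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_learning_curve([1.0, 0.5, 0.2])


class TestProbeProfile:
    def test_parked_at_target(self, bm1):
        pos = hole_positions(bm1)[0]
        traj = make_traj(np.tile(pos, (20 * 200, 1)), phase="probe")
        prof = probe_profile(traj, bm1, window=150.0)
        assert prof.dwell_by_offset[0] == pytest.approx(150.0, abs=0.1)
        assert sum(v for k, v in prof.dwell_by_offset.items() if k != 0) == 0

    def test_dwell_sum_never_exceeds_window(self, bm1):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 8, (4000, 2)), axis=0)
        traj = make_traj(pts, phase="probe")
        prof = probe_profile(traj, bm1, window=150.0)
        assert prof.total_dwell <= prof.window + 1e-9

    def test_uniform_sweep_gives_equal_dwell(self, bm1):
        traj = sample_arc(bm1.hole_ring_radius, math.radians(90),
                          math.radians(90 + 720), speed=400.0)
        prof = probe_profile(traj, bm1, window=traj.duration + 1)
        dwells = np.array(list(prof.dwell_by_offset.values()))
        assert dwells.std() / dwells.mean() < 0.1

    def test_offsets_are_the_twelve_hole_positions(self, bm1):
        traj = make_traj(np.zeros((3100, 2)), phase="probe")
        prof = probe_profile(traj, bm1)
        assert sorted(prof.dwell_by_offset) == list(range(-150, 181, 30))


class TestProbeLatency:
    def _stay(self, bm1, stay_s, t_before=30.0):
        pos = hole_positions(bm1)[0]
        pre = np.tile([[0.0, 0.0]], (int(t_before * 20), 1))
        stay = np.tile(pos, (int(stay_s * 20), 1))
        post = np.tile([[0.0, 0.0]], (200, 1))
        return make_traj(np.vstack([pre, stay, post]), phase="probe")

    def test_first_long_stay_start_time(self, bm1):
        traj = self._stay(bm1, 12.0, t_before=30.0)
        assert probe_latency(traj, bm1) == pytest.approx(30.0, abs=0.1)

    def test_short_stays_never_qualify(self, bm1):
        pos = hole_positions(bm1)[0]
        blocks = []
        for _ in range(5):
            blocks.append(np.tile(pos, (100, 1)))        # 5-s stay
            blocks.append(np.tile([[0.0, 0.0]], (40, 1)))
        traj = make_traj(np.vstack(blocks), phase="probe")
        assert probe_latency(traj, bm1) is None

    def test_first_of_two_qualifying_stays(self, bm1):
        pos = hole_positions(bm1)[0]
        seq = [np.tile([[0.0, 0.0]], (40 * 20, 1)),
               np.tile(pos, (11 * 20, 1)),
               np.tile([[0.0, 0.0]], (39 * 20, 1)),
               np.tile(pos, (12 * 20, 1))]
        traj = make_traj(np.vstack(seq), phase="probe")
        assert probe_latency(traj, bm1) == pytest.approx(40.0, abs=0.1)
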