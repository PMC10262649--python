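"""Shared fixtures and trajectory builders for the test suite."""

import numpy as np
import pytest

from mazenet.geometry import MazeSpec, builtin_spec
from mazenet.trajectory_io import Trajectory, TrialMeta

DT = 0.05  # 20 Hz


@pytest.fixture
def bm1() -> MazeSpec:
    return builtin_spec("BM1")


@pytest.fixture
def bm3() -> MazeSpec:
    return builtin_spec("BM3")


def make_traj(points, rate=20.0, **meta_kwargs) -> Trajectory:
    """Wrap a point array into a uniformly sampled trajectory."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    times = np.arange(len(points)) / rate
    return Trajectory(times=times, points=points,
                      meta=TrialMeta(**meta_kwargs), sampling_rate=rate)


def sample_polyline(waypoints, speed=200.0, rate=20.0, **meta_kwargs
                    ) -> Trajectory:
    """Constant-speed sampling along a polyline (vertices included)."""
    pts = [np.asarray(waypoints[0], dtype=float)]
    step = speed / rate
    for a, b in zip(waypoints, waypoints[1:]):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step)))
        for i in range(1, n + 1):
            pts.append(a + (b - a) * i / n)
    return make_traj(np.asarray(pts), rate=rate, **meta_kwargs)


def sample_arc(radius, angle_from, angle_to, speed=200.0, rate=20.0,
               **meta_kwargs) -> Trajectory:
    """Constant-speed sampling along a circular arc (radians, signed sweep
    taken directly from angle_from -> angle_to)."""
    sweep = angle_to - angle_from
    arc_len = abs(sweep) * radius
    n = max(2, int(np.ceil(arc_len * rate / speed)))
    ang = angle_from + sweep * np.arange(n + 1) / n
    pts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return make_traj(pts, rate=rate, **meta_kwargs)
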