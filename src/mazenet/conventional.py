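"""Conventional Barnes-maze scoring.

Per-trial features of spatial learning: error counts (visits to nontarget
hole areas), latency and travel distance to the goal, per-day averages,
probe-test dwell profiles, and exponential learning-curve fits
``y = alpha * exp(-beta * t)`` with trial index ``t``.  A lower decay
``beta`` means the learning curve takes longer to converge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .geometry import MazeSpec, hole_positions, region_labels
from .trajectory_io import Trajectory

logger = logging.getLogger("mazenet")

__all__ = [
    "HoleVisit",
    "LearningCurveFit",
    "ProbeProfile",
    "hole_visit_events",
    "count_errors",
    "latency_and_distance",
    "daily_average",
    "normalize_series",
    "fit_learning_curve",
    "probe_profile",
    "probe_latency",
]

TRIAL_CAP_S = 600.0      # training trials end after 10 min
PROBE_WINDOW_S = 150.0   # first half of the 300-s probe trial
PROBE_MIN_STAY_S = 10.0  # ">10 s in a row" probe-latency rule


@dataclass(frozen=True)
class HoleVisit:
    hole: int
    t_entry: float
    t_exit: float      # time of the last sample inside the area
    n_samples: int


def hole_visit_events(traj: Trajectory, spec: MazeSpec,
                      min_visit_duration: float = 0.0) -> List[HoleVisit]:
    """Ordered visits to hole areas.

    A visit is a maximal run of consecutive samples inside one hole's
    scoring circle; leaving and re-entering starts a new visit.  Runs
    shorter than ``min_visit_duration`` seconds are dropped (default keeps
    single-sample visits; raise it to debounce
    noisy tracking).
    """
    if len(traj) == 0:
        return []
    labels = region_labels(traj.points, spec, warn_off_arena=False)
    visits: List[HoleVisit] = []
    change = np.where(np.diff(labels) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(labels) - 1]])
    for s, e in zip(starts, ends):
        lab = labels[s]
        if lab < 0:
            continue
        n = int(e - s + 1)
        if n * traj.dt >= min_visit_duration or min_visit_duration <= 0:
            visits.append(HoleVisit(int(lab), float(traj.times[s]),
                                    float(traj.times[e]), n))
    return visits


def first_target_entry(visits: Sequence[HoleVisit],
                       target: int) -> Optional[float]:
    for v in visits:
        if v.hole == target:
            return v.t_entry
    return None


def count_errors(traj: Trajectory, spec: MazeSpec,
                 until_goal: bool = True,
                 window: Optional[float] = None,
                 min_visit_duration: float = 0.0) -> int:
    """Number of visits to nontarget hole areas.

    Training trials (``until_goal=True``) count visits up to the first
    target entry; probe trials count over the scoring ``window`` (seconds
    from trial start) with ``until_goal=False``.
    """
    visits = hole_visit_events(traj, spec, min_visit_duration)
    t0 = traj.times[0] if len(traj) else 0.0
    cutoff = math.inf
    if until_goal:
        goal_t = first_target_entry(visits, spec.target_index)
        if goal_t is not None:
            cutoff = goal_t
    if window is not None:
        cutoff = min(cutoff, t0 + window)
    return sum(1 for v in visits
               if v.hole != spec.target_index and v.t_entry < cutoff)


def latency_and_distance(traj: Trajectory, spec: MazeSpec,
                         cap: float = TRIAL_CAP_S) -> Tuple[float, float]:
    """(latency s, travel distance mm) from trial start to first entry into
    the target hole area; latency is capped at ``cap`` (and distance runs to
    trial end) if the goal is never entered."""
    if len(traj) < 2:
        return cap, 0.0
    labels = region_labels(traj.points, spec, warn_off_arena=False)
    inside = np.where(labels == spec.target_index)[0]
    steps = traj.step_lengths()
    if len(inside) == 0:
        return cap, float(steps.sum())
    i = int(inside[0])
    latency = float(traj.times[i] - traj.times[0])
    return min(latency, cap), float(steps[:i].sum())


def daily_average(values: Sequence[float], days: Sequence[int],
                  trials_per_day: int = 3) -> Dict[int, float]:
    """Arithmetic mean of a per-trial feature within each day.

    Days with fewer than ``trials_per_day`` trials are averaged over what is
    available, with a logged warning; empty days are simply absent.
    """
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=int)
    out: Dict[int, float] = {}
    for day in np.unique(days):
        sel = values[days == day]
        sel = sel[~np.isnan(sel)]
        if len(sel) == 0:
            continue
        if len(sel) < trials_per_day:
            logger.warning("day %d has %d/%d trials; averaging available",
                           day, len(sel), trials_per_day)
        out[int(day)] = float(sel.mean())
    return out


def normalize_series(series: Sequence[float]) -> np.ndarray:
    """Normalize a nonnegative per-trial series to unit sum (so learning
    curves of latency/distance are unitless and comparable across scales)."""
    x = np.asarray(series, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalize_series requires nonnegative values")
    total = x.sum()
    if total <= 0:
        raise ValueError("normalize_series requires a positive sum")
    return x / total


@dataclass(frozen=True)
class LearningCurveFit:
    alpha: float
    beta: float
    residual_norm: float
    n_trials_fit: int
    converged: bool = True


# multistart grid on the decay parameter keeps the fit deterministic and
# robust to flat or steep series
_BETA_STARTS = (0.01, 0.05, 0.1, 0.3, 0.7)
_BETA_BOUND = 10.0


def fit_learning_curve(series: Sequence[float],
                       trial_index_base: int = 1) -> LearningCurveFit:
    """Nonlinear least-squares fit of ``y_t = alpha * exp(-beta * t)``.

    ``t`` is the global trial number starting at ``trial_index_base``
    (1..18 for six training days of three trials).  Deterministic: alpha
    starts at the first observation and beta runs over a fixed 5-point
    multistart; the best candidate wins.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 points to fit the learning curve")
    if not np.all(np.isfinite(y)):
        raise ValueError("learning-curve series contains non-finite values")
    t = np.arange(trial_index_base, trial_index_base + len(y), dtype=float)

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    alpha0 = max(float(y[0]), 1e-9)
    best = None
    any_ok = False
    for beta0 in _BETA_STARTS:
        try:
            sol = least_squares(
                resid, x0=[alpha0, beta0],
                bounds=([0.0, -_BETA_BOUND], [np.inf, _BETA_BOUND]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - scipy failure is exotic
            continue
        any_ok = any_ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        return LearningCurveFit(float("nan"), float("nan"), float("inf"),
                                len(y), converged=False)
    return LearningCurveFit(float(best.x[0]), float(best.x[1]),
                            float(np.linalg.norm(best.fun)), len(y),
                            converged=bool(any_ok))


@dataclass(frozen=True)
class ProbeProfile:
    """Probe-test dwell profile keyed by angular offset from the target.

    ``dwell_by_offset`` maps offsets -150..+180 in 30° steps (the 12 hole
    positions) to seconds spent inside each hole's scoring circle within the
    scoring window.
    """

    dwell_by_offset: Dict[int, float]
    probe_latency: Optional[float]
    n_errors_probe: int
    window: float

    @property
    def total_dwell(self) -> float:
        return float(sum(self.dwell_by_offset.values()))


def probe_profile(traj: Trajectory, spec: MazeSpec,
                  window: float = PROBE_WINDOW_S) -> ProbeProfile:
    """Time spent around each hole within the probe scoring window.

    Convention: the first 150 s of the 300-s probe are scored (and 90 s vs
    150 s in the error-matched cross-scale comparison) — ``window`` covers
    both.
    """
    if traj.duration < window:
        logger.warning("probe trial %.0fs shorter than %.0fs window; "
                       "using the full trial", traj.duration, window)
        window = traj.duration
    t0 = traj.times[0]
    sel = traj.times - t0 < window
    sub = traj.slice(0, int(sel.sum()))
    labels = region_labels(sub.points, spec, warn_off_arena=False)
    dwell: Dict[int, float] = {}
    for hole in range(spec.n_holes):
        off = _signed_offset(hole, spec)
        dwell[off] = float(np.sum(labels == hole)) * traj.dt
    n_err = count_errors(traj, spec, until_goal=False, window=window)
    lat = probe_latency(traj, spec)
    return ProbeProfile(dwell, lat, n_err, float(window))


def _signed_offset(hole: int, spec: MazeSpec) -> int:
    raw = (hole - spec.target_index) * spec.hole_gap_deg
    off = (raw + 180.0) % 360.0 - 180.0
    if off == -180.0:
        off = 180.0
    return int(round(off))


def probe_latency(traj: Trajectory, spec: MazeSpec,
                  min_stay: float = PROBE_MIN_STAY_S) -> Optional[float]:
    """Start time (s from trial start) of the first stay in the target hole
    area longer than ``min_stay`` seconds in a row; None if there is none.

    With the escape removed, a sustained stay at the former goal replaces
    goal entry as the probe's "found it" event.
    """
    visits = hole_visit_events(traj, spec)
    t0 = traj.times[0] if len(traj) else 0.0
    for v in visits:
        if v.hole == spec.target_index and v.n_samples * traj.dt > min_stay:
            return float(v.t_entry - t0)
    return None
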