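"""Synthetic Barnes-maze trajectories.

No public animal tracking data accompany the analyses this package
implements, so this module generates 20-Hz trajectories with the
statistical structure those analyses assume: strategy-dependent paths
(direct runs, serial hole-to-hole scans, correlated-random-walk search),
Poisson-thinned pauses long enough to register as stops, optional
home-base roundtrips, probe-style focal search, and day-over-day learning
in which the expected nontarget-visit count follows ``alpha *
exp(-beta * t)`` over the global trial index ``t``.

Everything is driven by a single integer seed; identical parameters and
seed reproduce byte-identical trajectories.

What the generator emulates — and what it does not — is documented in
``docs/methods.md``; in short, it reproduces the *contracts* the analysis
stages depend on (region-visit sequences, stop statistics, learning decay),
not mouse biomechanics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (MazeSpec, hole_positions, rotate_points)
from .trajectory_io import (Trajectory, TrialMeta, write_manifest,
                            write_trial)

__all__ = [
    "AgentParams",
    "generate_trial",
    "generate_cohort",
    "bm1_like_params",
    "bm3_like_params",
]

TRIAL_CAP_S = 600.0
PROBE_DURATION_S = 300.0

#: day-indexed (spatial, serial, random) mixes; the last entry carries
#: forward for longer schedules.  The small-maze profile converges on the
#: spatial strategy within six days; the large-maze profile stays dominated
#: by random search — the qualitative contrast seen between a 1-m and a 3-m
#: arena.
_BM1_MIX = ((0.10, 0.30, 0.60), (0.20, 0.40, 0.40), (0.40, 0.35, 0.25),
            (0.55, 0.30, 0.15), (0.70, 0.20, 0.10), (0.80, 0.15, 0.05))
_BM3_MIX = ((0.00, 0.10, 0.90), (0.05, 0.15, 0.80), (0.08, 0.17, 0.75),
            (0.12, 0.23, 0.65), (0.16, 0.27, 0.57), (0.22, 0.28, 0.50))


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated mouse.

    ``learning_alpha``/``learning_beta`` program the expected nontarget
    visit count of random-strategy trials as ``alpha * exp(-beta * t)``
    (t = global trial index); ``strategy_mix`` gives per-day
    (spatial, serial, random) probabilities.
    """

    strategy_mix: Tuple[Tuple[float, float, float], ...] = _BM1_MIX
    speed_mean: float = 150.0         # mm/s, scale independent
    speed_sd: float = 30.0
    heading_noise: float = 0.12       # rad/step on directed runs
    wander_noise: float = 0.6         # rad/step on random search
    pause_prob: float = 0.5           # chance of a pause at each waypoint
    pause_median_s: float = 2.0       # log-normal pause durations
    pause_sigma: float = 0.5
    pause_jitter_mm: float = 0.5
    learning_alpha: float = 10.0
    learning_beta: float = 0.25
    serial_offset: Tuple[int, int] = (3, 5)   # start 3..5 holes from target
    home_base_roundtrips: int = 0     # roundtrips to a preferred site
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in self.strategy_mix:
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError("each day's strategy mix must be a "
                                 "probability vector")
        if self.speed_mean <= 0 or self.pause_median_s <= 0:
            raise ValueError("rates and durations must be positive")

    def mix_for_day(self, day: int) -> Tuple[float, float, float]:
        idx = min(max(day, 1), len(self.strategy_mix)) - 1
        return self.strategy_mix[idx]


def bm1_like_params(seed: int = 0, **overrides) -> AgentParams:
    """Fast-learning small-arena profile (spatial by the end of training)."""
    kw = dict(strategy_mix=_BM1_MIX, learning_alpha=10.0, learning_beta=0.25,
              seed=seed)
    kw.update(overrides)
    return AgentParams(**kw)


def bm3_like_params(seed: int = 0, **overrides) -> AgentParams:
    """Slow-learning large-arena profile: heavier random mix, higher error
    intercept, smaller decay."""
    kw = dict(strategy_mix=_BM3_MIX, learning_alpha=18.0, learning_beta=0.06,
              seed=seed)
    kw.update(overrides)
    return AgentParams(**kw)


# ---------------------------------------------------------------------------
# movement primitives (all emit points sampled at spec.dt)

def _clip_to_arena(p: np.ndarray, spec: MazeSpec) -> np.ndarray:
    r = math.hypot(p[0], p[1])
    rmax = spec.arena_radius - 1.0
    if r > rmax:
        p = p * (rmax / r)
    return p


def _walk_to(rng, pos, dest, params: AgentParams, spec: MazeSpec,
             heading_sd: Optional[float] = None,
             max_steps: int = 40000) -> List[np.ndarray]:
    """Directed walk with per-step heading noise; ends snapped on dest."""
    if heading_sd is None:
        heading_sd = params.heading_noise
    dt = spec.dt
    pts: List[np.ndarray] = []
    pos = np.asarray(pos, dtype=float).copy()
    dest = np.asarray(dest, dtype=float)
    for _ in range(max_steps):
        delta = dest - pos
        d = math.hypot(delta[0], delta[1])
        speed = max(30.0, rng.normal(params.speed_mean, params.speed_sd))
        step = speed * dt
        if d <= step:
            pts.append(dest.copy())
            return pts
        ang = math.atan2(delta[1], delta[0]) + rng.normal(0.0, heading_sd)
        pos = _clip_to_arena(
            pos + step * np.array([math.cos(ang), math.sin(ang)]), spec)
        pts.append(pos.copy())
        pos = pts[-1]
    return pts  # pragma: no cover - max_steps is generous


def _arc_to(rng, angle_from: float, angle_to: float, direction: int,
            params: AgentParams, spec: MazeSpec) -> List[np.ndarray]:
    """Move along the hole ring from one angle to another (radians)."""
    r = spec.hole_ring_radius
    sweep = (direction * (angle_to - angle_from)) % (2.0 * math.pi)
    omega = params.speed_mean / r * spec.dt
    n = max(1, int(math.ceil(sweep / omega)))
    angs = angle_from + direction * sweep * np.arange(1, n + 1) / n
    radii = r + rng.normal(0.0, 3.0, n)
    return list(np.column_stack([radii * np.cos(angs),
                                 radii * np.sin(angs)]))


def _pause(rng, pos, duration: float, params: AgentParams,
           spec: MazeSpec) -> List[np.ndarray]:
    n = max(1, int(round(duration / spec.dt)))
    jitter = rng.normal(0.0, params.pause_jitter_mm, (n, 2))
    return list(np.asarray(pos, dtype=float) + jitter)


def _maybe_pause(rng, pos, params: AgentParams, spec: MazeSpec,
                 force: bool = False) -> List[np.ndarray]:
    if not force and rng.random() >= params.pause_prob:
        return []
    dur = float(np.exp(rng.normal(math.log(params.pause_median_s),
                                  params.pause_sigma)))
    return _pause(rng, pos, dur, params, spec)


def _wander_waypoint(rng, spec: MazeSpec) -> np.ndarray:
    """Interior waypoint clear of both the start area and the hole ring."""
    lo = spec.start_area_radius + 40.0
    hi = spec.hole_ring_radius - spec.hole_area_radius - 60.0
    r = rng.uniform(lo, max(hi, lo + 1.0))
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([r * math.cos(ang), r * math.sin(ang)])


def _hole_gate(hole_xy: np.ndarray, spec: MazeSpec) -> np.ndarray:
    """Approach point just outside a hole's scoring circle, on the radial."""
    r = np.linalg.norm(hole_xy)
    return hole_xy * ((r - spec.hole_area_radius - 50.0) / r)


# ---------------------------------------------------------------------------
# strategy routes (target at hole 0; rotation to the true goal happens last)

def _route_spatial(rng, pts, params, spec, holes) -> None:
    pts += _walk_to(rng, pts[-1], holes[0], params, spec)


def _route_serial(rng, pts, params, spec, holes) -> None:
    lo, hi = params.serial_offset
    k = int(rng.integers(lo, hi + 1))
    direction = 1 if rng.random() < 0.5 else -1
    start_hole = (direction * k) % spec.n_holes
    pts += _walk_to(rng, pts[-1], holes[start_hole], params, spec)
    angles = np.arctan2(holes[:, 1], holes[:, 0])
    hole = start_hole
    while hole != 0:
        nxt = (hole - direction) % spec.n_holes
        if rng.random() < 0.3:
            pts += _maybe_pause(rng, pts[-1], params, spec, force=True)
        pts += _arc_to(rng, angles[hole], angles[nxt], -direction,
                       params, spec)
        pts += _walk_to(rng, pts[-1], holes[nxt], params, spec,
                        heading_sd=0.05)
        hole = nxt


def _route_random(rng, pts, params, spec, holes, n_errors: int) -> None:
    prev_hole: Optional[int] = None
    for _ in range(n_errors):
        for _ in range(int(rng.integers(1, 4))):
            pts += _walk_to(rng, pts[-1], _wander_waypoint(rng, spec),
                            params, spec, heading_sd=params.wander_noise)
            pts += _maybe_pause(rng, pts[-1], params, spec)
        while True:
            hole = int(rng.integers(1, spec.n_holes))
            if prev_hole is None or (
                    hole != prev_hole
                    and (hole - prev_hole) % spec.n_holes != 1
                    and (prev_hole - hole) % spec.n_holes != 1):
                break
        gate = _hole_gate(holes[hole], spec)
        pts += _walk_to(rng, pts[-1], gate, params, spec, heading_sd=0.08)
        pts += _walk_to(rng, pts[-1], holes[hole], params, spec,
                        heading_sd=0.05)
        pts += _walk_to(rng, pts[-1], gate, params, spec, heading_sd=0.05)
        prev_hole = hole
    for _ in range(int(rng.integers(2, 5))):
        pts += _walk_to(rng, pts[-1], _wander_waypoint(rng, spec),
                        params, spec, heading_sd=params.wander_noise)
        pts += _maybe_pause(rng, pts[-1], params, spec)
    gate = _hole_gate(holes[0], spec)
    pts += _walk_to(rng, pts[-1], gate, params, spec, heading_sd=0.08)
    pts += _walk_to(rng, pts[-1], holes[0], params, spec, heading_sd=0.05)


def _route_probe(rng, pts, params, spec, holes, duration: float) -> None:
    """Focal search around the (absent) goal: long dwells in the target
    area with brief excursions, mostly to neighboring holes."""
    dt = spec.dt
    n_target = duration / dt
    while len(pts) < n_target:
        near = holes[0] + rng.normal(0.0, spec.hole_area_radius / 4.0, 2)
        pts += _walk_to(rng, pts[-1], near, params, spec, heading_sd=0.1)
        dur = float(np.exp(rng.normal(math.log(3.0), params.pause_sigma)))
        pts += _pause(rng, pts[-1], dur, params, spec)
        if rng.random() < 0.35:
            off = int(rng.choice([-1, 1, -2, 2]))
            pts += _walk_to(rng, pts[-1], holes[off % spec.n_holes],
                            params, spec, heading_sd=0.1)
            pts += _maybe_pause(rng, pts[-1], params, spec)


def _route_home_base(rng, pts, params, spec) -> np.ndarray:
    """Roundtrips arriving and departing on one preferred site."""
    ang = rng.uniform(0.0, 2.0 * math.pi)
    base = 0.7 * spec.arena_radius * np.array([math.cos(ang), math.sin(ang)])
    pts += _walk_to(rng, pts[-1], base, params, spec,
                    heading_sd=params.wander_noise)
    for _ in range(params.home_base_roundtrips):
        pts += _maybe_pause(rng, pts[-1], params, spec, force=True)
        away = _wander_waypoint(rng, spec)
        pts += _walk_to(rng, pts[-1], away, params, spec,
                        heading_sd=params.wander_noise)
        pts += _maybe_pause(rng, pts[-1], params, spec)
        pts += _walk_to(rng, pts[-1], base, params, spec, heading_sd=0.1)
    pts += _maybe_pause(rng, pts[-1], params, spec, force=True)
    return base


def generate_trial(params: AgentParams, spec: MazeSpec, day: int = 1,
                   trial: int = 1, phase: str = "training",
                   strategy: Optional[str] = None,
                   mouse_id: str = "sim", cohort: str = "sim",
                   target_index: int = 0) -> Trajectory:
    """Generate one 20-Hz trial starting at the arena center.

    ``strategy`` forces a pure-strategy trial; otherwise it is drawn from
    the day's mix.  ``target_index`` rotates the whole scene so the goal
    sits at that hole (the raw-data condition that
    :func:`~mazenet.geometry.normalize_to_target` undoes downstream).
    The RNG stream is fully determined by ``(params.seed, day, trial)``.
    """
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, day, trial,
                                 {"training": 0, "probe": 1,
                                  "habituation": 2}[phase]])
    holes = hole_positions(spec)
    t_global = (day - 1) * 3 + trial
    pts: List[np.ndarray] = [np.zeros(2)]
    pts += _pause(rng, np.zeros(2), 0.5, params, spec)

    if phase == "probe":
        _route_probe(rng, pts, params, spec, holes, PROBE_DURATION_S)
        cap = PROBE_DURATION_S
    elif phase == "habituation" or params.home_base_roundtrips > 0:
        _route_home_base(rng, pts, params, spec)
        cap = TRIAL_CAP_S
    else:
        if strategy is None:
            mix = params.mix_for_day(day)
            strategy = ["spatial", "serial", "random"][
                int(rng.choice(3, p=mix))]
        if strategy == "spatial":
            _route_spatial(rng, pts, params, spec, holes)
        elif strategy == "serial":
            _route_serial(rng, pts, params, spec, holes)
        elif strategy == "random":
            mean_err = params.learning_alpha * math.exp(
                -params.learning_beta * t_global)
            n_err = int(rng.poisson(mean_err))
            _route_random(rng, pts, params, spec, holes, n_err)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        pts += _pause(rng, pts[-1], 1.0, params, spec)
        cap = TRIAL_CAP_S

    points = np.asarray(pts, dtype=float)
    n_cap = int(cap / spec.dt)
    points = points[:n_cap]
    times = spec.dt * np.arange(len(points))
    if target_index:
        points = rotate_points(points,
                               math.radians(target_index * spec.hole_gap_deg))
    meta = TrialMeta(mouse_id=mouse_id, cohort=cohort, phase=phase,
                     day=max(day, 1) if phase == "training" else day,
                     trial_in_day=trial, maze=spec.name,
                     target_index=target_index)
    return Trajectory(times=times, points=points, meta=meta,
                      sampling_rate=spec.sampling_rate)


def generate_cohort(n_mice: int, params_template: AgentParams,
                    spec: MazeSpec, n_days: int, trials_per_day: int = 3,
                    seed: int = 0, out_dir=None, cohort: str = "sim",
                    probe: bool = False):
    """Generate a cohort of mice with randomized goal holes.

    Per-mouse seeds derive from the master ``seed``; each mouse's goal hole
    is drawn uniformly (the normalization step downstream maps them all
    back to a common frame).  With ``out_dir`` set, trajectory CSVs and a
    manifest are written and the manifest DataFrame (with file paths) is
    returned along with the trajectories; otherwise paths are empty.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    master = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0_60_87])
    trajectories: List[Trajectory] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for m in range(n_mice):
        mouse_seed = int(master.integers(2 ** 31))
        target = int(master.integers(spec.n_holes))
        params = dataclasses.replace(params_template, seed=mouse_seed)
        mouse_id = f"{cohort}_m{m:02d}"
        schedule = [("training", d, tr) for d in range(1, n_days + 1)
                    for tr in range(1, trials_per_day + 1)]
        if probe:
            schedule.append(("probe", n_days + 1, 1))
        for phase, day, tr in schedule:
            traj = generate_trial(params, spec, day=day, trial=tr,
                                  phase=phase, mouse_id=mouse_id,
                                  cohort=cohort, target_index=target)
            path = ""
            if out_dir is not None:
                path = str(out_dir / f"{mouse_id}_{phase}_d{day:02d}_t{tr}.csv")
                write_trial(traj, path)
            trajectories.append(traj)
            rows.append(dict(path=path, mouse_id=mouse_id, cohort=cohort,
                             phase=phase, day=day, trial_in_day=tr,
                             maze=spec.name, target_index=target))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
    return manifest, trajectories
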