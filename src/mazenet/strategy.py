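"""Algorithmic navigation-strategy classification.

Each training trial is labeled spatial, serial, or random:

* **spatial** — the mouse moved directly toward the target hole with fewer
  than three nontarget-hole visits;
* **serial** — the mouse scanned neighboring holes in sequence until it
  reached the target, with fewer than three quadrant crossings;
* **random** — everything else.

The verbal rules are operationalized with two explicit, configurable
thresholds: a path-efficiency cutoff for "directly toward" and an
adjacent-visit consistency cutoff for "sequentially approached neighboring
holes".  The initial wobble on the start lift is discarded first so that
micromovements around the center cannot inflate the random class.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .conventional import HoleVisit, first_target_entry, hole_visit_events
from .geometry import MazeSpec, hole_positions, quadrant_sequence
from .trajectory_io import Trajectory

logger = logging.getLogger("mazenet")

__all__ = [
    "StrategyThresholds",
    "StrategyCall",
    "strip_start_area",
    "path_efficiency",
    "quadrant_crossings",
    "serial_consistency",
    "classify_strategy",
]


@dataclass(frozen=True)
class StrategyThresholds:
    """Tunable cutoffs of the classifier; echoed into every call."""

    direct_efficiency: float = 0.75   # "moved directly toward the target"
    serial_consistency: float = 0.8   # adjacent-visit fraction for serial
    max_nontarget_visits: int = 3     # spatial rule: visits < 3
    max_quadrant_crossings: int = 3   # serial rule: crossings < 3


@dataclass(frozen=True)
class StrategyCall:
    label: str                       # spatial | serial | random
    n_nontarget_visits: int
    path_efficiency: float
    n_quadrant_crossings: int
    serial_consistency: float
    target_reached: bool
    excluded_prefix: float           # seconds discarded in the start area
    flagged: bool = False            # degenerate input (never left start...)
    thresholds: StrategyThresholds = StrategyThresholds()


def strip_start_area(traj: Trajectory, spec: MazeSpec) -> Trajectory:
    """Drop the initial segment while the mouse stayed in the start area.

    Only the stay *since it entered the field* is discarded; later passes
    through the center are retained.  A trajectory already outside the start
    area is returned unchanged; one that never leaves it becomes empty.
    """
    r = np.hypot(traj.points[:, 0], traj.points[:, 1])
    outside = np.where(r >= spec.start_area_radius)[0]
    if len(outside) == 0:
        return traj.slice(len(traj))
    return traj.slice(int(outside[0]))


def path_efficiency(traj: Trajectory, spec: MazeSpec) -> tuple:
    """Straightness of the approach to the target, in (0, 1].

    Ratio of the straight-line distance (first post-strip point to target
    hole center) to the traveled distance to the target: path length up to
    the first entry into the target area plus the remaining straight leg
    from the entry point to the hole center, so that a perfectly straight
    approach scores 1.0.  If the target is never entered the traveled
    length runs to trial end and the call is flagged.

    Returns ``(efficiency, target_reached)``.
    """
    if len(traj) < 2:
        return 0.0, False
    target = hole_positions(spec)[spec.target_index]
    straight = float(np.linalg.norm(traj.points[0] - target))
    visits = hole_visit_events(traj, spec)
    entry_t = first_target_entry(visits, spec.target_index)
    steps = traj.step_lengths()
    if entry_t is None:
        travelled = float(steps.sum()) + float(
            np.linalg.norm(traj.points[-1] - target))
        reached = False
    else:
        i = int(np.searchsorted(traj.times, entry_t))
        travelled = float(steps[:i].sum()) + float(
            np.linalg.norm(traj.points[i] - target))
        reached = True
    if travelled <= 0:
        return 1.0, reached
    return min(1.0, straight / travelled), reached


def quadrant_crossings(traj: Trajectory, spec: MazeSpec) -> int:
    """Transitions between distinct 90° sectors across consecutive samples,
    ignoring samples inside the start radius."""
    if len(traj) < 2:
        return 0
    r = np.hypot(traj.points[:, 0], traj.points[:, 1])
    keep = r >= spec.start_area_radius
    if keep.sum() < 2:
        return 0
    q = quadrant_sequence(traj.points[keep], spec)
    return int(np.sum(np.diff(q) != 0))


def serial_consistency(visit_holes: Sequence[int], n_holes: int = 12) -> float:
    """Fraction of consecutive visit pairs that step to the adjacent hole in
    one dominant direction.

    A serial scan proceeds hole-to-hole in a single direction, so any
    adjacent step *against* the dominant direction (ping-ponging between two
    holes) voids seriality and scores 0.  Fewer than two visits also scores
    0 — there is no sequence to be consistent.
    """
    if len(visit_holes) < 2:
        return 0.0
    diffs = [(b - a) % n_holes for a, b in zip(visit_holes, visit_holes[1:])]
    ccw = sum(1 for d in diffs if d == 1)
    cw = sum(1 for d in diffs if d == n_holes - 1)
    if ccw and cw:
        return 0.0
    return max(ccw, cw) / len(diffs)


def classify_strategy(traj: Trajectory, spec: MazeSpec,
                      thresholds: StrategyThresholds = StrategyThresholds()
                      ) -> StrategyCall:
    """Label one training trial spatial, serial, or random.

    Rule order: spatial is tested first (it is the stricter, optimal
    strategy — a direct path trivially satisfies the serial crossing rule),
    then serial, then random as the remainder.  All evidence quantities are
    reported with the call.
    """
    stripped = strip_start_area(traj, spec)
    excluded = traj.duration - stripped.duration
    if len(stripped) < 2:
        logger.warning("mouse never left the start area; classified random")
        return StrategyCall("random", 0, 0.0, 0, 0.0, False, excluded,
                            flagged=True, thresholds=thresholds)

    visits = hole_visit_events(stripped, spec)
    entry_t = first_target_entry(visits, spec.target_index)
    if entry_t is not None:
        visits = [v for v in visits if v.t_entry <= entry_t]
        i = int(np.searchsorted(stripped.times, entry_t, side="right"))
        scored = stripped.slice(0, max(i, 2))
    else:
        scored = stripped
    n_nontarget = sum(1 for v in visits if v.hole != spec.target_index)
    eff, reached = path_efficiency(stripped, spec)
    crossings = quadrant_crossings(scored, spec)
    consistency = serial_consistency([v.hole for v in visits], spec.n_holes)

    if (n_nontarget < thresholds.max_nontarget_visits
            and eff >= thresholds.direct_efficiency):
        label = "spatial"
    elif (reached and consistency >= thresholds.serial_consistency
            and crossings < thresholds.max_quadrant_crossings):
        label = "serial"
    else:
        label = "random"
    return StrategyCall(label, n_nontarget, eff, crossings, consistency,
                        reached, excluded, thresholds=thresholds)
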