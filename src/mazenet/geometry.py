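"""Circular-arena geometry for the Barnes maze.

The Barnes maze is a brightly lit circular arena with ``n_holes`` escape
holes equally spaced on a ring near the rim; one hole (the target) leads to
an escape box.  Every downstream feature — error counts, probe dwell times,
strategy calls — reduces to point-in-region queries against this geometry,
so the region logic lives here in one place.

Two maze scales are built in: the conventional 1-m arena (``BM1``) and a
3-m arena (``BM3``) whose scoring regions are (approximately) a tripled
version of the BM1 layout.  All lengths are millimeters internally.

Coordinate conventions
----------------------
* Arena center at the origin.
* Hole ``i`` sits at angle ``90° + i * 360°/n_holes``, counterclockwise —
  i.e. hole 0 is at "north".  After :func:`normalize_to_target` the target
  hole is hole 0, so trajectories from mice with different goal holes are
  directly comparable.
* Quadrants are 90° sectors anchored to the target direction, with the
  target ray bisecting sector 0.  Anchoring to the target (rather than the
  camera frame) makes the serial-strategy rule rotation invariant.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

logger = logging.getLogger("mazenet")

__all__ = [
    "MazeSpec",
    "MazeConfigError",
    "Region",
    "builtin_spec",
    "spec_from_config",
    "hole_positions",
    "hole_angles",
    "region_of",
    "region_labels",
    "quadrant_of",
    "quadrant_sequence",
    "normalize_to_target",
]

#: label codes used by the vectorized region classifier
START_AREA = -2
OPEN_FIELD = -1


class MazeConfigError(ValueError):
    """Raised for unknown maze names or invalid geometry configurations."""


@dataclass(frozen=True)
class MazeSpec:
    """Geometry of one maze scale.

    Parameters
    ----------
    name:
        Label such as ``"BM1"`` or ``"BM3"``.
    arena_radius:
        Radius of the circular arena, mm.
    hole_ring_radius:
        Distance of hole centers from the arena center, mm.
    hole_area_radius:
        Radius of the scoring circle around each hole, mm.  Entering a
        nontarget scoring circle is an "error".
    start_area_radius:
        Radius of the central start area (the lift); trajectory inside it is
        discarded for strategy analysis.
    n_holes:
        Number of equally spaced peripheral holes.
    target_index:
        Index of the goal hole, in ``[0, n_holes)``; 0 after normalization.
    sampling_rate:
        Video tracking rate, Hz.
    rim_overhang_tolerance:
        How far (mm) the hole scoring circles may poke beyond the arena rim
        (the holes sit near the perimeter; on the 3-m maze they are slots in
        the rim itself).
    """

    name: str
    arena_radius: float
    hole_ring_radius: float
    hole_area_radius: float
    start_area_radius: float
    n_holes: int = 12
    target_index: int = 0
    sampling_rate: float = 20.0
    rim_overhang_tolerance: float = 150.0

    def __post_init__(self) -> None:
        if self.n_holes < 2:
            raise MazeConfigError("n_holes must be >= 2")
        if not (0 < self.start_area_radius
                < self.hole_ring_radius - self.hole_area_radius):
            raise MazeConfigError(
                "start area must be disjoint from hole areas: need "
                "0 < start_area_radius < hole_ring_radius - hole_area_radius")
        overhang = (self.hole_ring_radius + self.hole_area_radius
                    - self.arena_radius)
        if overhang > self.rim_overhang_tolerance:
            raise MazeConfigError(
                f"hole areas extend {overhang:.0f} mm beyond the rim, more "
                f"than the {self.rim_overhang_tolerance:.0f} mm tolerance")
        if not (0 <= self.target_index < self.n_holes):
            raise MazeConfigError("target_index out of range")

    @property
    def hole_gap_deg(self) -> float:
        return 360.0 / self.n_holes

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def scaled(self, k: float) -> "MazeSpec":
        """Return a geometrically similar spec with all lengths times ``k``."""
        return dataclasses.replace(
            self,
            name=f"{self.name}x{k:g}",
            arena_radius=self.arena_radius * k,
            hole_ring_radius=self.hole_ring_radius * k,
            hole_area_radius=self.hole_area_radius * k,
            start_area_radius=self.start_area_radius * k,
            rim_overhang_tolerance=self.rim_overhang_tolerance * k,
        )


#: canonical angle (deg) of hole 0 / the normalized target: "north"
CANONICAL_TARGET_ANGLE = 90.0

_BUILTINS = {
    # 98-cm arena, 12 holes 40 cm from the centroid, ~80-mm scoring circles,
    # 8-cm start-discard radius, 20-Hz tracking.
    "BM1": dict(arena_radius=490.0, hole_ring_radius=400.0,
                hole_area_radius=80.0, start_area_radius=80.0),
    # 300-cm arena; scoring and start radii are the BM1 values tripled
    # (270 mm = 3 x 80 mm plus the extra hole-size margin, 27-cm start).
    # The hole ring radius is not published for this scale; the holes are
    # slots in the rim, so the default keeps the scoring circles just inside
    # the arena.  Override via `hole_ring_radius` or a config file if needed.
    "BM3": dict(arena_radius=1500.0, hole_ring_radius=1350.0,
                hole_area_radius=270.0, start_area_radius=270.0),
}


def builtin_spec(name: str, target_index: int = 0,
                 hole_ring_radius: Optional[float] = None) -> MazeSpec:
    """Return the built-in parameterization of one maze scale.

    ``name`` must be ``"BM1"`` or ``"BM3"``.
    """
    try:
        params = dict(_BUILTINS[name])
    except KeyError:
        raise MazeConfigError(
            f"unknown maze {name!r}; built-ins are {sorted(_BUILTINS)}"
        ) from None
    if hole_ring_radius is not None:
        params["hole_ring_radius"] = float(hole_ring_radius)
    return MazeSpec(name=name, target_index=target_index, **params)


_UNIT_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def spec_from_config(path) -> MazeSpec:
    """Load a custom :class:`MazeSpec` from a YAML config file.

    Expected layout (lengths interpreted via the top-level ``unit`` key,
    default mm)::

        name: BM2
        unit: cm
        arena: {radius: 200}
        holes: {count: 12, ring_radius: 160, target_index: 0}
        scoring: {hole_area_radius: 16, start_area_radius: 16}
        sampling: {rate: 20}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        unit = _UNIT_MM[cfg.get("unit", "mm")]
        holes = cfg.get("holes", {})
        scoring = cfg["scoring"]
        return MazeSpec(
            name=str(cfg.get("name", Path(path).stem)),
            arena_radius=float(cfg["arena"]["radius"]) * unit,
            hole_ring_radius=float(holes["ring_radius"]) * unit,
            hole_area_radius=float(scoring["hole_area_radius"]) * unit,
            start_area_radius=float(scoring["start_area_radius"]) * unit,
            n_holes=int(holes.get("count", 12)),
            target_index=int(holes.get("target_index", 0)),
            sampling_rate=float(cfg.get("sampling", {}).get("rate", 20.0)),
        )
    except KeyError as exc:
        raise MazeConfigError(f"maze config {path} missing key {exc}") from exc


def hole_angles(spec: MazeSpec) -> np.ndarray:
    """Angles (radians) of the hole centers, counterclockwise from hole 0."""
    step = 2.0 * math.pi / spec.n_holes
    return math.radians(CANONICAL_TARGET_ANGLE) + step * np.arange(spec.n_holes)

def hole_positions(spec: MazeSpec) -> np.ndarray:
    """(n_holes, 2) array of hole-center coordinates, mm."""
    ang = hole_angles(spec)
    return spec.hole_ring_radius * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class Region:
    """Result of a point-in-region query: kind + hole index if applicable."""

    kind: str  # "start_area" | "hole" | "open_field"
    hole: Optional[int] = None


def region_labels(points: np.ndarray, spec: MazeSpec,
                  warn_off_arena: bool = True) -> np.ndarray:
    """Vectorized region classification.

    Returns an int array: hole index ``i >= 0``, ``START_AREA`` (-2) or
    ``OPEN_FIELD`` (-1).  The start area takes precedence over hole areas
    (they cannot overlap under the spec invariants, but malformed configs
    are still handled deterministically).  Points far outside the arena are
    classified open_field with a data-quality warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    r = np.hypot(pts[:, 0], pts[:, 1])
    labels = np.full(len(pts), OPEN_FIELD, dtype=int)

    tol = spec.rim_overhang_tolerance
    n_off = int(np.sum(r > spec.arena_radius + tol))
    if n_off and warn_off_arena:
        logger.warning("%d/%d points lie beyond the arena (+tolerance); "
                       "classified open_field", n_off, len(pts))

    d = np.linalg.norm(pts[:, None, :] - hole_positions(spec)[None, :, :],
                       axis=2)
    nearest = np.argmin(d, axis=1)  # ties break to the lowest index
    in_hole = d[np.arange(len(pts)), nearest] < spec.hole_area_radius
    labels[in_hole] = nearest[in_hole]
    labels[r < spec.start_area_radius] = START_AREA
    return labels


def region_of(point, spec: MazeSpec) -> Region:
    """Classify a single point; see :func:`region_labels`."""
    lab = int(region_labels(np.asarray(point, dtype=float), spec)[0])
    if lab == START_AREA:
        return Region("start_area")
    if lab == OPEN_FIELD:
        return Region("open_field")
    return Region("hole", lab)


def _target_angle_deg(spec: MazeSpec) -> float:
    return CANONICAL_TARGET_ANGLE + spec.target_index * spec.hole_gap_deg


def quadrant_of(point, spec: MazeSpec) -> int:
    """Index in {0,1,2,3} of the 90° sector containing ``point``.

    Sectors are counterclockwise, anchored so the target ray bisects
    sector 0.  Undefined at the origin (raises ValueError); callers walking
    a trajectory should use :func:`quadrant_sequence`, which carries the
    previous quadrant forward.
    """
    x, y = float(point[0]), float(point[1])
    if x == 0.0 and y == 0.0:
        raise ValueError("quadrant undefined at the arena center")
    ang = math.degrees(math.atan2(y, x))
    off = (ang - _target_angle_deg(spec) + 45.0) % 360.0
    return int(off // 90.0) % 4  # float modulo can yield exactly 360.0


def quadrant_sequence(points: np.ndarray, spec: MazeSpec) -> np.ndarray:
    """Per-sample quadrant indices, carrying the previous value across any
    sample exactly at the origin (where the angle is undefined)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ang = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    q = ((ang - _target_angle_deg(spec) + 45.0) % 360.0
         // 90.0).astype(int) % 4  # float modulo can yield exactly 360.0
    at_origin = (pts[:, 0] == 0.0) & (pts[:, 1] == 0.0)
    if at_origin.any():
        idx = np.where(at_origin, 0, np.arange(len(q)))
        np.maximum.accumulate(idx, out=idx)
        q = q[idx]  # first samples at origin inherit the first defined value
        if at_origin[0]:
            first = np.argmin(at_origin)
            q[: first] = q[first] if not at_origin.all() else 0
    return q


def rotate_points(points: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    pts = np.asarray(points, dtype=float)
    # row-vector convention: [x y] @ [[c, s], [-s, c]] rotates by +angle
    return pts @ np.array([[c, s], [-s, c]])


def normalize_to_target(traj, spec: MazeSpec):
    """Rotate a trajectory about the arena center so its target hole sits at
    the canonical angle (90°, "north").

    The target index is taken from ``traj.meta.target_index`` when set,
    else from ``spec.target_index``.  Returns a new trajectory whose meta
    has ``target_index == 0``; use a spec with ``target_index == 0`` for all
    downstream scoring.  A rigid rotation, so path lengths and all pairwise
    distances are preserved.
    """
    tgt = traj.meta.target_index
    if tgt is None:
        tgt = spec.target_index
    rotation = -math.radians(tgt * spec.hole_gap_deg)
    pts = rotate_points(traj.points, rotation)
    meta = dataclasses.replace(traj.meta, target_index=0)
    return dataclasses.replace(traj, points=pts, meta=meta)
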