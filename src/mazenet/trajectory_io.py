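"""Reading, validating and writing trial trajectories and feature tables.

Trajectories are plain CSV, one file per trial: ``#``-prefixed metadata
header lines followed by ``frame,t,x,y`` rows (t in seconds, x/y in mm,
pre-calibrated arena coordinates with the center at the origin).  A manifest
CSV (one row per trial: path + metadata) drives batch runs.

Validation enforces the assumptions the analyses rely on: strictly
increasing time, uniform sampling at the maze's rate, at most 5% missing
samples after interpolating gaps of at most 0.5 s, and at most 10% of
samples off the arena.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import MazeSpec

logger = logging.getLogger("mazenet")

__all__ = [
    "TrialMeta",
    "Trajectory",
    "TrajectoryQualityError",
    "read_trial",
    "write_trial",
    "read_manifest",
    "write_manifest",
    "write_features",
    "read_features",
]

MAX_GAP_S = 0.5          # internal dropouts longer than this are fatal
MAX_MISSING_FRAC = 0.05  # after interpolation
MAX_OFF_ARENA_FRAC = 0.10
DT_TOLERANCE = 0.01      # median dt must be within 1% of 1/rate


class TrajectoryQualityError(ValueError):
    """A trajectory file violates a validation rule; the message names it."""


@dataclass(frozen=True)
class TrialMeta:
    mouse_id: str = "m0"
    cohort: str = ""
    phase: str = "training"          # habituation | training | probe
    day: int = 1
    trial_in_day: int = 1
    maze: str = "BM1"
    target_index: Optional[int] = None
    goal_reached: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.phase not in ("habituation", "training", "probe"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.day < 0 or (self.phase == "training" and self.day < 1):
            raise ValueError("training days are positive")
        if not (1 <= self.trial_in_day <= 3):
            raise ValueError("trial_in_day must be in [1, 3] "
                             "(three trials per training day)")


@dataclass(frozen=True)
class Trajectory:
    """One trial's uniformly sampled 2-D path."""

    times: np.ndarray      # seconds, strictly increasing
    points: np.ndarray     # (n, 2) mm
    meta: TrialMeta = field(default_factory=TrialMeta)
    sampling_rate: float = 20.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "points", p)
        if len(t) != len(p):
            raise ValueError("times and points length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def path_length(self) -> float:
        return float(self.step_lengths().sum())

    def slice(self, start: int, stop: Optional[int] = None) -> "Trajectory":
        return dataclasses.replace(self, times=self.times[start:stop],
                                   points=self.points[start:stop])


# ---------------------------------------------------------------------------
# trajectory CSV

_META_FIELDS = ("mouse_id", "cohort", "phase", "day", "trial_in_day",
                "maze", "target_index")


def write_trial(traj: Trajectory, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# mazenet-trajectory v1\n")
        for name in _META_FIELDS:
            val = getattr(traj.meta, name)
            if val is not None:
                fh.write(f"# {name}: {val}\n")
        fh.write(f"# sampling_rate: {traj.sampling_rate:g}\n")
        frames = np.arange(len(traj))
        df = pd.DataFrame({"frame": frames,
                           "t": traj.times,
                           "x": traj.points[:, 0],
                           "y": traj.points[:, 1]})
        df.to_csv(fh, index=False, float_format="%.3f")


def _parse_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_trial(path, spec: MazeSpec,
               meta: Optional[TrialMeta] = None) -> Trajectory:
    """Read and validate one trial CSV.

    Internal gaps (NaN coordinates or skipped frames) of at most 0.5 s are
    filled by linear interpolation; leading/trailing missing samples are
    trimmed.  Violations raise :class:`TrajectoryQualityError` naming the
    rule.
    """
    header = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise TrajectoryQualityError(f"{path}: missing column {col!r}")

    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise TrajectoryQualityError(f"{path}: non-monotone time")

    rate = float(header.get("sampling_rate", spec.sampling_rate))
    dt_nominal = 1.0 / rate
    med_dt = float(np.median(np.diff(t))) if len(t) > 1 else dt_nominal
    if abs(med_dt - dt_nominal) > DT_TOLERANCE * dt_nominal:
        raise TrajectoryQualityError(
            f"{path}: median sample interval {med_dt:.4f}s deviates >1% "
            f"from 1/{rate:g}Hz")

    # rebuild the uniform grid so skipped frames appear as missing samples
    n_grid = int(round((t[-1] - t[0]) / dt_nominal)) + 1
    grid = t[0] + dt_nominal * np.arange(n_grid)
    idx = np.round((t - t[0]) / dt_nominal).astype(int)
    x = np.full(n_grid, np.nan)
    y = np.full(n_grid, np.nan)
    x[idx] = df["x"].to_numpy(dtype=float)
    y[idx] = df["y"].to_numpy(dtype=float)

    missing = np.isnan(x) | np.isnan(y)
    # trim leading/trailing missing samples
    valid = np.where(~missing)[0]
    if len(valid) < 2:
        raise TrajectoryQualityError(f"{path}: fewer than 2 valid samples")
    lo, hi = valid[0], valid[-1] + 1
    grid, x, y, missing = grid[lo:hi], x[lo:hi], y[lo:hi], missing[lo:hi]

    if missing.mean() > MAX_MISSING_FRAC:
        raise TrajectoryQualityError(
            f"{path}: {missing.mean():.1%} samples missing (> "
            f"{MAX_MISSING_FRAC:.0%} rule)")
    # internal gaps: each maximal missing run must be <= MAX_GAP_S
    if missing.any():
        edges = np.diff(missing.astype(int))
        starts = np.where(edges == 1)[0] + 1
        ends = np.where(edges == -1)[0] + 1
        for s, e in zip(starts, ends):
            if (e - s) * dt_nominal > MAX_GAP_S:
                raise TrajectoryQualityError(
                    f"{path}: tracking gap of {(e - s) * dt_nominal:.2f}s "
                    f"exceeds the {MAX_GAP_S}s interpolation limit")
        ok = ~missing
        x[missing] = np.interp(grid[missing], grid[ok], x[ok])
        y[missing] = np.interp(grid[missing], grid[ok], y[ok])

    r = np.hypot(x, y)
    off = r > spec.arena_radius + spec.rim_overhang_tolerance
    if off.mean() > MAX_OFF_ARENA_FRAC:
        raise TrajectoryQualityError(
            f"{path}: {off.mean():.1%} of samples off the arena (> "
            f"{MAX_OFF_ARENA_FRAC:.0%} rule)")

    if meta is None:
        kwargs = {}
        for name in _META_FIELDS:
            if name in header:
                val = header[name]
                if name in ("day", "trial_in_day", "target_index"):
                    val = int(val)
                kwargs[name] = val
        meta = TrialMeta(**kwargs)

    return Trajectory(times=grid, points=np.column_stack([x, y]),
                      meta=meta, sampling_rate=rate)


# ---------------------------------------------------------------------------
# manifest

MANIFEST_COLUMNS = ["path", "mouse_id", "cohort", "phase", "day",
                    "trial_in_day", "maze", "target_index"]


def write_manifest(rows: pd.DataFrame, path) -> None:
    rows.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df


def meta_from_row(row) -> TrialMeta:
    tgt = row.get("target_index")
    return TrialMeta(
        mouse_id=str(row["mouse_id"]), cohort=str(row["cohort"]),
        phase=str(row["phase"]), day=int(row["day"]),
        trial_in_day=int(row["trial_in_day"]), maze=str(row["maze"]),
        target_index=None if pd.isna(tgt) else int(tgt))


# ---------------------------------------------------------------------------
# feature tables

def write_features(records: pd.DataFrame, path,
                   provenance: Optional[dict] = None) -> None:
    """Write a per-trial feature table with stable column order.

    ``provenance`` entries (e.g. thresholds, config hash) are echoed as
    ``#`` header comments so every output records how it was produced.
    """
    with open(path, "w") as fh:
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key}: {val}\n")
        records.to_csv(fh, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
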