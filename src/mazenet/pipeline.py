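"""Batch orchestration: manifest -> per-trial features -> daily aggregates
-> learning-curve fits -> group statistics.

A single :class:`RunConfig` carries the maze reference, analysis toggles
and every threshold; all of it is echoed (plus a config hash) into the
header of each output file for provenance.  Trials that fail validation
are logged and skipped — a lost trial should not sink a cohort analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import conventional as conv
from . import network as netmod
from .geometry import MazeSpec, builtin_spec, normalize_to_target, spec_from_config
from .stats import per_day_ranksum, results_table
from .strategy import StrategyThresholds, classify_strategy
from .trajectory_io import (Trajectory, TrajectoryQualityError, meta_from_row,
                            read_manifest, read_trial, write_features)

logger = logging.getLogger("mazenet")

__all__ = ["RunConfig", "run", "features_for_trial", "fit_table"]


@dataclass(frozen=True)
class RunConfig:
    maze: str = "BM1"                    # BM1 | BM3 | custom:<path>
    do_conventional: bool = True
    do_strategy: bool = True
    do_network: bool = True
    strategy_thresholds: StrategyThresholds = field(
        default_factory=StrategyThresholds)
    stop_threshold_mm: float = netmod.STOP_THRESHOLD_MM
    stop_window_frames: int = netmod.STOP_WINDOW_FRAMES
    cca_merge_radius_mm: float = netmod.CCA_MERGE_RADIUS_MM
    probe_window_s: float = conv.PROBE_WINDOW_S
    trial_cap_s: float = conv.TRIAL_CAP_S
    fit_days: tuple = (1, 6)             # learning curves fit days 1-6
    out_dir: Optional[str] = None
    log_level: str = "INFO"
    seed: int = 0

    def maze_spec(self) -> MazeSpec:
        if self.maze.startswith("custom:"):
            return spec_from_config(self.maze.split(":", 1)[1])
        return builtin_spec(self.maze)

    def provenance(self) -> Dict[str, str]:
        payload = {f.name: repr(getattr(self, f.name))
                   for f in dataclasses.fields(self)}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
        out = {"config_hash": digest}
        out.update(payload)
        return out


def features_for_trial(traj: Trajectory, spec: MazeSpec,
                       config: RunConfig) -> Dict[str, object]:
    """All enabled feature families for one (raw-coordinate) trial."""
    traj = normalize_to_target(traj, spec)
    spec0 = dataclasses.replace(spec, target_index=0)
    meta = traj.meta
    row: Dict[str, object] = dict(
        mouse_id=meta.mouse_id, cohort=meta.cohort, phase=meta.phase,
        day=meta.day, trial_in_day=meta.trial_in_day, maze=meta.maze)
    is_probe = meta.phase == "probe"
    if config.do_conventional:
        if is_probe:
            profile = conv.probe_profile(traj, spec0,
                                         window=config.probe_window_s)
            row["n_errors"] = profile.n_errors_probe
            row["latency"] = (np.nan if profile.probe_latency is None
                              else profile.probe_latency)
            row["travel_distance"] = traj.path_length()
            for off, dwell in sorted(profile.dwell_by_offset.items()):
                row[f"dwell_{off:+d}"] = dwell
        else:
            row["n_errors"] = conv.count_errors(traj, spec0)
            lat, dist = conv.latency_and_distance(traj, spec0,
                                                  cap=config.trial_cap_s)
            row["latency"] = lat
            row["travel_distance"] = dist
    if config.do_strategy and meta.phase == "training":
        call = classify_strategy(traj, spec0, config.strategy_thresholds)
        row["strategy"] = call.label
        row["strategy_n_nontarget_visits"] = call.n_nontarget_visits
        row["strategy_path_efficiency"] = call.path_efficiency
        row["strategy_quadrant_crossings"] = call.n_quadrant_crossings
        row["strategy_serial_consistency"] = call.serial_consistency
    if config.do_network:
        nm = netmod.trial_network_features(
            traj, spec0, threshold=config.stop_threshold_mm,
            window=config.stop_window_frames,
            merge_radius=config.cca_merge_radius_mm)
        for key, val in nm.as_dict().items():
            row[f"net_{key}"] = val
    return row


def run(manifest, config: RunConfig,
        trajectories: Optional[Sequence[Trajectory]] = None
        ) -> Dict[str, pd.DataFrame]:
    """Run the full pipeline over a manifest.

    ``manifest`` is a path or DataFrame; ``trajectories`` may supply
    in-memory trajectories in manifest order (skipping file IO).  Returns
    ``{"features": ..., "daily": ..., "fits": ...}`` and, when
    ``config.out_dir`` is set, writes each as CSV with provenance headers.
    Failing trials are skipped with a logged reason.
    """
    logging.basicConfig(level=config.log_level)
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    spec = config.maze_spec()

    rows, n_skipped = [], 0
    for i, (_, mrow) in enumerate(manifest.iterrows()):
        try:
            if trajectories is not None:
                traj = trajectories[i]
            else:
                traj = read_trial(mrow["path"], spec,
                                  meta=meta_from_row(mrow))
            rows.append(features_for_trial(traj, spec, config))
        except (TrajectoryQualityError, OSError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping trial %s (%s)",
                           mrow.get("path") or mrow["mouse_id"], exc)
    logger.info("processed %d trials, skipped %d", len(rows), n_skipped)
    features = pd.DataFrame(rows)

    training = features[features["phase"] == "training"]
    daily_rows = []
    value_cols = [c for c in ("n_errors", "latency", "travel_distance")
                  if c in features.columns]
    value_cols += [c for c in features.columns if c.startswith("net_")]
    for (mouse, day), grp in training.groupby(["mouse_id", "day"]):
        row = {"mouse_id": mouse, "day": day,
               "cohort": grp["cohort"].iloc[0], "maze": grp["maze"].iloc[0]}
        for col in value_cols:
            row[col] = grp[col].mean()
        daily_rows.append(row)
    daily = pd.DataFrame(daily_rows)

    fits = fit_table(training, config)

    out = {"features": features, "daily": daily, "fits": fits}
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prov = config.provenance()
        for name, df in out.items():
            write_features(df, out_dir / f"{name}.csv", provenance=prov)
    return out


def fit_table(training: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-mouse exponential learning-curve fits over the fit-day window.

    Error counts are fitted raw; latency and travel distance are first
    normalized to unit sum within each mouse so curves are unitless and
    comparable across maze scales.
    """
    lo, hi = config.fit_days
    rows = []
    for mouse, grp in training.groupby("mouse_id"):
        grp = grp[(grp["day"] >= lo) & (grp["day"] <= hi)]
        grp = grp.sort_values(["day", "trial_in_day"])
        if len(grp) < 4:
            continue
        base = 1 + (int(grp["day"].iloc[0]) - lo) * 3
        for feat, normalize in (("n_errors", False), ("latency", True),
                                ("travel_distance", True)):
            if feat not in grp.columns:
                continue
            y = grp[feat].to_numpy(dtype=float)
            if normalize:
                if y.sum() <= 0:
                    continue
                y = y / y.sum()
            fit = conv.fit_learning_curve(y, trial_index_base=base)
            rows.append(dict(mouse_id=mouse, cohort=grp["cohort"].iloc[0],
                             maze=grp["maze"].iloc[0], feature=feat,
                             alpha=fit.alpha, beta=fit.beta,
                             residual_norm=fit.residual_norm,
                             n_trials_fit=fit.n_trials_fit))
    return pd.DataFrame(rows)
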