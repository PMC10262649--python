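"""Exploration-network analysis of stopping behavior.

A trajectory is reduced to an undirected graph in three steps:

1. **Stop detection** — a stop is a maximal run of at least 20 successive
   frames (1 s at 20 Hz) whose within-window traveled distance stays below
   4 cm (about half a mouse body length); each stop is summarized by its
   centroid.
2. **City Clustering Algorithm (CCA)** — stops are iteratively merged into
   nodes: each stop joins the nearest node closer than the merge radius
   (4 cm) or founds a new node; node centroids are then recomputed from
   their member stops, and the assignment pass repeats until it no longer
   changes.
3. **Graph construction** — consecutive stops mapped to distinct nodes add
   an undirected link; no self-links, duplicates collapse.

Seven measures quantify the resulting network: number of stops, order,
mean degree, density, mean clustering coefficient, mean shortest path,
mean betweenness centrality (fraction of shortest s–t paths through a
node, averaged over pairs excluding it) and mean closeness centrality
(defined as the *unnormalized* inverse of a node's summed path lengths).
Per-node measures are averaged over the nodes of each network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .geometry import MazeSpec
from .trajectory_io import Trajectory

logger = logging.getLogger("mazenet")

__all__ = [
    "StopEvent",
    "ExplorationNetwork",
    "NetworkMeasures",
    "detect_stops",
    "cca_cluster",
    "build_network",
    "measures",
    "trial_network_features",
]

STOP_THRESHOLD_MM = 40.0   # ~half the average mouse body length, absolute
STOP_WINDOW_FRAMES = 20    # 1 s at 20 Hz
CCA_MERGE_RADIUS_MM = 40.0
CCA_MAX_ITER = 100


@dataclass(frozen=True)
class StopEvent:
    centroid: np.ndarray   # (2,) mm
    t_start: float
    t_end: float
    n_frames: int


@dataclass(frozen=True)
class ExplorationNetwork:
    node_centroids: np.ndarray          # (k, 2)
    members: Tuple[Tuple[int, ...], ...]  # stop indices per node
    links: frozenset                    # of frozenset({u, v}), u != v
    stop_sequence: Tuple[int, ...]      # node index of each stop, in time

    @property
    def order(self) -> int:
        return len(self.members)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.order))
        g.add_edges_from(tuple(sorted(link)) for link in self.links)
        return g


def detect_stops(traj: Trajectory, spec: Optional[MazeSpec] = None,
                 threshold: float = STOP_THRESHOLD_MM,
                 window: int = STOP_WINDOW_FRAMES) -> List[StopEvent]:
    """Detect sustained low-movement epochs.

    Sliding-window semantics: frame ``j`` closes a qualifying window when
    the path length over frames ``j-window+1 .. j`` is below ``threshold``.
    Runs of consecutive qualifying windows form one stop covering the union
    of their frames, extended frame-by-frame for as long as the trailing
    window keeps qualifying; a single non-qualifying window separates
    distinct stops.  The stop threshold is an absolute length — it does not
    scale with the arena.
    """
    n = len(traj)
    if n < window:
        return []
    steps = traj.step_lengths()
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    # path length over frames [j-window+1, j] = csum[j] - csum[j-window+1]
    j = np.arange(window - 1, n)
    win_len = csum[j] - csum[j - window + 1]
    qualifying = win_len < threshold
    stops: List[StopEvent] = []
    if not qualifying.any():
        return stops
    edges = np.diff(qualifying.astype(int))
    run_starts = np.where(edges == 1)[0] + 1
    run_ends = np.where(edges == -1)[0]
    if qualifying[0]:
        run_starts = np.concatenate([[0], run_starts])
    if qualifying[-1]:
        run_ends = np.concatenate([run_ends, [len(qualifying) - 1]])
    for rs, re in zip(run_starts, run_ends):
        first = int(j[rs] - window + 1)
        last = int(j[re])
        pts = traj.points[first:last + 1]
        stops.append(StopEvent(pts.mean(axis=0),
                               float(traj.times[first]),
                               float(traj.times[last]),
                               last - first + 1))
    return stops


def cca_cluster(stops: Sequence[StopEvent],
                merge_radius: float = CCA_MERGE_RADIUS_MM,
                max_iter: int = CCA_MAX_ITER
                ) -> Tuple[np.ndarray, List[List[int]]]:
    """City Clustering Algorithm on stop centroids.

    Iterates: (1) visit stops in temporal order, assigning each to the
    nearest current node if closer than ``merge_radius`` (else the stop
    founds a new node at its own coordinate — new nodes are immediately
    available to later stops in the same pass); (2) recompute every node
    centroid as the centroid of its member stops; (3) repeat with cleared
    assignments until the partition no longer changes.

    Returns ``(node_centroids, members)``.  Processing order is the
    temporal order of the stops, which makes the result deterministic.
    """
    coords = np.array([s.centroid for s in stops], dtype=float).reshape(-1, 2)
    n = len(coords)
    if n == 0:
        return np.empty((0, 2)), []

    node_centroids: List[np.ndarray] = []
    prev_assignment: Optional[List[int]] = None
    for iteration in range(max_iter):
        assignment: List[int] = []
        pass_centroids: List[np.ndarray] = list(node_centroids)
        for i in range(n):
            if pass_centroids:
                d = np.linalg.norm(np.asarray(pass_centroids) - coords[i],
                                   axis=1)
                k = int(np.argmin(d))
                if d[k] < merge_radius:
                    assignment.append(k)
                    continue
            pass_centroids.append(coords[i].copy())
            assignment.append(len(pass_centroids) - 1)
        # drop nodes that attracted no stops this pass, then recompute
        # centroids from member stops
        used = sorted(set(assignment))
        relabel = {old: new for new, old in enumerate(used)}
        assignment = [relabel[a] for a in assignment]
        members: List[List[int]] = [[] for _ in used]
        for i, a in enumerate(assignment):
            members[a].append(i)
        node_centroids = [coords[m].mean(axis=0) for m in members]
        if assignment == prev_assignment:
            break
        prev_assignment = assignment
    else:
        logger.warning("CCA did not converge within %d iterations", max_iter)
    return np.asarray(node_centroids), members


def build_network(stops: Sequence[StopEvent],
                  node_centroids: np.ndarray,
                  members: Sequence[Sequence[int]]) -> ExplorationNetwork:
    """Add an undirected link for every temporal transition between stops
    mapped to distinct nodes; self-transitions and duplicates collapse."""
    node_of = {}
    for k, mem in enumerate(members):
        for i in mem:
            node_of[i] = k
    seq = tuple(node_of[i] for i in range(len(stops)))
    links = frozenset(frozenset((u, v))
                      for u, v in zip(seq, seq[1:]) if u != v)
    return ExplorationNetwork(np.asarray(node_centroids, dtype=float),
                              tuple(tuple(m) for m in members), links, seq)


@dataclass(frozen=True)
class NetworkMeasures:
    n_stops: int
    order: int
    degree: float
    density: float
    clustering: float
    shortest_path: float
    betweenness: float
    closeness: float

    def as_dict(self) -> dict:
        return {
            "n_stops": self.n_stops, "order": self.order,
            "degree": self.degree, "density": self.density,
            "clustering": self.clustering,
            "shortest_path": self.shortest_path,
            "betweenness": self.betweenness, "closeness": self.closeness,
        }


def measures(net: ExplorationNetwork,
             n_stops: Optional[int] = None) -> NetworkMeasures:
    """The seven network measures, each averaged over nodes.

    Conventions for awkward graphs (the underlying definitions are silent
    on disconnection, which empty-link trials produce):

    * shortest path and closeness average over *reachable* pairs only;
      a node with no reachable partner contributes NaN and is dropped from
      the node average (all-NaN networks report NaN);
    * betweenness counts only connected s–t pairs, normalized by the number
      of (unordered, for an undirected graph) pairs excluding the node;
    * density and degree are NaN/0 for order < 2; order 0 makes every
      measure NaN.
    """
    k = net.order
    if n_stops is None:
        n_stops = len(net.stop_sequence)
    if k == 0:
        nan = float("nan")
        return NetworkMeasures(n_stops, 0, nan, nan, nan, nan, nan, nan)
    g = net.graph()

    degree = 2.0 * g.number_of_edges() / k
    density = float("nan") if k < 2 else nx.density(g)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    betweenness = float(np.mean(list(
        nx.betweenness_centrality(g, normalized=(k > 2)).values())))

    sp_means, closeness_vals = [], []
    for node in g.nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        del dists[node]
        if dists:
            vals = list(dists.values())
            sp_means.append(float(np.mean(vals)))
            closeness_vals.append(1.0 / float(np.sum(vals)))
    shortest_path = float(np.mean(sp_means)) if sp_means else float("nan")
    closeness = (float(np.mean(closeness_vals))
                 if closeness_vals else float("nan"))
    return NetworkMeasures(int(n_stops), k, degree, density, clustering,
                           shortest_path, betweenness, closeness)


def trial_network_features(traj: Trajectory, spec: MazeSpec,
                           threshold: float = STOP_THRESHOLD_MM,
                           window: int = STOP_WINDOW_FRAMES,
                           merge_radius: float = CCA_MERGE_RADIUS_MM
                           ) -> NetworkMeasures:
    """Full stop-to-measures composition for one trial."""
    stops = detect_stops(traj, spec, threshold=threshold, window=window)
    centroids, members = cca_cluster(stops, merge_radius=merge_radius)
    net = build_network(stops, centroids, members)
    return measures(net, n_stops=len(stops))
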