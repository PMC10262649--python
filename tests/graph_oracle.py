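"""Brute-force graph-measure oracle for small graphs.

Everything here is computed by exhaustive enumeration of simple paths —
independent of networkx — so it can serve as the ground truth against the
package's network measures on graphs of up to ~8 nodes.
"""

from itertools import combinations
from math import comb


def _all_simple_paths(n, edges, s, t):
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    paths = []

    def dfs(node, visited, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return paths


def oracle_measures(n, edges):
    """Mean degree, density, clustering, shortest path, betweenness and
    closeness of an undirected simple graph, all from path enumeration.

    Unreachable pairs are skipped in shortest-path/closeness averages (a
    node with no reachable partner is dropped from the node average);
    betweenness is normalized by the number of unordered pairs excluding
    the node.  Returns a dict; values are None when undefined.
    """
    edges = {frozenset(e) for e in edges}
    adj = {i: set() for i in range(n)}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    degree = [len(adj[i]) for i in range(n)]
    density = (len(edges) / comb(n, 2)) if n >= 2 else None

    clustering = []
    for i in range(n):
        if degree[i] < 2:
            clustering.append(0.0)
            continue
        closed = sum(1 for a, b in combinations(adj[i], 2)
                     if frozenset((a, b)) in edges)
        clustering.append(closed / comb(degree[i], 2))

    # shortest paths between every pair by enumeration
    dist = {}
    shortest_paths = {}
    for s, t in combinations(range(n), 2):
        paths = _all_simple_paths(n, edges, s, t)
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        dist[(s, t)] = d
        shortest_paths[(s, t)] = [p for p in paths if len(p) - 1 == d]

    sp_means, closeness = [], []
    for i in range(n):
        ds = [d for (s, t), d in dist.items() if i in (s, t)]
        if ds:
            sp_means.append(sum(ds) / len(ds))
            closeness.append(1.0 / sum(ds))

    betweenness = []
    for i in range(n):
        total = 0.0
        for (s, t), paths in shortest_paths.items():
            if i in (s, t):
                continue
            total += sum(1 for p in paths if i in p) / len(paths)
        n_pairs = comb(n - 1, 2)
        betweenness.append(total / n_pairs if n_pairs else 0.0)

    def avg(vals):
        return sum(vals) / len(vals) if vals else None

    return {
        "degree": avg(degree),
        "density": density,
        "clustering": avg(clustering),
        "shortest_path": avg(sp_means),
        "betweenness": avg(betweenness),
        "closeness": avg(closeness),
    }
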