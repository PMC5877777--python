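"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different algorithmic routes from the package:
pairwise direct summation for correlations, exhaustive simple-path
enumeration for Dijkstra, explicit shortest-path counting for betweenness,
hand-rolled BFS for hop distances, and per-state Boltzmann summation for
the folding-unit ensemble.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

R_KCAL = 1.987e-3


def naive_dccm(frames: np.ndarray) -> np.ndarray:
    """Two-pass direct-summation cross-correlation, pair by pair."""
    F, N, _ = frames.shape
    mean = frames.sum(axis=0) / F
    d = frames - mean
    C = np.empty((N, N))
    for i in range(N):
        for j in range(i, N):
            dot = 0.0
            for axis in range(3):
                dot += float(np.dot(d[:, i, axis], d[:, j, axis]))
            C[i, j] = C[j, i] = dot / F
    norm = np.sqrt(np.diag(C))
    for i in range(N):
        for j in range(N):
            C[i, j] = C[i, j] / (norm[i] * norm[j])
    return C


def enumerate_simple_paths(graph, source, target):
    """Yield (cost, hops, path) over every simple path, DFS order."""
    def dfs(node, visited, cost, path):
        if node == target:
            yield cost, len(path) - 1, tuple(path)
            return
        for nbr in sorted(graph[node]):
            if nbr in visited:
                continue
            yield from dfs(nbr, visited | {nbr}, cost + graph[node][nbr]["cost"],
                           path + [nbr])
    yield from dfs(source, {source}, 0.0, [source])


def brute_shortest_path(graph, source, target):
    """Minimum over all simple paths under the (cost, hops, lex) order."""
    best = None
    for key in enumerate_simple_paths(graph, source, target):
        if best is None or key < best:
            best = key
    return best  # None if unreachable


def bfs_lengths(graph, source) -> dict:
    """Hop distances by hand-rolled BFS."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for nbr in graph[v]:
            if nbr not in dist:
                dist[nbr] = dist[v] + 1
                queue.append(nbr)
    return dist


def _all_shortest_paths(graph, s, t, dist_from_s):
    """Enumerate every shortest s-t path using BFS distance labels."""
    if t not in dist_from_s:
        return []
    target_d = dist_from_s[t]
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nbr in graph[node]:
            if dist_from_s.get(nbr) == dist_from_s[node] + 1 and \
                    dist_from_s[nbr] <= target_d:
                walk(nbr, path + [nbr])

    walk(s, [s])
    return paths


def brute_betweenness(graph) -> dict:
    """Fractional shortest-path counting over unordered pairs."""
    nodes = sorted(graph)
    bc = {v: 0.0 for v in nodes}
    for idx, s in enumerate(nodes):
        dist = bfs_lengths(graph, s)
        for t in nodes[idx + 1:]:
            paths = _all_shortest_paths(graph, s, t, dist)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += share
    return bc


def brute_reachability(graph):
    """(L_i, unreachable count) per node via hand BFS."""
    nodes = sorted(graph)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_lengths(graph, v)
        reach = len(dist) - 1
        total = sum(dist.values())
        l_val = total / reach if reach else float("nan")
        out[v] = (l_val, (n - 1) - reach)
    return out


def brute_ensemble(unit_energies, temperature):
    """Per-unit stability constants by explicit state-by-state summation."""
    import math

    g = list(unit_energies)
    u_count = len(g)
    rt = R_KCAL * temperature
    z = 0.0
    folded = [0.0] * u_count
    for state in itertools.product([False, True], repeat=u_count):
        energy = sum(gu for gu, is_folded in zip(g, state) if not is_folded)
        w = math.exp(-energy / rt)
        z += w
        for u, is_folded in enumerate(state):
            if is_folded:
                folded[u] += w
    kappa = [f / (z - f) if z > f else float("inf") for f in folded]
    dg = [-rt * math.log(k) if np.isfinite(k) else -np.inf for k in kappa]
    return np.array(kappa), np.array(dg), z
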