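"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (pair enumeration, BFS path counting,
rank-then-Pearson) and shares no code path with the package.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def auc_by_pair_enumeration(scores, labels) -> float:
    """P(positive outscores negative), ties 1/2, by explicit double loop."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def spearman_rank_then_pearson(x, y) -> float:
    """Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _all_shortest_paths(adj: dict, s, t):
    """Enumerate every shortest s-t path by BFS levels then DFS."""
    from collections import deque

    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def betweenness_by_path_enumeration(nodes, edges) -> dict:
    """Normalized betweenness via explicit shortest-path enumeration.

    Normalization divides by (n-1)(n-2)/2 with n = len(nodes); nodes and
    edges describe an undirected simple graph.
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {u: 0.0 for u in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    n = len(nodes)
    if n < 3:
        return {u: 0.0 for u in nodes}
    scale = (n - 1) * (n - 2) / 2
    return {u: bc[u] / scale for u in nodes}
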