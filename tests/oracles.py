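"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and networkx algorithms)
they are used to check: tallies are dict counting over raw records, component
finding is a hand-rolled union-find, and betweenness enumerates every
shortest path explicitly.
"""

from collections import Counter, deque
from itertools import combinations


def tally_scn(records):
    """(collector, taxon) -> co-occurrence count, straight off the records."""
    counts = Counter()
    for rec in records:
        for cid in rec.collector_ids:
            counts[(cid, rec.taxon_name)] += 1
    return counts


def tally_cwn_full_count(teams):
    """(u, v) sorted pair -> number of shared teams."""
    counts = Counter()
    for team in teams:
        for u, v in combinations(sorted(team.members), 2):
            counts[(u, v)] += 1
    return counts


def union_find_components(nodes, edges):
    """Connected components via union-find; returns a set of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def _bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj, dist, s, t):
    """Enumerate every shortest s-t path by walking the distance gradient."""
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nxt in adj[node]:
            if dist.get(nxt) == dist[node] + 1 and dist.get(t, -1) >= dist[nxt]:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_betweenness(nodes, edges, normalized=True):
    """Freeman betweenness by exhaustive shortest-path enumeration."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    score = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        dist = _bfs_distances(adj, s)
        for t in nodes[i + 1 :]:
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            sigma = len(paths)
            through = Counter(v for p in paths for v in p[1:-1])
            for v, c in through.items():
                score[v] += c / sigma
    n = len(nodes)
    if normalized and n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: s / norm for v, s in score.items()}
    return score
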